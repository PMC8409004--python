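import numpy as np
import pytest
from scipy import stats as sstats

from examvoice import evaluation as ev
from examvoice import features as ft
from examvoice.data_io import read_manifest, read_segmentation, read_timelines, read_wav
from examvoice.synthetic_cohort import (
    EFFECT_PRESETS,
    SyntheticCohortConfig,
    TEST_DURATION_PRIORS,
    class_acoustics,
    generate_cohort,
    measure_silence_fraction,
    sample_segmentation,
    synthesize_exam_audio,
)
from examvoice.data_io import TestSegmentation

NO_AUDIO = dict(synthesize_audio=False)


class TestDeterminism:
    def test_same_seed_identical_on_disk(self, tmp_path):
        cfg = SyntheticCohortConfig(n_recordings=10, seed=21, **NO_AUDIO)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        for name in ["manifest.csv", "timelines.csv"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
        for f in sorted((tmp_path / "a" / "segmentations").iterdir()):
            assert f.read_bytes() == \
                   (tmp_path / "b" / "segmentations" / f.name).read_bytes()

    def test_same_seed_identical_waveform(self):
        cfg = SyntheticCohortConfig(n_recordings=2, duration_scale=0.02,
                                    tests_per_recording=1, seed=5)
        a = generate_cohort(cfg).recordings[0].waveform.samples
        b = generate_cohort(cfg).recordings[0].waveform.samples
        np.testing.assert_array_equal(a, b)


class TestCohortStructure:
    def test_recording_level_class_mix_within_binomial_bounds(self):
        cfg = SyntheticCohortConfig(n_recordings=300, seed=8,
                                    class_mix=(0.4, 0.3, 0.3), **NO_AUDIO)
        cohort = generate_cohort(cfg)
        n = len(cohort.recordings)
        assert n == 300
        for label, p in zip(("NC", "MCI", "DE"), cfg.class_mix):
            count = cohort.labels.count(label)
            lo = sstats.binom.ppf(0.005, n, p)
            hi = sstats.binom.ppf(0.995, n, p)
            assert lo <= count <= hi, (label, count)

    def test_progression_is_monotone_within_participant(self):
        cfg = SyntheticCohortConfig(n_recordings=150, seed=2, **NO_AUDIO)
        cohort = generate_cohort(cfg)
        sev = {"NC": 0, "MCI": 1, "DE": 2}
        by_pid: dict[str, list] = {}
        for r in cohort.recordings:
            by_pid.setdefault(r.participant_id, []).append(r)
        for recs in by_pid.values():
            recs.sort(key=lambda r: r.recording_date)
            sevs = [sev[r.label] for r in recs]
            assert sevs == sorted(sevs)

    def test_label_rule_round_trip(self):
        cfg = SyntheticCohortConfig(n_recordings=80, seed=13, **NO_AUDIO)
        cohort = generate_cohort(cfg)
        for r in cohort.recordings:
            assigned = ev.assign_label(r.recording_date,
                                       cohort.timelines[r.participant_id])
            assert assigned == r.label

    def test_duration_means_follow_priors_at_full_scale(self):
        # class-conditional means within 3 SE of the configured priors
        rng = np.random.default_rng(31)
        cfg = SyntheticCohortConfig(duration_scale=1.0,
                                    battery=("Boston Naming Test",),
                                    tests_per_recording=1, **NO_AUDIO)
        n = 1000
        for label in ("NC", "DE"):
            mean, sd = TEST_DURATION_PRIORS["Boston Naming Test"][label]
            durs = []
            for _ in range(n):
                seg = sample_segmentation(label, cfg, rng)
                _, start, end = seg.intervals[0]
                durs.append(end - start)
            assert abs(np.mean(durs) - mean) < 3 * sd / np.sqrt(n)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(battery=())
        with pytest.raises(ValueError):
            SyntheticCohortConfig(class_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SyntheticCohortConfig(duration_scale=0.0)


class TestAcousticEffects:
    @staticmethod
    def _silence_fractions(effect_scale, label, n, seed):
        cfg = SyntheticCohortConfig(effect_scale=effect_scale, seed=0)
        rng = np.random.default_rng(seed)
        seg = TestSegmentation(intervals=[("probe", 0.5, 10.5)])
        return np.array([
            measure_silence_fraction(
                synthesize_exam_audio(label, seg, cfg, rng))
            for _ in range(n)
        ])

    def test_zero_effect_classes_identically_distributed(self):
        nc = self._silence_fractions(EFFECT_PRESETS["zero"], "NC", 100, 41)
        de = self._silence_fractions(EFFECT_PRESETS["zero"], "DE", 100, 42)
        assert sstats.ks_2samp(nc, de).pvalue > 0.01

    def test_strong_effect_increases_pauses_in_dementia(self):
        nc = self._silence_fractions(EFFECT_PRESETS["strong"], "NC", 40, 43)
        de = self._silence_fractions(EFFECT_PRESETS["strong"], "DE", 40, 44)
        assert de.mean() > nc.mean() + 0.05

    def test_effect_parameters_monotone_in_scale(self):
        rows = [class_acoustics("DE", SyntheticCohortConfig(effect_scale=s,
                                                            **NO_AUDIO))
                for s in (0.0, 0.5, 1.0)]
        assert rows[0]["pause_fraction"] < rows[1]["pause_fraction"] < rows[2]["pause_fraction"]
        assert rows[0]["syllable_hz"] > rows[1]["syllable_hz"] > rows[2]["syllable_hz"]
        assert rows[0]["jitter_hz"] < rows[1]["jitter_hz"] < rows[2]["jitter_hz"]
        nc = class_acoustics("NC", SyntheticCohortConfig(effect_scale=1.0, **NO_AUDIO))
        zero = class_acoustics("DE", SyntheticCohortConfig(effect_scale=0.0, **NO_AUDIO))
        assert nc == zero  # zero effect collapses DE onto the NC baseline

    def test_waveform_peak_bounded(self, tiny_cohort):
        for r in tiny_cohort.recordings:
            assert np.max(np.abs(r.waveform.samples)) <= 1.0


class TestEndToEnd:
    def test_disk_cohort_feeds_the_whole_pipeline(self, tmp_path):
        cfg = SyntheticCohortConfig(n_recordings=4, duration_scale=0.02,
                                    tests_per_recording=2, seed=17)
        generate_cohort(cfg, out_dir=tmp_path)
        manifest = read_manifest(tmp_path / "manifest.csv")
        assert len(manifest) == 4
        timelines = read_timelines(tmp_path / "timelines.csv")
        for rec in manifest:
            w = read_wav(tmp_path / rec.audio_path)
            assert abs(w.duration_s - rec.duration_s) < 0.01
            seg = read_segmentation(
                tmp_path / "segmentations" / f"{rec.recording_id}.tsv")
            assert seg.end_s <= w.duration_s
            m = ft.extract_mfcc(w)
            assert m.frames.shape[1] == 13
            assert ev.assign_label(rec.recording_date,
                                   timelines[rec.participant_id]) in (
                "NC", "MCI", "DE")
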