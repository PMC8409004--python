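"""Fully synthetic exam-like cohorts: waveforms, test segmentations, and
diagnosis timelines with the statistical structure the analysis assumes.

Each synthetic recording is a sequence of neuropsychological-test intervals.
Per-test administered durations are drawn from class-conditional truncated
normals whose means and standard deviations (in seconds, for NC / MCI / DE)
follow the observed per-test timing of the real exam battery; a
``duration_scale`` shrinks everything proportionally so that desk-scale
cohorts (default ~1-2 min recordings) exercise the same machinery as
hour-long exams. Within a test interval, two speakers alternate: an
examiner and the participant, each "utterance" a harmonic tone complex with
a speaker-specific fundamental band, amplitude-modulated at a syllable rate
and separated by pauses.

Cognitive impairment enters through four monotone, independently
configurable effects on the participant's audio, all scaled by a single
``effect_scale`` (0 = classes identically distributed, 1 = "strong"):

* pause fraction increases (speech is more hesitant);
* syllable (amplitude-modulation) rate decreases (slower speech);
* fundamental-frequency jitter increases (less stable phonation);
* harmonic roll-off steepens (duller spectrum).

MCI receives half of the DE shift. Utterance loudness is RMS-normalized so
no class is separable by amplitude alone. Diagnosis timelines place one
entry on each recording date, with statuses sorted by severity within a
participant (so cognitive status can progress across repeat recordings but
never regresses), which makes the 180-day labeling rule reproduce the
intended label for every recording by construction.

Acoustic realism is intentionally minimal — tone-complex "speech" is enough
to exercise the MFCC front-end and the temporal structure the models
consume — and none of the distributional choices are claims about real
exam audio.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path


import numpy as np

from .data_io import (
    DiagnosisTimeline,
    RecordingRecord,
    TestSegmentation,
    Waveform,
    write_manifest,
    write_segmentation,
    write_timelines,
    write_wav,
)

CLASS_SEVERITY = {"NC": 0, "MCI": 1, "DE": 2}

#: Per-test administered-duration priors, seconds: {test: {class: (mean, sd)}}.
#: Values follow the observed class-conditional timing of the standard
#: neuropsychological battery on which this pipeline is modeled.
TEST_DURATION_PRIORS: dict[str, dict[str, tuple[float, float]]] = {
    "Demographics": {"NC": (244.4, 151.0), "MCI": (178.7, 106.4), "DE": (295.5, 163.2)},
    "Logical memory immediate recall": {"NC": (135.0, 28.6), "MCI": (116.9, 19.5), "DE": (128.9, 38.5)},
    "Visual reproductions immediate recall": {"NC": (219.3, 79.2), "MCI": (190.8, 37.9), "DE": (236.1, 67.9)},
    "Verbal paired associates learning": {"NC": (367.6, 80.4), "MCI": (366.4, 65.3), "DE": (414.3, 155.1)},
    "Digit span forward": {"NC": (115.9, 31.4), "MCI": (100.1, 32.3), "DE": (107.5, 36.7)},
    "Digit span backward": {"NC": (109.0, 42.5), "MCI": (128.2, 44.7), "DE": (132.6, 52.6)},
    "Logical memory delayed recall": {"NC": (86.3, 37.8), "MCI": (57.1, 20.2), "DE": (54.0, 25.3)},
    "Logical memory multiple choice": {"NC": (89.4, 18.3), "MCI": (103.8, 31.2), "DE": (138.9, 62.3)},
    "Visual reproductions delayed recall": {"NC": (140.6, 73.2), "MCI": (114.8, 28.3), "DE": (79.1, 48.2)},
    "Visual reproductions multiple choice": {"NC": (63.5, 26.5), "MCI": (60.9, 27.8), "DE": (77.5, 37.1)},
    "Verbal paired associates recall": {"NC": (66.2, 23.5), "MCI": (85.6, 43.7), "DE": (90.3, 48.7)},
    "Verbal paired associates recognition": {"NC": (75.8, 21.6), "MCI": (90.0, 26.4), "DE": (126.0, 52.2)},
    "Similarities": {"NC": (227.8, 89.6), "MCI": (217.3, 79.5), "DE": (228.0, 120.4)},
    "Command clock": {"NC": (80.9, 31.2), "MCI": (83.3, 29.1), "DE": (133.0, 82.2)},
    "Verbal fluency": {"NC": (325.5, 39.0), "MCI": (330.0, 29.2), "DE": (336.1, 65.4)},
    "Boston Naming Test": {"NC": (405.9, 176.8), "MCI": (321.2, 93.8), "DE": (611.1, 260.2)},
    "Copy clock": {"NC": (70.1, 33.5), "MCI": (54.7, 14.0), "DE": (90.9, 44.4)},
    "Trails A": {"NC": (115.4, 58.3), "MCI": (105.3, 23.7), "DE": (199.0, 107.1)},
    "Trails B": {"NC": (219.2, 107.6), "MCI": (241.0, 117.5), "DE": (431.2, 278.0)},
    "WRAT-3 reading": {"NC": (119.7, 36.8), "MCI": (115.1, 52.3), "DE": (142.8, 70.4)},
    "Hooper visual organization test": {"NC": (398.5, 182.1), "MCI": (284.1, 90.8), "DE": (424.6, 187.4)},
    "Block design (WAIS)": {"NC": (357.3, 213.6), "MCI": (389.7, 145.0), "DE": (487.3, 214.3)},
    "Finger tapping": {"NC": (294.4, 106.9), "MCI": (323.8, 87.6), "DE": (289.0, 130.6)},
    "Information (WAIS-R)": {"NC": (392.7, 181.2), "MCI": (335.8, 156.9), "DE": (372.7, 153.6)},
    "Cookie theft": {"NC": (198.9, 75.3), "MCI": (244.6, 101.7), "DE": (186.9, 147.0)},
    "Clock drawing number placement": {"NC": (47.6, 40.6), "MCI": (51.8, 20.5), "DE": (81.6, 71.5)},
    "Clock drawing time setting": {"NC": (44.0, 26.9), "MCI": (37.9, 7.6), "DE": (75.3, 59.3)},
}

#: Named effect scales: 0 makes all classes identically distributed.
EFFECT_PRESETS = {"zero": 0.0, "weak": 0.5, "strong": 1.0}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_recordings: int = 120
    class_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # NC, MCI, DE
    recordings_per_participant: tuple[float, float, float] = (0.5, 0.3, 0.2)  # P(1..3)
    tests_per_recording: int = 5
    duration_scale: float = 0.1   # fraction of realistic administered length
    effect_scale: float = 1.0     # "strong"; see EFFECT_PRESETS
    duration_effect_scale: float | None = None  # defaults to effect_scale
    rate: int = 8000
    seed: int = 0
    battery: tuple[str, ...] = tuple(TEST_DURATION_PRIORS)
    synthesize_audio: bool = True
    # acoustics (class-invariant baselines)
    examiner_f0: tuple[float, float] = (100.0, 140.0)
    participant_f0: tuple[float, float] = (160.0, 220.0)
    utterance_s: tuple[float, float] = (0.8, 2.0)
    base_pause_fraction: float = 0.25
    base_syllable_hz: float = 4.0
    base_jitter_hz: float = 2.0
    base_rolloff: float = 0.75
    n_harmonics: int = 5
    speech_amplitude: float = 0.3
    noise_level: float = 0.01
    # maximal (DE at effect_scale 1) shifts; MCI gets half
    pause_fraction_shift: float = 0.20
    syllable_rate_drop: float = 0.40
    jitter_gain: float = 4.0
    rolloff_drop: float = 0.20

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 < self.duration_scale <= 1.0:
            raise ValueError("duration_scale must be in (0, 1]")
        if not self.battery:
            raise ValueError("battery must name at least one test")
        if self.tests_per_recording < 1:
            raise ValueError("tests_per_recording must be >= 1")
        if any(TEST_DURATION_PRIORS[t]["NC"][0] <= 0 for t in self.battery):
            raise ValueError("all duration means must be positive")


def full_scale_config(**overrides) -> SyntheticCohortConfig:
    """Profile with unscaled, hour-scale administered durations."""
    return replace(SyntheticCohortConfig(duration_scale=1.0,
                                         tests_per_recording=20), **overrides)


@dataclass
class SyntheticRecording:
    recording_id: str
    participant_id: str
    recording_date: _dt.date
    label: str
    segmentation: TestSegmentation
    waveform: Waveform | None = None


@dataclass
class Cohort:
    recordings: list[SyntheticRecording]
    timelines: dict[str, DiagnosisTimeline]
    config: SyntheticCohortConfig

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.recordings]

    @property
    def participants(self) -> list[str]:
        return [r.participant_id for r in self.recordings]

    def manifest_records(self, audio_dir: str = "wavs") -> list[RecordingRecord]:
        return [
            RecordingRecord(
                recording_id=r.recording_id,
                participant_id=r.participant_id,
                recording_date=r.recording_date,
                audio_path=f"{audio_dir}/{r.recording_id}.wav",
                duration_s=(r.waveform.duration_s if r.waveform is not None
                            else r.segmentation.end_s + 0.5),
            )
            for r in self.recordings
        ]


def class_acoustics(label: str, cfg: SyntheticCohortConfig) -> dict[str, float]:
    """Participant acoustic parameters for one class at cfg.effect_scale."""
    frac = {"NC": 0.0, "MCI": 0.5, "DE": 1.0}[label] * cfg.effect_scale
    return {
        "pause_fraction": cfg.base_pause_fraction + frac * cfg.pause_fraction_shift,
        "syllable_hz": cfg.base_syllable_hz * (1.0 - frac * cfg.syllable_rate_drop),
        "jitter_hz": cfg.base_jitter_hz * (1.0 + frac * cfg.jitter_gain),
        "rolloff": cfg.base_rolloff - frac * cfg.rolloff_drop,
    }


def _truncated_normal(mean: float, sd: float, floor: float,
                      rng: np.random.Generator, max_tries: int = 200) -> float:
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x >= floor:
            return x
    return floor


def sample_segmentation(label: str, cfg: SyntheticCohortConfig,
                        rng: np.random.Generator) -> TestSegmentation:
    """Draw a per-recording battery and class-conditional test durations.

    Duration priors interpolate between the class-neutral (NC) prior and
    the full class-conditional prior with the duration effect scale, so at
    effect scale 0 all classes draw identically distributed durations and
    at scale 1 durations follow the observed class-conditional timing.
    Draws are truncated at ``5 s x duration_scale``; tests are laid out
    sequentially from 0.5 s with 0.5 s un-annotated gaps.
    """
    s = (cfg.duration_effect_scale if cfg.duration_effect_scale is not None
         else cfg.effect_scale)
    names = list(cfg.battery)
    k = min(cfg.tests_per_recording, len(names))
    chosen = rng.choice(len(names), size=k, replace=False)
    t = 0.5
    intervals = []
    floor = 5.0 * cfg.duration_scale
    for i in chosen:
        name = names[i]
        mean_nc, sd_nc = TEST_DURATION_PRIORS[name]["NC"]
        mean_cl, sd_cl = TEST_DURATION_PRIORS[name][label]
        mean = (1.0 - s) * mean_nc + s * mean_cl
        sd = (1.0 - s) * sd_nc + s * sd_cl
        dur = _truncated_normal(mean * cfg.duration_scale,
                                sd * cfg.duration_scale, floor, rng)
        intervals.append((name, t, t + dur))
        t += dur + 0.5
    return TestSegmentation(intervals=intervals)


def _utterance(duration_s: float, f0_band: tuple[float, float],
               jitter_hz: float, rolloff: float, syllable_hz: float,
               cfg: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    """One harmonic-complex utterance, RMS-normalized before amplitude."""
    m = int(round(duration_s * cfg.rate))
    if m < 8:
        return np.zeros(max(m, 0))
    # piecewise-constant f0 jitter at 100 Hz control rate
    n_ctrl = m // 80 + 1
    f0 = rng.uniform(*f0_band) + np.repeat(rng.normal(0.0, jitter_hz, n_ctrl), 80)[:m]
    phase = 2.0 * np.pi * np.cumsum(f0) / cfg.rate
    sig = np.zeros(m)
    for h in range(1, cfg.n_harmonics + 1):
        sig += rolloff**h * np.sin(h * phase + rng.uniform(0.0, 2.0 * np.pi))
    sig /= math.sqrt(sum(rolloff ** (2 * h) for h in range(1, cfg.n_harmonics + 1)) / 2.0)
    tt = np.arange(m) / cfg.rate
    env = 0.55 + 0.45 * np.sin(2.0 * np.pi * syllable_hz * tt + rng.uniform(0.0, 2.0 * np.pi))
    return cfg.speech_amplitude * sig * env


def synthesize_exam_audio(label: str, seg: TestSegmentation,
                          cfg: SyntheticCohortConfig,
                          rng: np.random.Generator) -> Waveform:
    """Render a two-speaker exam waveform for one recording.

    Within each test interval the examiner and participant alternate;
    examiner acoustics are class-invariant, participant acoustics follow
    :func:`class_acoustics`. Pauses between utterances are exponential with
    mean set so the long-run pause fraction matches the class target.
    """
    acous = class_acoustics(label, cfg)
    total_s = seg.end_s + 0.5
    n = int(round(total_s * cfg.rate))
    x = rng.normal(0.0, cfg.noise_level, n)
    utt_mean = 0.5 * (cfg.utterance_s[0] + cfg.utterance_s[1])
    pf = acous["pause_fraction"]
    pause_mean = utt_mean * pf / max(1.0 - pf, 1e-6)
    for _, start, end in seg:
        t = start
        participant_turn = False  # examiner opens each test
        while t < end - 0.1:
            dur = min(rng.uniform(*cfg.utterance_s), end - t)
            if participant_turn:
                u = _utterance(dur, cfg.participant_f0, acous["jitter_hz"],
                               acous["rolloff"], acous["syllable_hz"], cfg, rng)
            else:
                u = _utterance(dur, cfg.examiner_f0, cfg.base_jitter_hz,
                               cfg.base_rolloff, cfg.base_syllable_hz, cfg, rng)
            i0 = int(round(t * cfg.rate))
            x[i0 : i0 + u.size] += u[: max(n - i0, 0)]
            t += dur + min(rng.exponential(pause_mean), 4.0 * pause_mean)
            participant_turn = not participant_turn
    return Waveform(samples=np.clip(x, -1.0, 1.0), rate=cfg.rate)


def generate_cohort(cfg: SyntheticCohortConfig = SyntheticCohortConfig(),
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate a synthetic cohort; optionally write it to disk.

    Deterministic under ``cfg.seed``. Per-recording class labels are drawn
    i.i.d. from ``class_mix`` and sorted by severity within a participant,
    so the recording-level class mix is exact in expectation while repeat
    recordings show realistic monotone progression. On-disk layout:
    ``wavs/*.wav``, ``segmentations/*.tsv``, ``timelines.csv``,
    ``manifest.csv``.
    """
    rng = np.random.default_rng(cfg.seed)
    statuses = np.array(["NC", "MCI", "DE"])
    recordings: list[SyntheticRecording] = []
    timelines: dict[str, DiagnosisTimeline] = {}
    pid_no = 0
    while len(recordings) < cfg.n_recordings:
        pid_no += 1
        pid = f"P{pid_no:04d}"
        n_rec = int(rng.choice([1, 2, 3], p=cfg.recordings_per_participant))
        n_rec = min(n_rec, cfg.n_recordings - len(recordings))
        labels = list(rng.choice(statuses, size=n_rec, p=cfg.class_mix))
        labels.sort(key=CLASS_SEVERITY.__getitem__)
        first_date = _dt.date(2012, 1, 1) + _dt.timedelta(
            days=int(rng.integers(0, 2500)))
        entries = []
        for j, label in enumerate(labels):
            rec_date = first_date + _dt.timedelta(days=365 * j)
            seg = sample_segmentation(label, cfg, rng)
            wav = (synthesize_exam_audio(label, seg, cfg, rng)
                   if cfg.synthesize_audio else None)
            rid = f"R{len(recordings) + 1:04d}"
            recordings.append(SyntheticRecording(
                recording_id=rid, participant_id=pid, recording_date=rec_date,
                label=label, segmentation=seg, waveform=wav))
            entries.append((rec_date, label))
        timelines[pid] = DiagnosisTimeline(participant_id=pid, entries=entries)
    cohort = Cohort(recordings=recordings, timelines=timelines, config=cfg)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    import yaml

    (out_dir / "wavs").mkdir(parents=True, exist_ok=True)
    (out_dir / "segmentations").mkdir(exist_ok=True)
    for r in cohort.recordings:
        if r.waveform is not None:
            write_wav(out_dir / "wavs" / f"{r.recording_id}.wav", r.waveform)
        write_segmentation(out_dir / "segmentations" / f"{r.recording_id}.tsv",
                           r.segmentation)
    write_timelines(out_dir / "timelines.csv", cohort.timelines)
    write_manifest(out_dir / "manifest.csv", cohort.manifest_records())
    snapshot = asdict(cohort.config)
    snapshot["battery"] = list(snapshot["battery"])
    (out_dir / "cohort_config.yaml").write_text(yaml.safe_dump(snapshot))


def measure_silence_fraction(w: Waveform, frame_s: float = 0.025,
                             hop_s: float = 0.010,
                             threshold: float = 0.02) -> float:
    """Energy-threshold silence detector: fraction of frames whose RMS is
    below ``threshold``. Used to verify configured pause-fraction effects."""
    win = int(round(frame_s * w.rate))
    hop = int(round(hop_s * w.rate))
    if w.samples.size < win:
        raise ValueError("Waveform shorter than one detector frame")
    from numpy.lib.stride_tricks import sliding_window_view

    frames = sliding_window_view(w.samples, win)[::hop]
    rms = np.sqrt(np.mean(frames**2, axis=1))
    return float(np.mean(rms < threshold))
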