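import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from examvoice.data_io import DiagnosisTimeline
from examvoice.evaluation import (
    FoldSplit,
    aggregate_metrics,
    assign_label,
    compute_metrics,
    cross_validate,
    duration_stats,
    extract_segment,
    is_task_member,
    make_splits,
    star_code,
)
from examvoice.features import MFCCMatrix

D0 = dt.date(2015, 1, 1)


def _tl(*entries):
    return DiagnosisTimeline(participant_id="P", entries=list(entries))


class TestAssignLabel:
    def test_diagnosis_100_days_after_is_used(self):
        tl = _tl((D0 + dt.timedelta(days=100), "DE"))
        assert assign_label(D0, tl) == "DE"

    def test_normal_beyond_180_days_counts_as_normal(self):
        tl = _tl((D0 + dt.timedelta(days=200), "NC"))
        assert assign_label(D0, tl) == "NC"

    def test_impaired_beyond_180_days_is_unlabeled(self):
        tl = _tl((D0 + dt.timedelta(days=200), "DE"))
        assert assign_label(D0, tl) == "UNLABELED"

    def test_closest_wins(self):
        tl = _tl((D0 - dt.timedelta(days=300), "NC"),
                 (D0 + dt.timedelta(days=50), "MCI"))
        assert assign_label(D0, tl) == "MCI"

    def test_equidistant_tie_prefers_on_or_before(self):
        tl = _tl((D0 - dt.timedelta(days=30), "NC"),
                 (D0 + dt.timedelta(days=30), "DE"))
        assert assign_label(D0, tl) == "NC"

    def test_empty_timeline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_label(D0, _tl())

    @settings(max_examples=100, deadline=None)
    @given(offsets=st.lists(st.integers(-1000, 1000), min_size=1, max_size=5,
                            unique=True),
           statuses=st.lists(st.sampled_from(["NC", "MCI", "DE"]),
                             min_size=5, max_size=5))
    def test_totality(self, offsets, statuses):
        tl = _tl(*[(D0 + dt.timedelta(days=o), s)
                   for o, s in zip(offsets, statuses)])
        assert assign_label(D0, tl) in {"NC", "MCI", "DE", "UNLABELED"}

    def test_task_membership(self):
        assert is_task_member("DE", "nc-vs-de") == 1
        assert is_task_member("NC", "nc-vs-de") == 0
        assert is_task_member("MCI", "nc-vs-de") is None
        assert is_task_member("MCI", "nde-vs-de") == 0
        assert is_task_member("UNLABELED", "nde-vs-de") is None


class TestSplits:
    def test_101_participants_one_held_out_balanced_folds(self):
        ids = [f"P{i}" for i in range(101)]
        split = make_splits(ids, k=5, test_fraction=1 / 101, seed=0)
        assert len(split.test_participants) == 1
        assert sorted(len(f) for f in split.folds) == [20] * 5

    def test_same_seed_identical(self):
        ids = [f"P{i}" for i in range(37)]
        a = make_splits(ids, seed=4)
        b = make_splits(ids, seed=4)
        assert a.test_participants == b.test_participants
        assert a.folds == b.folds

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(10, 60))
    def test_disjoint_and_complete(self, seed, n):
        ids = {f"P{i}" for i in range(n)}
        split = make_splits(ids, k=5, test_fraction=0.2, seed=seed)
        groups = [split.test_participants, *split.folds]
        assert set().union(*groups) == ids
        assert sum(len(g) for g in groups) == n  # pairwise disjoint

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="multiple groups"):
            FoldSplit(test_participants={"A"}, folds=[{"A"}, {"B"}])

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_splits(["a", "b", "c"], k=5, test_fraction=0.0)


class TestExtractSegment:
    def test_five_minutes_is_30000_frames(self, rng):
        m = MFCCMatrix(frames=np.zeros((73 * 6000, 13)))
        frames, flagged, start = extract_segment(m, 5, rng)
        assert frames.shape[0] == 30000
        assert not flagged
        assert 0 <= start <= 73 * 6000 - 30000

    def test_short_recording_returned_whole_with_flag(self, rng):
        m = MFCCMatrix(frames=np.zeros((1000, 13)))
        frames, flagged, _ = extract_segment(m, 5, rng)
        assert frames.shape[0] == 1000 and flagged

    def test_seeded_rng_reproducible(self):
        m = MFCCMatrix(frames=np.zeros((50000, 13)))
        starts = [extract_segment(m, 5, np.random.default_rng(11))[2]
                  for _ in range(2)]
        assert starts[0] == starts[1]


def _sweep_roc_auc(y, s):
    """Mann-Whitney formulation: independent of the step-curve integral."""
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    greater = (pos > neg).sum()
    ties = (pos == neg).sum()
    return (greater + 0.5 * ties) / (pos.size // 1 * neg.size // 1)


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(y, s)
        assert m["roc_auc"] == 1.0
        assert m["mcc"] == 1.0
        assert m["balanced_accuracy"] == 1.0

    def test_hand_computed_confusion_matrix(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        s = np.array([0.9, 0.4, 0.6, 0.3, 0.7, 0.2, 0.1])
        m = compute_metrics(y, s, threshold=0.5)
        # tp=2 fn=1 fp=1 tn=3 by inspection
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(3 / 4)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(5 / 7)
        assert m["f1"] == pytest.approx(2 / 3)
        mcc = (2 * 3 - 1 * 1) / np.sqrt(3 * 3 * 4 * 4)
        assert m["mcc"] == pytest.approx(mcc)

    def test_threshold_tie_goes_negative(self):
        m = compute_metrics([0, 1], [0.5, 0.9], threshold=0.5)
        assert m["specificity"] == 1.0

    def test_balanced_accuracy_identity_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = rng.random(n)
            m = compute_metrics(y, s)
            assert m["balanced_accuracy"] == pytest.approx(
                (m["sensitivity"] + m["specificity"]) / 2
            )
            assert m["roc_auc"] == pytest.approx(_sweep_roc_auc(y, s))
            assert -1 <= m["mcc"] <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="[Bb]oth classes"):
            compute_metrics([1, 1], [0.2, 0.9])

    def test_shuffled_labels_near_chance(self, rng):
        aucs = []
        for _ in range(60):
            y = rng.permutation([0] * 25 + [1] * 25)
            aucs.append(compute_metrics(y, rng.random(50))["roc_auc"])
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * max(se, 0.01)

    def test_aggregate_mean_sd(self):
        folds = [
            {k: v for k in
             ("accuracy", "balanced_accuracy", "sensitivity", "specificity",
              "precision", "f1", "weighted_f1", "mcc", "roc_auc", "pr_auc")}
            for v in (0.4, 0.6)
        ]
        agg = aggregate_metrics(folds)
        mean, sd = agg["roc_auc"]
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.std([0.4, 0.6], ddof=1))


class TestCrossValidate:
    def test_participant_recordings_never_split(self, rng):
        # trivially separable features so the driver runs fast at tiny size
        X = [MFCCMatrix(frames=(1.0 if i % 2 else -1.0)
                        + 0.01 * rng.normal(size=(250, 13)))
             for i in range(20)]
        y = [i % 2 for i in range(20)]
        pids = [f"P{i // 2}" for i in range(20)]  # 2 recordings each

        from examvoice.models import HierarchicalLSTM, TrainConfig

        reports = cross_validate(
            X, y, pids, lambda fi: HierarchicalLSTM(seed=fi),
            TrainConfig(epochs=1, learning_rate=1e-2, seed=0), k=5, seed=2)
        assert len(reports) == 5
        for r in reports:
            assert set(r) >= {"roc_auc", "balanced_accuracy", "mcc"}


class TestDurationStats:
    def test_identical_groups_not_significant(self):
        x = list(np.linspace(10, 20, 12))
        df = duration_stats({"BNT": {"NC": x, "MCI": x, "DE": x}})
        row = df[(df.group_a == "NC") & (df.group_b == "DE")].iloc[0]
        assert row.t_stat == pytest.approx(0.0)
        assert row.stars == "n.s."

    def test_separated_groups_highly_significant(self, rng):
        nc = 10 + 0.01 * rng.normal(size=30)
        de = 1000 + 0.01 * rng.normal(size=30)
        df = duration_stats({"BNT": {"NC": nc, "MCI": nc, "DE": de}})
        row = df[(df.group_a == "NC") & (df.group_b == "DE")].iloc[0]
        assert row.stars == "***"

    def test_matches_textbook_welch_formula(self, rng):
        a = rng.normal(5.0, 2.0, 14)
        b = rng.normal(6.0, 1.0, 9)
        df = duration_stats({"T": {"NC": a, "MCI": b, "DE": b}})
        row = df[(df.group_a == "NC") & (df.group_b == "MCI")].iloc[0]
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), dof)
        assert row.t_stat == pytest.approx(t)
        assert row.p_value == pytest.approx(p)

    def test_insufficient_n_marked(self):
        df = duration_stats({"T": {"NC": [1.0], "MCI": [2.0, 3.0],
                                   "DE": [2.0, 3.0]}})
        row = df[(df.group_a == "NC") & (df.group_b == "MCI")].iloc[0]
        assert row.stars == "n/a"

    def test_star_codes(self):
        assert star_code(0.04) == "*"
        assert star_code(0.009) == "**"
        assert star_code(0.0009) == "***"
        assert star_code(0.2) == "n.s."
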