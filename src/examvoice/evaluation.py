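"""Cohort labeling, participant-level splits, short-segment extraction,
the binary-classification metric suite, and the test-duration analysis.

Labeling applies the 180-day rule: a recording takes the status of the
closest diagnosis on/before the recording date or within 180 days after it;
if the only diagnoses are more than 180 days after and the closest of those
is NC, the recording is labeled NC; otherwise it is UNLABELED and excluded
from modeling. NDE (non-demented) is the union of NC and MCI.

Splits are drawn at the participant level — every recording of a
participant stays in that participant's fold — which prevents speaker
identity from leaking across train and test.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn import metrics as skm

from .data_io import DiagnosisTimeline
from .features import MFCCMatrix

NC, MCI, DE, UNLABELED = "NC", "MCI", "DE", "UNLABELED"
NDE_STATUSES = (NC, MCI)
WITHIN_DAYS = 180

METRIC_NAMES = ("accuracy", "balanced_accuracy", "sensitivity", "specificity",
                "precision", "f1", "weighted_f1", "mcc", "roc_auc", "pr_auc")


def assign_label(recording_date: _dt.date, tl: DiagnosisTimeline) -> str:
    """Cognitive label of a recording under the 180-day rule."""
    if isinstance(recording_date, str):
        recording_date = _dt.date.fromisoformat(recording_date)
    if not tl.entries:
        raise ValueError(f"{tl.participant_id}: empty diagnosis timeline")
    deltas = [(d - recording_date).days for d, _ in tl.entries]
    candidates = [
        (abs(delta), 0 if delta <= 0 else 1, status)
        for delta, (_, status) in zip(deltas, tl.entries)
        if delta <= WITHIN_DAYS
    ]
    if candidates:
        # ties between an on/before and an after diagnosis at equal distance
        # resolve to the on/before one (status at the time of testing)
        return min(candidates)[2]
    _, _, status = min(
        (delta, d, status) for delta, (d, status) in zip(deltas, tl.entries)
    )
    return NC if status == NC else UNLABELED


def is_task_member(label: str, task: str) -> bool | None:
    """Binary task membership: returns the class (1 = DE) or None if the
    recording is outside the task. Tasks: 'nc-vs-de', 'nde-vs-de'."""
    if label == DE:
        return 1
    if task == "nc-vs-de":
        return 0 if label == NC else None
    if task == "nde-vs-de":
        return 0 if label in NDE_STATUSES else None
    raise ValueError(f"Unknown task {task!r}")


@dataclass
class FoldSplit:
    """Participant-level partition: a held-out test set plus k CV folds."""

    test_participants: set[str]
    folds: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups = [self.test_participants, *self.folds]
        seen: set[str] = set()
        for g in groups:
            if seen & g:
                raise ValueError(
                    f"Participants appear in multiple groups: {sorted(seen & g)}"
                )
            seen |= g


def make_splits(participants: Iterable[str], k: int = 5,
                test_fraction: float = 0.2, seed: int = 0) -> FoldSplit:
    """Seeded random participant-level split into a test set and k folds.

    Folds are balanced in participant count within +/- 1.
    """
    ids = sorted(set(map(str, participants)))
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = int(round(test_fraction * len(ids)))
    test = set(order[:n_test])
    rest = order[n_test:]
    if k > len(rest):
        raise ValueError(
            f"Cannot make {k} non-empty folds from {len(rest)} participants"
        )
    folds = [set(rest[i::k]) for i in range(k)]
    return FoldSplit(test_participants=test, folds=folds)


def extract_segment(m: MFCCMatrix, length_min: float,
                    rng: np.random.Generator):
    """A contiguous random sub-sequence of ``length_min`` minutes of frames.

    Returns ``(frames, flagged, start)``; recordings shorter than the
    request yield the whole recording with ``flagged=True``.
    """
    frames = m.frames if isinstance(m, MFCCMatrix) else np.asarray(m, float)
    want = int(round(length_min * 60.0 / getattr(m, "hop_s", 0.010)))
    T = frames.shape[0]
    if T <= want:
        return frames, True, 0
    start = int(rng.integers(0, T - want + 1))
    return frames[start : start + want], False, start


def compute_metrics(y_true: Sequence[int], scores: Sequence[float],
                    threshold: float = 0.5) -> dict[str, float]:
    """Single-fold metric suite from DE-probabilities.

    Confusion-matrix metrics use ``score > threshold`` (a score exactly at
    the threshold predicts the negative class); ROC and PR AUCs integrate
    the exact step curves trapezoidally over all thresholds.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size or y.size == 0:
        raise ValueError("y_true and scores must be equal-length, non-empty")
    if np.unique(y).size < 2:
        raise ValueError("Both classes must be present to compute AUCs")
    pred = (s > threshold).astype(int)
    tn, fp, fn, tp = skm.confusion_matrix(y, pred, labels=[0, 1]).ravel()
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec, rec, _ = skm.precision_recall_curve(y, s)
    pr_auc = float(np.trapezoid(np.flip(prec), np.flip(rec)))
    return {
        "accuracy": (tp + tn) / y.size,
        "balanced_accuracy": (sens + spec) / 2.0,
        "sensitivity": sens,
        "specificity": spec,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "f1": skm.f1_score(y, pred, zero_division=0),
        "weighted_f1": skm.f1_score(y, pred, average="weighted",
                                    zero_division=0),
        "mcc": skm.matthews_corrcoef(y, pred),
        "roc_auc": skm.roc_auc_score(y, s),
        "pr_auc": pr_auc,
    }


def aggregate_metrics(folds: Sequence[Mapping[str, float]]) -> dict[str, tuple[float, float]]:
    """Mean +/- sd (sample estimator; 0 for a single fold) over folds."""
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([f[name] for f in folds], dtype=float)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[name] = (float(vals.mean()), sd)
    return out


def cross_validate(
    features: Sequence[MFCCMatrix],
    labels: Sequence[int],
    participants: Sequence[str],
    model_factory,
    train_config,
    k: int = 5,
    seed: int = 0,
) -> list[dict[str, float]]:
    """k-fold participant-level cross-validation; per-fold metric dicts.

    ``model_factory(fold_index)`` builds a fresh model per fold; training
    uses :func:`examvoice.models.train_model`.
    """
    from .models import predict_scores, train_model

    y = np.asarray(labels, dtype=int)
    pids = np.asarray([str(p) for p in participants])
    split = make_splits(pids, k=k, test_fraction=0.0, seed=seed)
    reports = []
    for fi, fold in enumerate(split.folds):
        held = np.isin(pids, sorted(fold))
        if held.all() or not held.any():
            raise ValueError(f"Fold {fi} is degenerate")
        model = model_factory(fi)
        train_model(model,
                    [features[i] for i in np.flatnonzero(~held)],
                    y[~held], train_config)
        scores = predict_scores(model, [features[i] for i in np.flatnonzero(held)])
        reports.append(compute_metrics(y[held], scores))
    return reports


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    for cut, sym in _STARS:
        if p < cut:
            return sym
    return "n.s."


def duration_stats(durations: Mapping[str, Mapping[str, Sequence[float]]],
                   welch: bool = True) -> pd.DataFrame:
    """Pairwise t-tests of per-test durations between cognitive groups.

    ``durations[test][group]`` lists observed durations (seconds); groups
    are NC, MCI, DE (NDE is derived as NC + MCI when absent). Pairs tested:
    NC-MCI, MCI-DE, NC-DE, DE-NDE. Welch's unequal-variance test by default;
    pairs with fewer than 2 observations on a side are marked
    not-computable.
    """
    pairs = [(NC, MCI), (MCI, DE), (NC, DE), (DE, "NDE")]
    rows = []
    for test, groups in durations.items():
        g = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
        if "NDE" not in g:
            g["NDE"] = np.concatenate([g.get(NC, []), g.get(MCI, [])])
        for a, b in pairs:
            xa, xb = g.get(a, np.array([])), g.get(b, np.array([]))
            row = {
                "test_name": test, "group_a": a, "group_b": b,
                "n_a": xa.size, "n_b": xb.size,
                "mean_a": xa.mean() if xa.size else np.nan,
                "sd_a": xa.std(ddof=1) if xa.size > 1 else np.nan,
                "mean_b": xb.mean() if xb.size else np.nan,
                "sd_b": xb.std(ddof=1) if xb.size > 1 else np.nan,
            }
            if xa.size >= 2 and xb.size >= 2:
                t, p = sstats.ttest_ind(xa, xb, equal_var=not welch)
                row.update(t_stat=float(t), p_value=float(p),
                           stars=star_code(float(p)))
            else:
                row.update(t_stat=np.nan, p_value=np.nan, stars="n/a")
            rows.append(row)
    return pd.DataFrame(rows)
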