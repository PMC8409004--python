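"""Temporal saliency from the CNN and salient administered fractions (SAF).

Because the CNN's classifier is linear and sits on top of a global average,
applying it position-wise to the pre-pool feature map yields a per-position
evidence track whose mean is exactly the recording-level logit. The DE row
of that track is the DE[+] saliency. Each position spans
``frames_per_position × 10 ms`` of audio (~164 s with the default seven
stride-4 reductions); the track is expanded to one value per second by
nearest-neighbor interpolation, realized as span membership: second ``s``
takes the value of the position whose temporal span contains it (clamped at
the edges).

SAF[+] of a neuropsychological test in one recording is the fraction of the
test's administered seconds whose DE[+] value is strictly positive; SAF[−]
uses the complementary condition (≤ 0), so SAF[+] + SAF[−] = 1 per test.
Cohort-level tables aggregate SAF[+] over true-positive recordings and
SAF[−] over true-negative ones; tests observed in too few recordings are
routed to a separate low-sample table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import TestSegmentation
from .features import MFCCMatrix


@dataclass
class SaliencyTrack:
    """Per-position and per-second DE[+] evidence for one recording."""

    raw: np.ndarray        # (L,) position scores; mean == DE logit
    stride_s: float        # seconds spanned per position
    per_second: np.ndarray # (ceil(duration_s),)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.per_second = np.asarray(self.per_second, dtype=np.float64)
        if self.raw.ndim != 1 or self.raw.size < 1:
            raise ValueError("raw saliency must be a non-empty 1-D vector")

    @classmethod
    def from_raw(cls, raw: np.ndarray, stride_s: float,
                 duration_s: float) -> "SaliencyTrack":
        raw = np.asarray(raw, dtype=np.float64)
        n_seconds = math.ceil(duration_s)
        idx = np.clip((np.arange(n_seconds) / stride_s).astype(int),
                      0, raw.size - 1)
        return cls(raw=raw, stride_s=stride_s, per_second=raw[idx])


def compute_saliency(model, m: MFCCMatrix, duration_s: float) -> SaliencyTrack:
    """DE[+] saliency track of one recording under a trained CNN.

    ``raw[t]`` is the DE row of the linear classifier applied to pre-pool
    feature column t, bias included — so ``mean(raw)`` equals the
    recording's DE logit exactly (up to floating point).
    """
    frames = m.frames if isinstance(m, MFCCMatrix) else np.asarray(m, float)
    hop_s = getattr(m, "hop_s", 0.010)
    span = frames.shape[0] * hop_s
    window_s = getattr(m, "window_s", 0.025)
    if abs(duration_s - span) > window_s + hop_s:
        raise ValueError(
            f"duration_s={duration_s:.3f} inconsistent with {frames.shape[0]} "
            f"frames at hop {hop_s} s (span {span:.3f} s)"
        )
    prepool = model.prepool_features(m)            # (C, L)
    w_de = model.fc_w.data[:, 1]
    b_de = model.fc_b.data[1]
    raw = w_de @ prepool + b_de
    stride_s = model.cfg.frames_per_position * hop_s
    return SaliencyTrack.from_raw(raw, stride_s, duration_s)


def saf(track: SaliencyTrack, seg: TestSegmentation,
        sign: str = "+") -> dict[str, float]:
    """Salient administered fraction per test for one recording.

    A test's seconds are the integer indices s with start <= s < end (each
    index s stands for the second [s, s+1)). SAF[+] is the fraction of those
    seconds with per-second DE[+] value > 0; SAF[-] uses <= 0.
    """
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    n = track.per_second.size
    out: dict[str, float] = {}
    for name, start, end in seg:
        lo, hi = math.ceil(start), math.ceil(end)
        if not (0 <= lo and hi <= n):
            raise ValueError(
                f"{name}: interval [{start}, {end}) outside the "
                f"{n}-second saliency track"
            )
        if hi <= lo:
            warnings.warn(f"{name}: zero-length test interval excluded")
            continue
        vals = track.per_second[lo:hi]
        positive = np.count_nonzero(vals > 0)
        out[name] = positive / vals.size if sign == "+" else 1.0 - positive / vals.size
    return out


@dataclass
class SAFTable:
    """Cohort-level SAF summary: main table plus a low-sample table.

    Both tables have columns ``test_name, saf_pos_mean, saf_pos_sd, n_pos,
    saf_neg_mean, saf_neg_sd, n_neg``. SAF[+] statistics are over true
    positives; SAF[-] over true negatives; n counts recordings containing
    the test. The sd uses the sample (n-1) estimator, reported as 0 for
    n = 1 groups.
    """

    main: pd.DataFrame
    low_n: pd.DataFrame


def _group_stats(values: list[float]) -> tuple[float, float, int]:
    n = len(values)
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def aggregate_saf(results, min_n: int = 10) -> SAFTable:
    """Aggregate per-recording SAFs into a cohort table.

    ``results`` is an iterable of ``(track, segmentation, true_label,
    predicted_label)`` with binary labels (1 = DE). Only true positives
    contribute SAF[+] and only true negatives SAF[-]; false predictions
    contribute to neither. Tests whose larger sample count is below
    ``min_n`` go to the low-sample table.
    """
    pos: dict[str, list[float]] = {}
    neg: dict[str, list[float]] = {}
    any_tp = any_tn = False
    for track, seg, y_true, y_pred in results:
        if y_true == 1 and y_pred == 1:
            any_tp = True
            for name, frac in saf(track, seg, "+").items():
                pos.setdefault(name, []).append(frac)
        elif y_true == 0 and y_pred == 0:
            any_tn = True
            for name, frac in saf(track, seg, "-").items():
                neg.setdefault(name, []).append(frac)
    if not (any_tp or any_tn):
        warnings.warn("No true-positive or true-negative recordings; "
                      "SAF table is empty")
    rows = []
    for name in sorted(set(pos) | set(neg)):
        pm, psd, np_ = _group_stats(pos.get(name, []))
        nm, nsd, nn = _group_stats(neg.get(name, []))
        rows.append((name, pm, psd, np_, nm, nsd, nn))
    cols = ["test_name", "saf_pos_mean", "saf_pos_sd", "n_pos",
            "saf_neg_mean", "saf_neg_sd", "n_neg"]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return SAFTable(main=df, low_n=df.copy())
    in_main = df[["n_pos", "n_neg"]].max(axis=1) >= min_n
    main = df[in_main].sort_values("saf_pos_mean", ascending=False,
                                   na_position="last").reset_index(drop=True)
    return SAFTable(main=main, low_n=df[~in_main].reset_index(drop=True))


def plot_saliency_map(track: SaliencyTrack, seg: TestSegmentation, ax=None):
    """Strip chart of per-second DE[+] saliency with test-interval shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2))
    n = track.per_second.size
    ax.imshow(track.per_second[None, :], aspect="auto", cmap="coolwarm",
              extent=(0, n, 0, 1))
    for i, (name, start, end) in enumerate(seg):
        ax.axvline(start, color="k", lw=0.5)
        ax.text((start + end) / 2, 1.05, name, rotation=90, fontsize=6,
                ha="center", va="bottom")
    ax.set_xlabel("seconds")
    ax.set_yticks([])
    return ax
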