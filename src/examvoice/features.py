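"""MFCC front-end: 13-dimensional acoustic features at a 10 ms hop.

The recipe, applied to 8 kHz mono audio:

1. split into 25 ms frames (200 samples) with a 10 ms stride (80 samples);
   trailing samples that do not fill a full frame are dropped;
2. per frame, the periodogram power-spectrum estimate via a 256-point DFT
   (frame zero-padded 200 -> 256), ``P[k] = |DFT(x·win)[k]|^2 / 200`` on the
   one-sided grid k = 0..128;
3. a bank of 26 triangular filters with centers evenly spaced on the Mel
   scale between 0 and 4000 Hz, ``mel(f) = 2595·log10(1 + f/700)``;
4. DCT-II (orthonormal) of the natural log of the filterbank energies;
   cepstral coefficients 2-13 (1-based) are kept, and the discarded first
   coefficient is replaced by the natural log of the frame's total energy
   (sum of squared raw samples), giving the 13-dim vector
   ``[log-energy, c2..c13]``.

Energies are floored at ``eps`` before the log so silent audio is
well-defined. The analysis window is rectangular by default (a plain
periodogram); a Hamming taper is available by config. There is no
pre-emphasis, liftering, or per-recording normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, rfft


def mel_from_hz(f):
    """Mel-scale value of a frequency in Hz."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def hz_from_mel(m):
    """Inverse Mel map."""
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@dataclass(frozen=True)
class FeatureConfig:
    rate: int = 8000
    window_ms: float = 25.0
    hop_ms: float = 10.0
    n_dft: int = 256
    n_filters: int = 26
    first_kept: int = 2   # 1-based cepstral index range kept ...
    last_kept: int = 13   # ... "2nd-13th coefficients"
    energy_substitution: bool = True
    window: str = "rectangular"  # or "hamming"
    eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_dft < self.window_samples:
            raise ValueError("n_dft must be >= window length in samples")
        if self.window not in ("rectangular", "hamming"):
            raise ValueError(f"Unknown analysis window {self.window!r}")
        if not 1 <= self.first_kept <= self.last_kept <= self.n_filters:
            raise ValueError("Kept cepstral index range is invalid")

    @property
    def window_samples(self) -> int:
        return int(round(self.rate * self.window_ms / 1000.0))

    @property
    def hop_samples(self) -> int:
        return int(round(self.rate * self.hop_ms / 1000.0))

    @property
    def n_bins(self) -> int:
        """One-sided spectrum length."""
        return self.n_dft // 2 + 1

    @property
    def n_coefficients(self) -> int:
        n_ceps = self.last_kept - self.first_kept + 1
        return n_ceps + (1 if self.energy_substitution else 0)

    @property
    def hop_s(self) -> float:
        return self.hop_ms / 1000.0

    @property
    def window_s(self) -> float:
        return self.window_ms / 1000.0

    def taper(self) -> np.ndarray:
        if self.window == "hamming":
            return np.hamming(self.window_samples)
        return np.ones(self.window_samples)


@dataclass
class MFCCMatrix:
    """Time-ordered feature vectors: column 0 is the log total frame energy,
    columns 1..12 are cepstral coefficients 2-13."""

    frames: np.ndarray  # (T, 13)
    hop_s: float = 0.010
    window_s: float = 0.025

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2:
            raise ValueError("MFCCMatrix.frames must be 2-D (T x n_coefficients)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("MFCCMatrix contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        """Span of audio the frames cover (start of first to end of last hop)."""
        return self.n_frames * self.hop_s

    def __len__(self) -> int:
        return self.n_frames


def frame_count(n_samples: int, cfg: FeatureConfig) -> int:
    """T = 1 + floor((n - window) / hop) for n >= window."""
    if n_samples < cfg.window_samples:
        raise ValueError(
            f"Waveform of {n_samples} samples is shorter than one "
            f"{cfg.window_samples}-sample analysis window"
        )
    return 1 + (n_samples - cfg.window_samples) // cfg.hop_samples


def frame_signal(w, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Split a waveform into overlapping frames, shape (T, window_samples).

    Frame t covers samples [hop·t, hop·t + window); trailing samples that do
    not fill a full frame are dropped.
    """
    x = np.asarray(getattr(w, "samples", w), dtype=np.float64)
    T = frame_count(x.size, cfg)
    view = sliding_window_view(x, cfg.window_samples)[:: cfg.hop_samples]
    return np.array(view[:T])


def periodogram(frames: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """One-sided periodogram power spectrum of each frame.

    ``P[k] = |DFT_{n_dft}(frame · taper)[k]|^2 / window_samples`` for
    k = 0..n_dft/2; the frame is zero-padded from the window length to
    ``n_dft``. Accepts a single frame or a (T, window) stack.
    """
    f = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if f.shape[-1] != cfg.window_samples:
        raise ValueError(
            f"Frames must have {cfg.window_samples} samples, got {f.shape[-1]}"
        )
    spec = rfft(f * cfg.taper(), n=cfg.n_dft, axis=-1)
    P = (spec.real**2 + spec.imag**2) / cfg.window_samples
    return P[0] if np.ndim(frames) == 1 else P


def mel_filterbank(cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Triangular Mel filterbank, shape (n_filters, n_bins).

    Filter centers sit at ``hz_from_mel(linspace(mel(0), mel(rate/2),
    n_filters + 2))[1:-1]``. Triangles are built in DFT-bin index space
    (each center mapped to ``floor((n_dft + 1) · f / rate)``) so every
    filter peaks at exactly 1 at its center bin.
    """
    edges_hz = filterbank_edges_hz(cfg)
    bins = np.floor((cfg.n_dft + 1) * edges_hz / cfg.rate).astype(int)
    M = np.zeros((cfg.n_filters, cfg.n_bins))
    k = np.arange(cfg.n_bins)
    for j in range(cfg.n_filters):
        left, center, right = bins[j], bins[j + 1], bins[j + 2]
        up = (k - left) / max(center - left, 1)
        down = (right - k) / max(right - center, 1)
        M[j] = np.clip(np.minimum(up, down), 0.0, None)
    return M


def filterbank_edges_hz(cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """The n_filters + 2 Mel-evenly-spaced edge/center frequencies in Hz."""
    mel_edges = np.linspace(
        mel_from_hz(0.0), mel_from_hz(cfg.rate / 2.0), cfg.n_filters + 2
    )
    return hz_from_mel(mel_edges)


def center_frequencies_hz(cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Center frequencies (Hz) of the triangular filters."""
    return filterbank_edges_hz(cfg)[1:-1]


def extract_mfcc(w, cfg: FeatureConfig = FeatureConfig()) -> MFCCMatrix:
    """Full featurization of a waveform into an :class:`MFCCMatrix`."""
    frames = frame_signal(w, cfg)
    P = periodogram(frames, cfg)
    energies = P @ mel_filterbank(cfg).T  # (T, n_filters)
    ceps = dct(np.log(np.maximum(energies, cfg.eps)), type=2, norm="ortho", axis=-1)
    kept = ceps[:, cfg.first_kept - 1 : cfg.last_kept]
    if cfg.energy_substitution:
        total = np.log(np.maximum(np.sum(frames**2, axis=-1), cfg.eps))
        out = np.column_stack([total, kept])
    else:
        out = kept
    return MFCCMatrix(frames=out, hop_s=cfg.hop_s, window_s=cfg.window_s)


def extract_mfcc_batch(waveforms: Iterable, cfg: FeatureConfig = FeatureConfig()):
    """Featurize an iterable of waveforms (list of MFCCMatrix)."""
    return [extract_mfcc(w, cfg) for w in waveforms]
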