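"""The two classifiers: a two-level hierarchical LSTM and a variable-length
1-D CNN with global average pooling.

Hierarchical LSTM
    MFCC vectors are grouped into non-overlapping segments of 2000 frames
    (the last segment zero-padded to a multiple of 10). Within a segment the
    low-level LSTM consumes 10 consecutive 13-dim vectors at a time as one
    130-dim step input; its last hidden state (64-dim) summarizes the
    segment. The high-level LSTM runs over the sequence of segment vectors
    to a 64-dim recording summary, followed by an MLP (64-dim hidden layer,
    ReLU) and a 2-way softmax. All initial states are zero; the two levels
    use the same hidden dimension. The hierarchy exists because hour-scale
    recordings yield hundreds of thousands of frames — far beyond what a
    single recurrence can retain.

Variable-length CNN
    Seven stacked convolutional blocks of two conv layers each (kernel 3,
    stride 1, padding 1) with ReLU, followed by max pooling (kernel 4,
    stride 4). Global average pooling collapses the remaining positions into
    one fixed-length vector regardless of input length, followed by a linear
    2-way classifier and softmax. With 7 stride-4 reductions each pre-pool
    position spans 4^7 frames = ~164 s of audio (~2.5 min); the reduction
    count is configurable (6 gives ~41 s). Inputs shorter than one position
    are right-zero-padded; in batches, a validity mask keeps padding out of
    the average.

Training uses Adam (lr 1e-4, betas (0.99, 0.999)), batch size 4, and
inverse-frequency class weights in the cross-entropy (dementia is the
minority class in the cohorts this targets). Everything is seeded: one
TrainConfig seed fans out to initialization and batch shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Adam, Tensor
from .features import MFCCMatrix

#: Default per-task/model epoch counts for the full training protocol.
DEFAULT_EPOCHS = {
    ("nc-vs-de", "lstm"): 8,
    ("nc-vs-de", "cnn"): 32,
    ("nde-vs-de", "lstm"): 32,
    ("nde-vs-de", "cnn"): 64,
}


@dataclass(frozen=True)
class LSTMConfig:
    segment_len: int = 2000      # frames per segment
    step_group: int = 10         # MFCC vectors concatenated per LSTM step
    hidden_dim: int = 64
    mlp_hidden: int = 64
    n_features: int = 13
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.segment_len % self.step_group != 0:
            raise ValueError("segment_len must be divisible by step_group")
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")

    @property
    def step_dim(self) -> int:
        return self.step_group * self.n_features


@dataclass(frozen=True)
class CNNConfig:
    n_blocks: int = 7
    convs_per_block: int = 2
    kernel: int = 3
    stride: int = 1
    padding: int = 1
    pool_kernel: int = 4
    pool_stride: int = 4
    n_pool_blocks: int = 7       # stride-4 reductions before GAP (6 or 7)
    channel_widths: tuple[int, ...] = (16, 32, 32, 64, 64, 128, 128)
    relu_per_conv: bool = True   # False: single ReLU after the block's pool
    n_features: int = 13
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.channel_widths) != self.n_blocks:
            raise ValueError("channel_widths must list one width per block")
        if self.n_pool_blocks > self.n_blocks:
            raise ValueError("n_pool_blocks cannot exceed n_blocks")

    @property
    def frames_per_position(self) -> int:
        """MFCC frames spanned by one pre-pool position (4^n_pool_blocks)."""
        return self.pool_stride**self.n_pool_blocks


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.99, 0.999)
    batch_size: int = 4
    epochs: int = 8
    seed: int = 0
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class Prediction:
    probs: np.ndarray            # over (negative class, DE)
    logits: np.ndarray
    predicted_label: int         # argmax; tie broken toward the negative class

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.logits)):
            raise FloatingPointError("Non-finite logits in prediction")


def _predict_from_logits(logits: np.ndarray) -> Prediction:
    probs = ag.softmax(logits)
    label = int(probs[1] > probs[0])  # ties go to the negative class
    return Prediction(probs=probs, logits=logits, predicted_label=label)


def segment_mfcc(m: MFCCMatrix, cfg: LSTMConfig = LSTMConfig()) -> list[np.ndarray]:
    """Group an MFCC sequence into per-segment step matrices.

    Returns ``ceil(T / segment_len)`` arrays of shape (n_steps, step_dim);
    the last segment is zero-padded to a multiple of ``step_group`` frames.
    """
    frames = m.frames if isinstance(m, MFCCMatrix) else np.asarray(m, float)
    T, d = frames.shape
    if T < 1:
        raise ValueError("Cannot segment an empty MFCC matrix")
    if d != cfg.n_features:
        raise ValueError(f"Expected {cfg.n_features}-dim features, got {d}")
    segments = []
    for start in range(0, T, cfg.segment_len):
        chunk = frames[start : start + cfg.segment_len]
        n = chunk.shape[0]
        padded = -(-n // cfg.step_group) * cfg.step_group
        if padded != n:
            chunk = np.vstack([chunk, np.zeros((padded - n, d))])
        segments.append(chunk.reshape(-1, cfg.step_dim))
    return segments


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    k = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-k, k, size=shape)


class HierarchicalLSTM:
    """Two-level LSTM over segmented MFCC sequences (see module docstring)."""

    name = "lstm"

    def __init__(self, cfg: LSTMConfig = LSTMConfig(), seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        H, D, M = cfg.hidden_dim, cfg.step_dim, cfg.mlp_hidden

        def par(shape, fan_in):
            return Tensor(_uniform(rng, shape, fan_in), requires_grad=True)

        self.low_wx = par((D, 4 * H), D)
        self.low_wh = par((H, 4 * H), H)
        self.low_b = par((4 * H,), H)
        self.high_wx = par((H, 4 * H), H)
        self.high_wh = par((H, 4 * H), H)
        self.high_b = par((4 * H,), H)
        self.mlp_w1 = par((H, M), H)
        self.mlp_b1 = par((M,), H)
        self.mlp_w2 = par((M, cfg.n_classes), M)
        self.mlp_b2 = par((cfg.n_classes,), M)
        # forget-gate bias starts at 1 (standard recurrence-stability trick)
        for b, h in ((self.low_b, H), (self.high_b, H)):
            b.data[h : 2 * h] += 1.0

    @property
    def parameters(self) -> list[Tensor]:
        return [self.low_wx, self.low_wh, self.low_b,
                self.high_wx, self.high_wh, self.high_b,
                self.mlp_w1, self.mlp_b1, self.mlp_w2, self.mlp_b2]

    def forward_batch(self, batch: Sequence[MFCCMatrix]) -> Tensor:
        """Logits (B, 2) for a batch of variable-length recordings."""
        cfg = self.cfg
        all_segments: list[np.ndarray] = []
        groups: list[list[int]] = []
        for m in batch:
            segs = segment_mfcc(m, cfg)
            groups.append(list(range(len(all_segments),
                                     len(all_segments) + len(segs))))
            all_segments.extend(segs)
        step_counts = np.array([s.shape[0] for s in all_segments])
        S = int(step_counts.max())
        X = np.zeros((len(all_segments), S, cfg.step_dim))
        for i, s in enumerate(all_segments):
            X[i, : s.shape[0]] = s
        low_out = ag.lstm_last(Tensor(X), step_counts,
                               self.low_wx, self.low_wh, self.low_b)
        seq = ag.pack_rows(low_out, groups)
        seg_counts = np.array([len(g) for g in groups])
        summary = ag.lstm_last(seq, seg_counts,
                               self.high_wx, self.high_wh, self.high_b)
        hidden = ag.relu(ag.linear(summary, self.mlp_w1, self.mlp_b1))
        logits = ag.linear(hidden, self.mlp_w2, self.mlp_b2)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("Non-finite activations in LSTM forward")
        return logits

    def predict(self, m: MFCCMatrix) -> Prediction:
        return _predict_from_logits(self.forward_batch([m]).data[0])


class VarLenCNN:
    """1-D CNN over MFCC sequences with global average pooling."""

    name = "cnn"

    def __init__(self, cfg: CNNConfig = CNNConfig(), seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.conv_w: list[Tensor] = []
        self.conv_b: list[Tensor] = []
        c_in = cfg.n_features
        for width in cfg.channel_widths:
            for _ in range(cfg.convs_per_block):
                fan = c_in * cfg.kernel
                # He init: preserves activation scale through deep ReLU stacks
                self.conv_w.append(
                    Tensor(rng.normal(0.0, np.sqrt(2.0 / fan),
                                      (width, c_in, cfg.kernel)),
                           requires_grad=True))
                self.conv_b.append(
                    Tensor(np.zeros(width), requires_grad=True))
                c_in = width
        self.fc_w = Tensor(_uniform(rng, (c_in, cfg.n_classes), c_in),
                           requires_grad=True)
        self.fc_b = Tensor(_uniform(rng, (cfg.n_classes,), c_in),
                           requires_grad=True)

    @property
    def parameters(self) -> list[Tensor]:
        return [*self.conv_w, *self.conv_b, self.fc_w, self.fc_b]

    def _pad_batch(self, batch: Sequence[MFCCMatrix]):
        """Right-zero-pad features to a common multiple of frames_per_position.

        Returns (B, 13, Lmax*fpp) array, per-recording position counts, and
        the (B, Lmax) validity mask. A recording of T frames owns
        ``max(1, T // fpp)`` positions; a trailing remainder not filling a
        full position is dropped (it is covered by padding instead).
        """
        fpp = self.cfg.frames_per_position
        mats = [m.frames if isinstance(m, MFCCMatrix) else np.asarray(m, float)
                for m in batch]
        if any(m.shape[0] < 1 for m in mats):
            raise ValueError("Cannot run the CNN on an empty MFCC matrix")
        n_pos = np.array([max(1, m.shape[0] // fpp) for m in mats])
        Lmax = int(n_pos.max())
        X = np.zeros((len(mats), self.cfg.n_features, Lmax * fpp))
        for i, m in enumerate(mats):
            t = min(m.shape[0], Lmax * fpp)
            X[i, :, :t] = m[:t].T
        mask = np.zeros((len(mats), Lmax))
        for i, n in enumerate(n_pos):
            mask[i, :n] = 1.0
        return X, n_pos, mask

    def _stem(self, x: Tensor) -> Tensor:
        """Convolutional stem: (B, 13, L) -> pre-pool features (B, C, L')."""
        cfg = self.cfg
        li = 0
        for block in range(cfg.n_blocks):
            for _ in range(cfg.convs_per_block):
                x = ag.conv1d(x, self.conv_w[li], self.conv_b[li],
                              padding=cfg.padding)
                li += 1
                if cfg.relu_per_conv:
                    x = ag.relu(x)
            if block < cfg.n_pool_blocks:
                x = ag.maxpool1d(x, cfg.pool_kernel, cfg.pool_stride)
            if not cfg.relu_per_conv:
                x = ag.relu(x)
        return x

    def forward_batch(self, batch: Sequence[MFCCMatrix],
                      return_prepool: bool = False):
        X, n_pos, mask = self._pad_batch(batch)
        prepool = self._stem(Tensor(X))
        pooled = ag.global_average_pool(prepool, mask)
        logits = ag.linear(pooled, self.fc_w, self.fc_b)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("Non-finite activations in CNN forward")
        if return_prepool:
            return logits, prepool, n_pos
        return logits

    def predict(self, m: MFCCMatrix) -> Prediction:
        return _predict_from_logits(self.forward_batch([m]).data[0])

    def prepool_features(self, m: MFCCMatrix) -> np.ndarray:
        """Pre-GAP feature map (C, L) for one recording (no padding beyond
        the single-position minimum)."""
        _, prepool, n_pos = self.forward_batch([m], return_prepool=True)
        return prepool.data[0, :, : n_pos[0]]


def lstm_forward(m: MFCCMatrix, model: HierarchicalLSTM) -> Prediction:
    return model.predict(m)


def cnn_forward(m: MFCCMatrix, model: VarLenCNN):
    """Prediction plus the pre-pool feature matrix (L, C)."""
    logits, prepool, n_pos = model.forward_batch([m], return_prepool=True)
    pred = _predict_from_logits(logits.data[0])
    return pred, prepool.data[0, :, : n_pos[0]].T


def train_model(
    model,
    cohort: Sequence[MFCCMatrix],
    labels: Sequence[int],
    tc: TrainConfig = TrainConfig(),
) -> list[float]:
    """Train a model in place; returns the per-epoch mean training loss.

    Minimizes class-weighted softmax cross-entropy with Adam over shuffled
    mini-batches of variable-length recordings. Deterministic given
    ``tc.seed`` (which also drives the shuffle order).
    """
    y = np.asarray(labels, dtype=int)
    if len(cohort) != y.size:
        raise ValueError("cohort and labels must have equal length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("Training set must contain at least 2 classes")
    if tc.class_weighting:
        weight_by_class = {c: y.size / (classes.size * n)
                           for c, n in zip(classes, counts)}
    else:
        weight_by_class = {c: 1.0 for c in classes}
    sample_w = np.array([weight_by_class[c] for c in y])

    opt = Adam(model.parameters, lr=tc.learning_rate, betas=tc.betas)
    rng = np.random.default_rng(tc.seed)
    trace: list[float] = []
    for _ in range(tc.epochs):
        order = rng.permutation(y.size)
        losses = []
        for lo in range(0, y.size, tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            logits = model.forward_batch([cohort[i] for i in idx])
            loss = ag.softmax_cross_entropy(logits, y[idx], sample_w[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return trace


def predict_scores(model, cohort: Sequence[MFCCMatrix],
                   batch_size: int = 8) -> np.ndarray:
    """DE-class probabilities for a list of recordings."""
    out = []
    for lo in range(0, len(cohort), batch_size):
        logits = model.forward_batch(list(cohort[lo : lo + batch_size]))
        out.append(ag.softmax(logits.data)[:, 1])
    return np.concatenate(out) if out else np.array([])
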