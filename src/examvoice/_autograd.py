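"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the tensor engine behind the two classifiers. It is intentionally
small: a handful of primitive ops (linear algebra, pointwise nonlinearities)
plus fused ops with hand-written backward passes for the expensive pieces —
the LSTM recurrence (vectorized truncated-at-length BPTT), 1-D convolution
(im2col), max pooling, masked global average pooling, and a weighted softmax
cross-entropy. Keeping the network math in NumPy makes the package
dependency-light and fully deterministic on CPU.

Conventions: float64 throughout; gradients accumulate into ``Tensor.grad``;
``backward()`` topologically sorts the graph and seeds the output gradient
with ones.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward: Callable[[np.ndarray], None] | None = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, _needs(a, b), (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, _needs(a, b), (a, b), bwd)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x @ w + b for 2-D x."""
    return add(matmul(x, w), b)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, x.requires_grad, (x,), bwd)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_last(
    x: Tensor,
    lengths: np.ndarray,
    wx: Tensor,
    wh: Tensor,
    b: Tensor,
) -> Tensor:
    """Run an LSTM over (N, T, D) inputs; return the hidden state at each
    sequence's true length (N, H). Initial hidden and cell states are zero.

    Gate order in the fused weight matrices is (input, forget, cell, output).
    Steps past a sequence's length never influence its output, so their
    gradient is exactly zero; the recurrence is still computed over the full
    padded length for vectorization.
    """
    X = x.data
    N, T, D = X.shape
    H = wh.data.shape[0]
    lengths = np.asarray(lengths, dtype=int)
    if np.any(lengths < 1) or np.any(lengths > T):
        raise ValueError("lengths must be in [1, T]")

    Wx, Wh, bias = wx.data, wh.data, b.data
    xp = X.reshape(N * T, D) @ Wx  # precomputed input projections
    xp = xp.reshape(N, T, 4 * H) + bias

    i_s = np.empty((T, N, H)); f_s = np.empty((T, N, H))
    g_s = np.empty((T, N, H)); o_s = np.empty((T, N, H))
    c_s = np.empty((T, N, H)); tc_s = np.empty((T, N, H))
    h_s = np.empty((T, N, H))
    h = np.zeros((N, H)); c = np.zeros((N, H))
    for t in range(T):
        z = xp[:, t, :] + h @ Wh
        i = _sigmoid(z[:, :H]); f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H]); o = _sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        i_s[t] = i; f_s[t] = f; g_s[t] = g; o_s[t] = o
        c_s[t] = c; tc_s[t] = tc; h_s[t] = h

    out_data = h_s[lengths - 1, np.arange(N)]

    def bwd(gout):
        dWx = np.zeros_like(Wx); dWh = np.zeros_like(Wh); db = np.zeros_like(bias)
        dX = np.zeros_like(X) if x.requires_grad else None
        dh = np.zeros((N, H)); dc = np.zeros((N, H))
        for t in range(T - 1, -1, -1):
            at_end = lengths - 1 == t
            if np.any(at_end):
                dh = dh + gout * at_end[:, None]
            i, f, g, o = i_s[t], f_s[t], g_s[t], o_s[t]
            tc = tc_s[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            c_prev = c_s[t - 1] if t > 0 else np.zeros((N, H))
            df = dc * c_prev
            dpre = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            h_prev = h_s[t - 1] if t > 0 else np.zeros((N, H))
            dWx += X[:, t, :].T @ dpre
            dWh += h_prev.T @ dpre
            db += dpre.sum(axis=0)
            if dX is not None:
                dX[:, t, :] = dpre @ Wx.T
            dh = dpre @ Wh.T
            dc = dc * f
        if wx.requires_grad:
            wx._accumulate(dWx)
        if wh.requires_grad:
            wh._accumulate(dWh)
        if b.requires_grad:
            b._accumulate(db)
        if dX is not None:
            x._accumulate(dX)

    return Tensor(out_data, _needs(x, wx, wh, b), (x, wx, wh, b), bwd)


def pack_rows(x: Tensor, groups: Sequence[Sequence[int]], pad_to: int | None = None) -> Tensor:
    """Gather rows of (N, H) into a padded (B, S, H) batch; zero padding.

    ``groups[b]`` lists the row indices forming sequence b, in order.
    """
    N, H = x.data.shape
    S = pad_to if pad_to is not None else max(len(g) for g in groups)
    B = len(groups)
    out_data = np.zeros((B, S, H))
    for bi, g in enumerate(groups):
        out_data[bi, : len(g)] = x.data[list(g)]

    def bwd(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for bi, grp in enumerate(groups):
                dx[list(grp)] += g[bi, : len(grp)]
            x._accumulate(dx)

    return Tensor(out_data, x.requires_grad, (x,), bwd)


def conv1d(x: Tensor, w: Tensor, b: Tensor, padding: int = 1) -> Tensor:
    """1-D convolution, stride 1: x (B, C, L), w (Cout, Cin, K), b (Cout,).

    With K = 3 and padding 1 the length is preserved.
    """
    B, C, L = x.data.shape
    Cout, Cin, K = w.data.shape
    if Cin != C:
        raise ValueError(f"Channel mismatch: input {C}, weight expects {Cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    Lout = L + 2 * padding - K + 1
    # (B, C, Lout, K) windows -> (B*Lout, C*K) columns
    cols = sliding_window_view(xp, K, axis=2)
    cols = cols.transpose(0, 2, 1, 3).reshape(B * Lout, C * K)
    Wm = w.data.reshape(Cout, C * K).T
    out = (cols @ Wm + b.data).reshape(B, Lout, Cout).transpose(0, 2, 1)

    def bwd(g):
        gm = g.transpose(0, 2, 1).reshape(B * Lout, Cout)
        if w.requires_grad:
            w._accumulate((cols.T @ gm).T.reshape(Cout, C, K))
        if b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ Wm.T).reshape(B, Lout, C, K)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, :, k : k + Lout] += dcols[:, :, :, k].transpose(0, 2, 1)
            x._accumulate(dxp[:, :, padding : padding + L])

    return Tensor(out, _needs(x, w, b), (x, w, b), bwd)


def maxpool1d(x: Tensor, kernel: int = 4, stride: int = 4) -> Tensor:
    """Non-overlapping max pooling (kernel == stride); remainder dropped."""
    if kernel != stride:
        raise NotImplementedError("Only kernel == stride pooling is supported")
    B, C, L = x.data.shape
    Lout = L // kernel
    if Lout == 0:
        raise ValueError(f"Input length {L} shorter than pooling kernel {kernel}")
    xr = x.data[:, :, : Lout * kernel].reshape(B, C, Lout, kernel)
    arg = xr.argmax(axis=3)
    out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]

    def bwd(g):
        if x.requires_grad:
            dxr = np.zeros((B, C, Lout, kernel))
            np.put_along_axis(dxr, arg[..., None], g[..., None], axis=3)
            dx = np.zeros_like(x.data)
            dx[:, :, : Lout * kernel] = dxr.reshape(B, C, Lout * kernel)
            x._accumulate(dx)

    return Tensor(out, x.requires_grad, (x,), bwd)


def global_average_pool(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Average (B, C, L) over temporal positions -> (B, C).

    ``mask`` (B, L) restricts the average to valid (un-padded) positions.
    """
    B, C, L = x.data.shape
    if mask is None:
        mask = np.ones((B, L))
    mask = np.asarray(mask, dtype=np.float64)
    counts = mask.sum(axis=1)
    if np.any(counts < 1):
        raise ValueError("Every sequence needs at least one valid position")
    out = (x.data * mask[:, None, :]).sum(axis=2) / counts[:, None]

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[:, :, None] * mask[:, None, :] / counts[:, None, None])

    return Tensor(out, x.requires_grad, (x,), bwd)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, sample_weights: np.ndarray | None = None
) -> Tensor:
    """Weighted-mean softmax cross-entropy over a batch of 2-class logits."""
    y = np.asarray(labels, dtype=int)
    B = y.size
    w = np.ones(B) if sample_weights is None else np.asarray(sample_weights, float)
    wsum = w.sum()
    p = softmax(logits.data)
    loss = -(w * np.log(np.maximum(p[np.arange(B), y], 1e-300))).sum() / wsum

    def bwd(g):
        if logits.requires_grad:
            dlog = p.copy()
            dlog[np.arange(B), y] -= 1.0
            logits._accumulate(g * dlog * (w / wsum)[:, None])

    return Tensor(loss, logits.requires_grad, (logits,), bwd)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.99, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
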