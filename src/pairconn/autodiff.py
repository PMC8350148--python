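"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the connectivity network are implemented:
dense linear maps, 1-D convolution/pooling, elementwise nonlinearities,
a handful of structured reshuffles (pairwise concatenation, off-diagonal
row sums, row scaling) and fused masked losses.  Gradients of every op
are exercised against central finite differences in the test suite.

Tensors hold float64 data by default (float32 inputs are preserved,
and every op keeps its input dtype); the graph is a DAG of `Tensor` nodes and
`Tensor.backward()` runs a topological sweep accumulating `.grad`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        # float32 inputs stay float32 (all ops preserve dtype); anything
        # else is promoted to float64
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def matmul(self, other: "Tensor") -> "Tensor":
        out = _node(self.data @ other.data, (self, other))

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def affine(self, scale: float, shift: float) -> "Tensor":
        """scale * t + shift with python-scalar coefficients."""
        out = _node(scale * self.data + shift, (self,))
        out._backward = lambda g: self._accumulate(scale * g)
        return out

    # -- shape ops -----------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def sum(self) -> "Tensor":
        out = _node(self.data.sum(), (self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = _node(self.data.mean(), (self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g / n, self.data.shape).copy())
        return out

    # -- nonlinearities ------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = _node(np.where(mask, self.data, 0.0), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)
        out = _node(s, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out


class Parameter(Tensor):
    """A leaf tensor that always receives gradient."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _node(data, parents):
    t = Tensor(data)
    t._parents = tuple(parents)
    return t


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Reduce gradient g to `shape` by summing the broadcast axes."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------


def linear(x: Tensor, weight: Parameter, bias: Parameter) -> Tensor:
    """x (M, in) @ weight.T (in, out) + bias (out,)."""
    out = _node(x.data @ weight.data.T + bias.data, (x, weight, bias))

    def bwd(g):
        x._accumulate(g @ weight.data)
        weight._accumulate(g.T @ x.data)
        bias._accumulate(g.sum(axis=0))

    out._backward = bwd
    return out


def conv1d(x: Tensor, weight: Parameter, bias: Parameter, pad: int = 1) -> Tensor:
    """Cross-correlation, stride 1, via im2col + batched GEMM.

    x (M,C,L), weight (O,C,k), bias (O,).
    """
    M, C, L_in = x.data.shape
    O, _, k = weight.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (M,C,Lo,k)
    Lo = win.shape[2]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(M, Lo, C * k)
    W2 = weight.data.reshape(O, C * k)
    y = cols @ W2.T                                  # (M,Lo,O)
    y = y.transpose(0, 2, 1) + bias.data[None, :, None]
    out = _node(np.ascontiguousarray(y), (x, weight, bias))

    def bwd(g):
        # g: (M,O,Lo)
        bias._accumulate(g.sum(axis=(0, 2)))
        gt = np.ascontiguousarray(g.transpose(0, 2, 1))            # (M,Lo,O)
        gw = gt.reshape(M * Lo, O).T @ cols.reshape(M * Lo, C * k)
        weight._accumulate(gw.reshape(O, C, k))
        dcols = (gt @ W2).reshape(M, Lo, C, k).transpose(0, 2, 1, 3)  # (M,C,Lo,k)
        dxp = np.zeros((M, C, L_in + 2 * pad), dtype=x.data.dtype)
        for t in range(k):
            dxp[:, :, t:t + Lo] += dcols[:, :, :, t]
        x._accumulate(dxp[:, :, pad:pad + L_in])

    out._backward = bwd
    return out


def maxpool1d(x: Tensor) -> Tensor:
    """Kernel 2, stride 2; a trailing odd sample is dropped."""
    M, C, L = x.data.shape
    Lo = L // 2
    if Lo < 1:
        raise ValueError(f"sequence of length {L} too short for 2x max-pooling")
    xr = x.data[:, :, : 2 * Lo].reshape(M, C, Lo, 2)
    idx = xr.argmax(axis=3)
    out = _node(np.take_along_axis(xr, idx[..., None], axis=3)[..., 0], (x,))

    def bwd(g):
        dx = np.zeros_like(x.data)
        dxr = dx[:, :, : 2 * Lo].reshape(M, C, Lo, 2)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=3)
        x._accumulate(dx)

    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when p == 0."""
    if p <= 0.0:
        return x
    keep = ((rng.random(x.data.shape) >= p) / (1.0 - p)).astype(x.data.dtype)
    out = _node(x.data * keep, (x,))
    out._backward = lambda g: x._accumulate(g * keep)
    return out


def pairwise_concat(emb: Tensor) -> Tensor:
    """(B,N,d) -> (B,N,N,2d) with out[b,i,j] = [emb[b,i], emb[b,j]]."""
    B, N, d = emb.data.shape
    left = np.broadcast_to(emb.data[:, :, None, :], (B, N, N, d))
    right = np.broadcast_to(emb.data[:, None, :, :], (B, N, N, d))
    out = _node(np.concatenate([left, right], axis=3), (emb,))

    def bwd(g):
        emb._accumulate(g[:, :, :, :d].sum(axis=2) + g[:, :, :, d:].sum(axis=1))

    out._backward = bwd
    return out


def offdiag_row_sum(K: Tensor) -> Tensor:
    """(B,N,N) -> (B,N): sum_j K[b,i,j] for j != i."""
    B, N, _ = K.data.shape
    diag = np.diagonal(K.data, axis1=1, axis2=2)
    out = _node(K.data.sum(axis=2) - diag, (K,))

    def bwd(g):
        gK = np.repeat(g[:, :, None], N, axis=2).astype(K.data.dtype)
        ii = np.arange(N)
        gK[:, ii, ii] = 0.0
        K._accumulate(gK)

    out._backward = bwd
    return out


def scale_rows(emb: Tensor, w: Tensor) -> Tensor:
    """(B,N,d) scaled per-row by w (B,N)."""
    out = _node(emb.data * w.data[:, :, None], (emb, w))

    def bwd(g):
        emb._accumulate(g * w.data[:, :, None])
        w._accumulate((g * emb.data).sum(axis=2))

    out._backward = bwd
    return out


def masked_weighted_bce_with_logits(logits: Tensor, targets, mask, pos_weight) -> Tensor:
    """Mean over observed entries of class-weighted BCE with logits.

    targets/mask broadcast to logits' shape; pos_weight multiplies the
    positive-label term only.  Raises if no entry is observed.
    """
    dt = logits.data.dtype
    y = np.broadcast_to(np.asarray(targets, dtype=dt), logits.data.shape)
    m = np.broadcast_to(np.asarray(mask, dtype=dt), logits.data.shape)
    w = np.broadcast_to(np.asarray(pos_weight, dtype=dt), logits.data.shape)
    denom = m.sum()
    if denom == 0:
        raise ValueError("all labels masked: loss undefined")
    x = logits.data
    # stable softplus
    sp_negx = np.logaddexp(0.0, -x)   # -log sigmoid(x)
    sp_posx = np.logaddexp(0.0, x)    # -log(1 - sigmoid(x))
    per = w * y * sp_negx + (1.0 - y) * sp_posx
    out = _node((per * m).sum() / denom, (logits,))

    def bwd(g):
        s = _sigmoid(x)
        dx = (w * y * (s - 1.0) + (1.0 - y) * s) * m / denom
        logits._accumulate(g * dx)

    out._backward = bwd
    return out


def masked_mse(pred: Tensor, targets, mask) -> Tensor:
    """Mean squared error over observed entries."""
    dt = pred.data.dtype
    t = np.broadcast_to(np.asarray(targets, dtype=dt), pred.data.shape)
    m = np.broadcast_to(np.asarray(mask, dtype=dt), pred.data.shape)
    denom = m.sum()
    if denom == 0:
        raise ValueError("all targets masked: loss undefined")
    r = pred.data - t
    out = _node((m * r * r).sum() / denom, (pred,))
    out._backward = lambda g: pred._accumulate(g * 2.0 * m * r / denom)
    return out
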