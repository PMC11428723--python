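"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module powers the registration networks: 3-D convolution (im2col +
BLAS), pooling, trilinear resizing, trilinear grid sampling of images and
fields by a displacement (the spatial transformer), activations, and the two
training losses with analytic adjoints.  It is deliberately small: only the
operations the stepwise registration cascade needs, each with a hand-written
backward pass that is verified against finite differences in the test suite.

Tensors carry a ``requires_grad`` flag; gradients are only propagated into
subgraphs that need them, so constant inputs (images, masks) cost nothing at
backward time.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .losses import ncc_terms, _box


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _acc(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = np.asarray(g).astype(t.data.dtype, copy=False)  # keep float32 graphs float32
    t.grad = g if t.grad is None else t.grad + g


def constant(x) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=True)


def _node(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents),
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# Elementwise and structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        _acc(a, g)
        _acc(b, g)

    return _node(out_data, (a, b), bw)


def scale(a: Tensor, s: float) -> Tensor:
    def bw(g):
        _acc(a, g * s)

    return _node(a.data * s, (a,), bw)


def mul_const(a: Tensor, c: np.ndarray) -> Tensor:
    c = np.asarray(c)

    def bw(g):
        _acc(a, g * c)

    return _node(a.data * c, (a,), bw)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, alpha * x.data)

    def bw(g):
        _acc(x, np.where(pos, g, alpha * g))

    return _node(out, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        _acc(x, g * out * (1.0 - out))

    return _node(out, (x,), bw)


def maximum_const(x: Tensor, c: np.ndarray) -> Tensor:
    """Elementwise max with a constant array; gradient flows where x wins."""
    c = np.asarray(c, dtype=x.data.dtype)
    win = x.data > c
    out = np.where(win, x.data, c)

    def bw(g):
        _acc(x, np.where(win, g, 0.0))

    return _node(out, (x,), bw)


def clamped_add_const(x: Tensor, c: np.ndarray, hi: float = 1.0) -> Tensor:
    """min(x + c, hi) — the alternative attention-combination rule."""
    c = np.asarray(c, dtype=x.data.dtype)
    s = x.data + c
    under = s < hi
    out = np.where(under, s, hi)

    def bw(g):
        _acc(x, np.where(under, g, 0.0))

    return _node(out, (x,), bw)


def concat_channels(parts: Sequence[Tensor]) -> Tensor:
    out = np.concatenate([p.data for p in parts], axis=0)
    sizes = [p.data.shape[0] for p in parts]

    def bw(g):
        off = 0
        for p, s in zip(parts, sizes):
            _acc(p, g[off:off + s])
            off += s

    return _node(out, tuple(parts), bw)


# ---------------------------------------------------------------------------
# Convolution / pooling / resizing
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, L, W, D) -> (C*k^3, L*W*D) patch matrix, 'same' zero padding.

    Built by k^3 strided slice assignments, which is far cheaper than
    materializing a sliding-window view.
    """
    r = k // 2
    C, L, W, D = x.shape
    xp = np.pad(x, ((0, 0), (r, r), (r, r), (r, r)))
    cols = np.empty((C, k ** 3, L, W, D), dtype=x.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            for dl in range(k):
                cols[:, idx] = xp[:, di:di + L, dj:dj + W, dl:dl + D]
                idx += 1
    return cols.reshape(C * k ** 3, L * W * D)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' zero-padded stride-1 cross-correlation.

    x: (Cin, L, W, D); w: (Cout, Cin, k, k, k); b: (Cout,).
    """
    Cout, Cin, k, _, _ = w.data.shape
    _, L, W, D = x.data.shape
    cols = _im2col(x.data, k)
    y = w.data.reshape(Cout, -1) @ cols + b.data[:, None]
    out = y.reshape(Cout, L, W, D)

    def bw(g):
        gf = g.reshape(Cout, -1)
        if w.requires_grad:
            _acc(w, (gf @ cols.T).reshape(w.data.shape))
        if b.requires_grad:
            _acc(b, gf.sum(axis=1))
        if x.requires_grad:
            wt = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4).reshape(Cin, -1)
            gcols = _im2col(np.ascontiguousarray(g), k)
            _acc(x, (wt @ gcols).reshape(Cin, L, W, D))

    return _node(out, (x, w, b), bw)


def avg_pool3d(x: Tensor, f: int = 2) -> Tensor:
    C, L, W, D = x.data.shape
    if L % f or W % f or D % f:
        raise ValueError(f"spatial dims {x.data.shape[1:]} not divisible by {f}")
    out = x.data.reshape(C, L // f, f, W // f, f, D // f, f).mean(axis=(2, 4, 6))

    def bw(g):
        gx = np.repeat(np.repeat(np.repeat(g, f, axis=1), f, axis=2), f, axis=3)
        _acc(x, gx / f ** 3)

    return _node(out, (x,), bw)


def _resize_positions(src_shape, tgt_shape) -> np.ndarray:
    axes = []
    for s, t in zip(src_shape, tgt_shape):
        axes.append(np.linspace(0.0, s - 1.0, t) if t > 1 else np.array([(s - 1) / 2.0]))
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid])


class _TriCache:
    """Cached corner indices/weights for one trilinear sampling pattern."""

    __slots__ = ("shape", "lin", "wgt", "frac_live", "n", "_ts")

    def __init__(self, shape, pos: np.ndarray):
        L, W, D = shape
        self.shape = shape
        self.n = pos.shape[1]
        i0s, ts, lives = [], [], []
        for a, S in enumerate(shape):
            p = np.clip(pos[a], 0.0, S - 1.0)
            if S > 1:
                i0 = np.minimum(np.floor(p).astype(np.int64), S - 2)
            else:
                i0 = np.zeros(self.n, dtype=np.int64)
            t = p - i0
            live = (pos[a] > 0.0) & (pos[a] < S - 1.0)  # clamp kills the derivative
            i0s.append(i0)
            ts.append(t)
            lives.append(live)
        self.frac_live = lives
        self.lin = []
        self.wgt = []
        tx, ty, tz = ts
        wx = (1.0 - tx, tx)
        wy = (1.0 - ty, ty)
        wz = (1.0 - tz, tz)
        self._ts = ts  # kept for disp gradients
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ix = np.minimum(i0s[0] + dx, L - 1)
                    iy = np.minimum(i0s[1] + dy, W - 1)
                    iz = np.minimum(i0s[2] + dz, D - 1)
                    self.lin.append((ix * W + iy) * D + iz)
                    self.wgt.append(wx[dx] * wy[dy] * wz[dz])

    def gather(self, vol_flat: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """vol_flat: (C, L*W*D) -> (C, n) interpolated values + corner values."""
        dt = vol_flat.dtype
        corners = [vol_flat[:, l] for l in self.lin]
        out = np.zeros_like(corners[0])
        for v, w in zip(corners, self.wgt):
            out += v * w.astype(dt, copy=False)
        return out, corners

    def scatter(self, g: np.ndarray) -> np.ndarray:
        """Adjoint of gather w.r.t. the sampled volume; g: (C, n)."""
        C = g.shape[0]
        size = int(np.prod(self.shape))
        out = np.zeros((C, size))
        for l, w in zip(self.lin, self.wgt):
            gw = g * w.astype(g.dtype, copy=False)
            for c in range(C):
                out[c] += np.bincount(l, weights=gw[c], minlength=size)
        return out.astype(g.dtype, copy=False)

    def disp_grad(self, g: np.ndarray, corners: list[np.ndarray]) -> np.ndarray:
        """Adjoint w.r.t. the sample positions; returns (3, n) summed over C."""
        tx, ty, tz = self._ts
        wx = (1.0 - tx, tx)
        wy = (1.0 - ty, ty)
        wz = (1.0 - tz, tz)
        gpos = np.zeros((3, self.n))
        i = 0
        for dx in (0, 1):
            sx = 1.0 if dx else -1.0
            for dy in (0, 1):
                sy = 1.0 if dy else -1.0
                for dz in (0, 1):
                    sz = 1.0 if dz else -1.0
                    gc = (g * corners[i]).sum(axis=0)  # sum over channels
                    gpos[0] += gc * sx * wy[dy] * wz[dz]
                    gpos[1] += gc * wx[dx] * sy * wz[dz]
                    gpos[2] += gc * wx[dx] * wy[dy] * sz
                    i += 1
        for a in range(3):
            gpos[a] *= self.frac_live[a]
        return gpos


def resize_trilinear(x: Tensor, target_shape: Sequence[int]) -> Tensor:
    """Corner-aligned trilinear resize of a (C, L, W, D) tensor."""
    C = x.data.shape[0]
    src = x.data.shape[1:]
    tgt = tuple(int(t) for t in target_shape)
    pos = _resize_positions(src, tgt)
    cache = _TriCache(src, pos)
    out, _ = cache.gather(x.data.reshape(C, -1))
    out = out.reshape((C, *tgt))

    def bw(g):
        _acc(x, cache.scatter(g.reshape(C, -1)).reshape(x.data.shape))

    return _node(out, (x,), bw)


def grid_sample(vol: Tensor, disp: Tensor) -> Tensor:
    """Spatial transformer: out(x) = vol(x + u(x)), trilinear, border clamp.

    vol: (C, L, W, D) tensor (constant image or a field being composed);
    disp: (3, L, W, D) displacement in voxel units of the same grid.
    Differentiable w.r.t. both arguments.
    """
    C = vol.data.shape[0]
    shape = vol.data.shape[1:]
    if disp.data.shape != (3, *shape):
        raise ValueError("displacement shape mismatch")
    axes = [np.arange(s, dtype=np.float64) for s in shape]
    base = np.stack(np.meshgrid(*axes, indexing="ij")).reshape(3, -1)
    pos = base + disp.data.reshape(3, -1)
    cache = _TriCache(shape, pos)
    vol_flat = vol.data.reshape(C, -1)
    out, corners = cache.gather(vol_flat)
    out = out.reshape(vol.data.shape)

    def bw(g):
        gf = g.reshape(C, -1)
        if vol.requires_grad:
            _acc(vol, cache.scatter(gf).reshape(vol.data.shape))
        if disp.requires_grad:
            _acc(disp, cache.disp_grad(gf, corners).reshape(disp.data.shape))

    return _node(out, (vol, disp), bw)


def compose_fields(outer: Tensor, inner: Tensor) -> Tensor:
    """c(x) = inner(x) + outer(x + inner(x)); both (3, L, W, D) tensors."""
    return add(inner, grid_sample(outer, inner))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def masked_ncc_loss(fixed: np.ndarray, warped: Tensor, mask: np.ndarray | None,
                    window: int, eps: float = 1e-5,
                    variant: str = "squared") -> Tensor:
    """Similarity term: -(sum cc * (1-mask)) / count(1-mask), analytic adjoint.

    ``fixed`` and ``mask`` are constants; only the warped image receives a
    gradient.  The forward value matches :func:`stepreg.losses.similarity_loss`
    for the same NCC variant.
    """
    f = np.asarray(fixed, dtype=np.float64)
    w = warped.data.astype(np.float64)
    if mask is None:
        keep = np.ones(f.shape)
    else:
        keep = 1.0 - np.asarray(mask, dtype=np.float64)
    n_keep = keep.sum()
    if n_keep == 0:
        return _node(np.asarray(0.0), (warped,), lambda g: None)
    cc, cross, varf, varw, fbar, wbar = ncc_terms(f, w, window, eps, variant)
    loss = -(cc * keep).sum() / n_keep

    def bw(g):
        if not warped.requires_grad:
            return
        m = keep / n_keep
        denom = varf * varw + eps
        if variant == "squared":
            # d(cc^2)/dw(y) summed over window centers, see ncc_terms
            a = 2.0 * m * cross / denom
            b = 2.0 * m * cc * varf / denom
        else:
            # cc = cross * denom^{-1/2}
            rt = np.sqrt(denom)
            a = m / rt
            b = m * cross * varf / (denom * rt)
        grad = -(f * _box(a, window) - _box(a * fbar, window)
                 - w * _box(b, window) + _box(b * wbar, window))
        _acc(warped, float(g) * grad.astype(warped.data.dtype))

    return _node(np.asarray(loss), (warped,), bw)


def gradient_l2_loss(field: Tensor) -> Tensor:
    """Smoothness term; forward value matches :func:`stepreg.losses.smoothness_loss`."""
    u = field.data.astype(np.float64)
    _, L, W, D = u.shape
    n_int = (L - 1) * (W - 1) * (D - 1)
    d0 = (u[:, 1:, :, :] - u[:, :-1, :, :])[:, :, : W - 1, : D - 1]
    d1 = (u[:, :, 1:, :] - u[:, :, :-1, :])[:, : L - 1, :, : D - 1]
    d2 = (u[:, :, :, 1:] - u[:, :, :, :-1])[:, : L - 1, : W - 1, :]
    loss = (np.sum(d0 ** 2) + np.sum(d1 ** 2) + np.sum(d2 ** 2)) / n_int

    def bw(g):
        gu = np.zeros_like(u)
        c = 2.0 * float(g) / n_int
        gu[:, 1:, : W - 1, : D - 1] += c * d0
        gu[:, :-1, : W - 1, : D - 1] -= c * d0
        gu[:, : L - 1, 1:, : D - 1] += c * d1
        gu[:, : L - 1, :-1, : D - 1] -= c * d1
        gu[:, : L - 1, : W - 1, 1:] += c * d2
        gu[:, : L - 1, : W - 1, :-1] -= c * d2
        _acc(field, gu.astype(field.data.dtype))

    return _node(np.asarray(loss), (field,), bw)


def weighted_sum(terms: Sequence[Tensor], weights: Sequence[float]) -> Tensor:
    out = sum(float(w) * t.data for t, w in zip(terms, weights))

    def bw(g):
        for t, w in zip(terms, weights):
            _acc(t, g * float(w))

    return _node(np.asarray(out), tuple(terms), bw)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer with optional decoupled weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                upd = upd + self.lr * self.weight_decay * p.data
            p.data = p.data - upd.astype(p.data.dtype)
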