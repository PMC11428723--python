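"""Stepwise multi-level registration networks with corrected attention.

Three convolutional displacement estimators operate on an image pyramid from
coarse to fine.  The coarsest level sees the largest convolution kernels
(default 7) to capture broad deformations; kernel size shrinks toward the
finest level (default 7, 5, 3) so refinement focuses on local structure.
Each finer level receives the fixed image, the moving image warped by the
upsampled upper-level field, and an attention map; its output is a residual
field composed with the upsampled field.

The corrected attention module turns the upper level's (upsampled) field into
a single-channel map in [0, 1] through a small convolution block, then
combines it with the pathology mask of the preoperative image by elementwise
maximum, so pathological voxels always receive full attention while the rest
of the map stays learnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from . import _engine as eng
from .transform import DisplacementField
from .volumes import BinaryMask, Pyramid, downsample_mask

_DTYPE = np.float32


@dataclass
class LevelConfig:
    """One registration level. ``level_index`` 1 is the finest level."""

    level_index: int
    kernel_size: int
    channels: tuple[int, ...] = (16, 32, 32)
    factor: int = 1

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if not self.channels or any(c < 1 for c in self.channels):
            raise ValueError("channels must be positive")


@dataclass
class NetworkConfig:
    n_levels: int = 3
    levels: list[LevelConfig] = dc_field(default_factory=list)  # coarsest first
    attention_channels: int = 4
    attention_combine: str = "max"  # "max" (union) or "sum" (clamped addition)
    share_weights: bool = True  # both directions use one parameter set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if not self.levels:
            kernels = _default_kernels(self.n_levels)
            factors = [2 ** (self.n_levels - 1 - i) for i in range(self.n_levels)]
            self.levels = [
                LevelConfig(level_index=self.n_levels - i, kernel_size=kernels[i],
                            factor=factors[i])
                for i in range(self.n_levels)
            ]
        if len(self.levels) != self.n_levels:
            raise ValueError("need one LevelConfig per level")
        ks = [lc.kernel_size for lc in self.levels]
        if any(a < b for a, b in zip(ks, ks[1:])):
            raise ValueError("kernel sizes must be non-increasing from coarse to fine")
        if self.attention_combine not in ("max", "sum"):
            raise ValueError("attention_combine must be 'max' or 'sum'")


def _default_kernels(n_levels: int) -> list[int]:
    # shrink by 2 per level toward the finest (3), e.g. [7, 5, 3] for 3 levels
    return [max(3, 3 + 2 * (n_levels - 1 - i)) for i in range(n_levels)]


@dataclass
class AttentionMap:
    """Scalar guidance map in [0, 1] on one level's grid."""

    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        if self.a.ndim != 3:
            raise ValueError("attention map must be 3-D")
        if self.a.min() < -1e-6 or self.a.max() > 1 + 1e-6:
            raise ValueError("attention values must lie in [0, 1]")


@dataclass
class RegistrationResult:
    """Bidirectional registration output for one image pair."""

    field_fwd: DisplacementField
    field_bwd: DisplacementField
    warped_fwd: np.ndarray
    warped_bwd: np.ndarray
    mask_fwd: BinaryMask
    mask_bwd: BinaryMask
    levels_fwd: list[DisplacementField] = dc_field(default_factory=list)
    levels_bwd: list[DisplacementField] = dc_field(default_factory=list)
    attention_fwd: list[AttentionMap | None] = dc_field(default_factory=list)
    attention_bwd: list[AttentionMap | None] = dc_field(default_factory=list)
    delta_fwd: np.ndarray | None = None
    delta_bwd: np.ndarray | None = None


@dataclass
class CascadeResult:
    """One-direction cascade output (numpy views of the graph outputs)."""

    field: DisplacementField
    warped: np.ndarray
    level_fields: list[DisplacementField]
    attention: list[AttentionMap | None]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)


class _ConvLayer:
    def __init__(self, rng, cin, cout, k, zero: bool = False):
        if zero:
            w = np.zeros((cout, cin, k, k, k), dtype=_DTYPE)
        else:
            w = _he_init(rng, (cout, cin, k, k, k))
        self.w = eng.parameter(w)
        self.b = eng.parameter(np.zeros(cout, dtype=_DTYPE))

    def __call__(self, x):
        return eng.conv3d(x, self.w, self.b)

    @property
    def params(self):
        return [self.w, self.b]


def _pool_stages(shape: Sequence[int], requested: int) -> int:
    """How many 2x poolings the grid supports (each dim even and quotient >= 2)."""
    stages = 0
    dims = list(shape)
    while stages < requested:
        if any(d % 2 or d // 2 < 2 for d in dims):
            break
        dims = [d // 2 for d in dims]
        stages += 1
    return stages


class LevelNet:
    """Encoder-decoder displacement estimator for one pyramid level.

    The final convolution is zero-initialized so a fresh network is the
    identity transform; all other layers use He-normal initialization from
    the given seed.  Pooling depth adapts to the grid so tiny test volumes
    remain usable.

    On grids that support pooling, the decoder stops at half resolution and
    the 3-channel flow head runs there; the field is then trilinearly
    upsampled (with displacement scaling) to the level grid.  A displacement
    field is spatially smooth by construction (the smoothness prior is part
    of the objective), so the half-resolution head loses little while the
    decoder convolutions run on one eighth of the voxels.
    """

    def __init__(self, cfg: LevelConfig, in_channels: int, seed: int,
                 grid_shape: Sequence[int] | None = None):
        self.cfg = cfg
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        k = cfg.kernel_size
        widths = list(cfg.channels)
        self._stages = len(widths) - 1
        if grid_shape is not None:
            self._stages = _pool_stages(grid_shape, self._stages)
            widths = widths[: self._stages + 1]
        self.enc = []
        cin = in_channels
        for w in widths:
            self.enc.append(_ConvLayer(rng, cin, w, k))
            cin = w
        # decode back up to half resolution only (skips exist at stages >= 1)
        self.dec = []
        for i in range(self._stages - 1, 0, -1):
            self.dec.append(_ConvLayer(rng, widths[i + 1] + widths[i], widths[i], k))
        head_in = widths[1] if self._stages >= 1 else widths[0]
        self.head = _ConvLayer(rng, head_in, 3, min(k, 3), zero=True)

    @property
    def params(self):
        out = []
        for layer in self.enc + self.dec + [self.head]:
            out.extend(layer.params)
        return out

    def __call__(self, x: eng.Tensor) -> eng.Tensor:
        if x.data.shape[0] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.data.shape[0]}")
        full_shape = x.data.shape[1:]
        skips = []
        h = x
        for i, layer in enumerate(self.enc):
            if i > 0:
                skips.append(h)
                h = eng.avg_pool3d(h, 2)
            h = eng.leaky_relu(layer(h))
        for layer, skip in zip(self.dec, reversed(skips[1:])):
            h = eng.resize_trilinear(h, skip.data.shape[1:])
            h = eng.leaky_relu(layer(eng.concat_channels([h, skip])))
        flow = self.head(h)
        if flow.data.shape[1:] != full_shape:
            scales = np.array([t / s for t, s in zip(full_shape, flow.data.shape[1:])],
                              dtype=flow.data.dtype).reshape(3, 1, 1, 1)
            flow = eng.mul_const(eng.resize_trilinear(flow, full_shape), scales)
        return flow


def build_level_net(cfg: LevelConfig, in_channels: int, seed: int = 0,
                    grid_shape: Sequence[int] | None = None) -> LevelNet:
    """Construct a reproducible displacement estimator for one level."""
    return LevelNet(cfg, in_channels, seed, grid_shape)


class AttentionBlock:
    """Field (3 ch) -> attention (1 ch) convolution block with sigmoid squash.

    The output convolution is zero-initialized so a fresh block emits a flat
    0.5 map instead of seeded noise; the map becomes informative as training
    shapes it.
    """

    def __init__(self, channels: int, seed: int):
        rng = np.random.default_rng(seed)
        self.c1 = _ConvLayer(rng, 3, channels, 3)
        self.c2 = _ConvLayer(rng, channels, 1, 3, zero=True)

    @property
    def params(self):
        return self.c1.params + self.c2.params

    def __call__(self, field_t: eng.Tensor) -> eng.Tensor:
        h = eng.leaky_relu(self.c1(field_t))
        return eng.sigmoid(self.c2(h))


def corrected_attention(upsampled_field: DisplacementField | eng.Tensor,
                        pathology_mask_at_level: BinaryMask | np.ndarray,
                        params: AttentionBlock,
                        combine: str = "max") -> AttentionMap:
    """Attention for the current level from the upper level's upsampled field.

    The learned map is forced to 1 on the pathology mask support: with the
    default ``max`` rule A(x) = max(block(field)(x), M_p(x)); the ``sum``
    alternative uses min(block + M_p, 1).
    """
    t = _corrected_attention_t(
        upsampled_field if isinstance(upsampled_field, eng.Tensor)
        else eng.constant(upsampled_field.u.astype(_DTYPE)),
        pathology_mask_at_level.data if isinstance(pathology_mask_at_level, BinaryMask)
        else np.asarray(pathology_mask_at_level),
        params, combine)
    return AttentionMap(np.clip(t.data[0], 0.0, 1.0))


def _corrected_attention_t(field_t: eng.Tensor, mask: np.ndarray,
                           params: AttentionBlock, combine: str) -> eng.Tensor:
    if field_t.data.shape[1:] != mask.shape:
        raise ValueError("field and pathology mask must share the level grid")
    a = params(field_t)
    m = mask[None].astype(_DTYPE)
    if combine == "max":
        return eng.maximum_const(a, m)
    return eng.clamped_add_const(a, m, 1.0)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def _cascade_tensors(fixed_lvls: list[np.ndarray], moving_lvls: list[np.ndarray],
                     mask_lvls: list[np.ndarray] | None,
                     nets: list[LevelNet], attention_params: list[AttentionBlock],
                     combine: str = "max"):
    """Differentiable coarse-to-fine pass; returns per-level field tensors,
    attention tensors and the finest warped image tensor."""
    n = len(nets)
    phis: list[eng.Tensor] = []
    atts: list[eng.Tensor | None] = []
    phi: eng.Tensor | None = None
    for i in range(n):
        f = fixed_lvls[i].astype(_DTYPE)
        m = moving_lvls[i].astype(_DTYPE)
        if phi is None:
            x = eng.concat_channels([eng.constant(f[None]), eng.constant(m[None])])
            phi = nets[i](x)
            atts.append(None)
        else:
            tgt = f.shape
            scales = np.array([t / s for t, s in zip(tgt, phi.data.shape[1:])],
                              dtype=_DTYPE).reshape(3, 1, 1, 1)
            up = eng.mul_const(eng.resize_trilinear(phi, tgt), scales)
            mask_i = mask_lvls[i] if mask_lvls is not None else np.zeros(tgt)
            a_t = _corrected_attention_t(up, mask_i, attention_params[i - 1], combine)
            warped_m = eng.grid_sample(eng.constant(m[None]), up)
            x = eng.concat_channels([eng.constant(f[None]), warped_m, a_t])
            resid = nets[i](x)
            phi = eng.compose_fields(up, resid)
            atts.append(a_t)
        phis.append(phi)
    warped_final = eng.grid_sample(
        eng.constant(moving_lvls[-1].astype(_DTYPE)[None]), phis[-1])
    return phis, atts, warped_final


def stepwise_register(fixed_pyr: Pyramid, moving_pyr: Pyramid,
                      pathology_pyr: Sequence[BinaryMask] | None,
                      nets: list[LevelNet],
                      attention_params: list[AttentionBlock],
                      combine: str = "max") -> CascadeResult:
    """One-direction stepwise registration over aligned pyramids.

    ``pathology_pyr`` holds the preoperative pathology mask at every level
    (coarsest first); pass None for an all-zero prior.  With a single level
    the cascade degenerates to plain single-resolution registration.
    """
    if fixed_pyr.n_levels != moving_pyr.n_levels or fixed_pyr.n_levels != len(nets):
        raise ValueError("pyramids and nets must have matching level counts")
    for lf, lm in zip(fixed_pyr.levels, moving_pyr.levels):
        if lf.shape != lm.shape:
            raise ValueError("fixed/moving pyramid level shape mismatch")
    fixed_lvls = [v.data for v in fixed_pyr.levels]
    moving_lvls = [v.data for v in moving_pyr.levels]
    if pathology_pyr is not None:
        mask_lvls = [m.data for m in pathology_pyr]
        for ml, fl in zip(mask_lvls, fixed_lvls):
            if ml.shape != fl.shape:
                raise ValueError("pathology mask level shape mismatch")
    else:
        mask_lvls = None
    phis, atts, _warped32 = _cascade_tensors(fixed_lvls, moving_lvls, mask_lvls,
                                             nets, attention_params, combine)
    final = DisplacementField(phis[-1].data.astype(np.float64))
    from .transform import warp as _warp

    return CascadeResult(
        field=final,
        warped=_warp(moving_lvls[-1], final),
        level_fields=[DisplacementField(p.data.astype(np.float64)) for p in phis],
        attention=[AttentionMap(np.clip(a.data[0], 0.0, 1.0)) if a is not None else None
                   for a in atts],
    )


def pathology_pyramid(mask: BinaryMask, level_shapes: Sequence[Sequence[int]]
                      ) -> list[BinaryMask]:
    """Nearest-neighbour mask pyramid matching the image pyramid levels."""
    return [downsample_mask(mask, s) for s in level_shapes]
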