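"""Training objective: masked local NCC similarity + field-gradient smoothness.

The similarity metric is windowed (local) normalized cross-correlation in its
squared form, ``cc = cross^2 / (var_f * var_w + eps)``, computed over cubic
windows truncated at the grid border (each mean divides by the true
in-bounds count).  NCC is
invariant to affine intensity changes, which suits longitudinal MRI where
absolute intensities are not comparable.  The non-correspondence mask removes
voxels without a counterpart from the similarity average; the smoothness term
penalizes forward-difference gradients of the displacement field and is
deliberately *not* masked.

The total objective is ``L = L_sim + lambda_reg * L_reg`` with
``lambda_reg = 0.1`` by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .transform import DisplacementField
from .volumes import BinaryMask, Volume


@dataclass
class LossConfig:
    ncc_window: int = 9
    lambda_reg: float = 0.1
    epsilon: float = 1e-5
    ncc_variant: str = "squared"  # "squared" in [0,1] or "signed" in [-1,1]

    def __post_init__(self) -> None:
        if self.ncc_window % 2 == 0 or self.ncc_window < 1:
            raise ValueError("ncc_window must be odd and positive")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.ncc_variant not in ("signed", "squared"):
            raise ValueError("ncc_variant must be 'signed' or 'squared'")


def _box(x: np.ndarray, n: int) -> np.ndarray:
    """Zero-padded sliding-window sum over an n^3 cube."""
    return ndimage.uniform_filter(x, size=n, mode="constant", cval=0.0) * float(n) ** 3


def ncc_terms(f: np.ndarray, w: np.ndarray, n: int, eps: float,
              variant: str = "squared"):
    """Window sums and derived NCC quantities shared with the autodiff op.

    Windows are truncated at the grid border and every mean divides by the
    true in-bounds voxel count, so the metric keeps its affine-intensity
    invariance up to the edges.  ``variant`` selects the signed correlation
    ``cross / sqrt(var_f var_w + eps)`` or its square.
    """
    cnt = _box(np.ones_like(f), n)
    sf, sw = _box(f, n), _box(w, n)
    sff, sww, sfw = _box(f * f, n), _box(w * w, n), _box(f * w, n)
    cross = sfw - sf * sw / cnt
    varf = sff - sf * sf / cnt
    varw = sww - sw * sw / cnt
    denom = varf * varw + eps
    if variant == "squared":
        cc = cross * cross / denom
    else:
        cc = cross / np.sqrt(denom)
    return cc, cross, varf, varw, sf / cnt, sw / cnt


def local_ncc(a: Volume | np.ndarray, b: Volume | np.ndarray,
              window: int = 9, epsilon: float = 1e-5,
              variant: str = "squared"):
    """Per-voxel local NCC map and its mean.

    Returns ``(map, mean)``; values lie in [0, 1] for the squared variant
    (default) or [-1, 1] for the signed one, up to epsilon effects.
    """
    fa = a.data if isinstance(a, Volume) else np.asarray(a)
    fb = b.data if isinstance(b, Volume) else np.asarray(b)
    if fa.shape != fb.shape:
        raise ValueError(f"shape mismatch {fa.shape} vs {fb.shape}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > min(fa.shape):
        raise ValueError("window larger than smallest axis extent")
    cc, *_ = ncc_terms(fa.astype(np.float64), fb.astype(np.float64), window,
                       epsilon, variant)
    return cc, float(cc.mean())


def similarity_loss(fixed: Volume | np.ndarray, warped: Volume | np.ndarray,
                    mask: BinaryMask | np.ndarray | None, cfg: LossConfig) -> float:
    """Masked similarity term: minus the mean NCC over voxels with mask == 0.

    The average divides by the count of unmasked voxels so the loss scale is
    independent of mask size.  An all-ones mask leaves nothing to score and
    returns 0 with a warning.
    """
    fa = fixed.data if isinstance(fixed, Volume) else np.asarray(fixed)
    wa = warped.data if isinstance(warped, Volume) else np.asarray(warped)
    if fa.shape != wa.shape:
        raise ValueError("fixed/warped shape mismatch")
    if mask is None:
        m = np.zeros(fa.shape)
    else:
        m = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
        if m.shape != fa.shape:
            raise ValueError("mask shape mismatch")
    keep = 1.0 - m.astype(np.float64)
    n_keep = keep.sum()
    if n_keep == 0:
        warnings.warn("mask covers every voxel; similarity loss is 0", RuntimeWarning)
        return 0.0
    window = min(cfg.ncc_window, _largest_odd(min(fa.shape)))
    cc, _ = local_ncc(fa, wa, window, cfg.epsilon, cfg.ncc_variant)
    return float(-(cc * keep).sum() / n_keep)


def _largest_odd(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def smoothness_loss(field: DisplacementField | np.ndarray) -> float:
    """Mean squared forward-difference gradient norm of the field.

    Forward differences are cropped to the common interior so every retained
    voxel contributes all 3 x 3 derivative entries; a constant field scores 0
    and a unit-slope component scores 1.
    """
    u = field.u if isinstance(field, DisplacementField) else np.asarray(field)
    if u.ndim != 4 or u.shape[0] != 3:
        raise ValueError("field must have shape (3, L, W, D)")
    L, W, D = u.shape[1:]
    if min(L, W, D) < 2:
        raise ValueError("grid must be at least 2 voxels per axis")
    d0 = (u[:, 1:, :, :] - u[:, :-1, :, :])[:, :, : W - 1, : D - 1]
    d1 = (u[:, :, 1:, :] - u[:, :, :-1, :])[:, : L - 1, :, : D - 1]
    d2 = (u[:, :, :, 1:] - u[:, :, :, :-1])[:, : L - 1, : W - 1, :]
    n_int = (L - 1) * (W - 1) * (D - 1)
    return float((np.sum(d0 ** 2) + np.sum(d1 ** 2) + np.sum(d2 ** 2)) / n_int)


def total_loss(fixed, warped, mask, field, cfg: LossConfig):
    """Eq-style total objective; returns (scalar, breakdown dict)."""
    sim = similarity_loss(fixed, warped, mask, cfg)
    reg = smoothness_loss(field)
    total = sim + cfg.lambda_reg * reg
    return total, {"similarity": sim, "regularization": reg,
                   "lambda_reg": cfg.lambda_reg, "total": total}
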