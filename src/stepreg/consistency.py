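"""Non-correspondence detection via forward-backward inverse consistency.

If two images depict the same anatomy, the forward field (fixed A -> moving B)
and the backward field (fixed B -> moving A) should be mutual inverses.  At
voxels with no counterpart in the other image — a resection cavity, new CSF —
the unsupervised fields are unconstrained and the round trip breaks down.  The
residual

    delta(x) = || u_fwd(x) + u_bwd(x + u_fwd(x)) ||_2        (voxel units)

is thresholded at tau = mean(delta) + const to produce a binary
non-correspondence mask (strict inequality: delta == tau is not masked).
``const`` defaults to 0.015 voxels and the threshold is computed per
direction, since each direction has its own moving image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .transform import DisplacementField, identity_grid
from .volumes import BinaryMask

DEFAULT_CONST = 0.015


def const_to_voxels(const: float, shape, units: str = "normalized") -> float:
    """Convert the threshold constant to voxels of the working grid.

    ``normalized`` reads the constant as a fraction of the mean grid
    half-extent (the convention of the work the 0.015 default comes from,
    where sampling grids span [-1, 1]); ``voxel`` takes it literally.  On a
    48x48x24 grid the normalized reading of 0.015 is 0.3 voxels.
    """
    if units == "voxel":
        return float(const)
    if units != "normalized":
        raise ValueError("const units must be 'normalized' or 'voxel'")
    mean_extent = sum(shape) / len(shape)
    return float(const) * mean_extent / 2.0


@dataclass
class ConsistencyResult:
    delta: np.ndarray
    tau: float
    mask: BinaryMask


def inverse_consistency_error(fwd: DisplacementField,
                              bwd: DisplacementField) -> np.ndarray:
    """Per-voxel forward-backward residual delta on the forward field's grid.

    The backward field is trilinearly sampled (border clamp) at the
    forward-mapped position; swapping the arguments yields the symmetric
    direction's residual.
    """
    if fwd.shape != bwd.shape:
        raise ValueError("fields must share a grid")
    coords = (identity_grid(fwd.shape) + fwd.u).reshape(3, -1)
    back = np.stack([
        ndimage.map_coordinates(bwd.u[c], coords, order=1, mode="nearest")
        for c in range(3)
    ]).reshape(fwd.u.shape)
    return np.sqrt(((fwd.u + back) ** 2).sum(axis=0))


def compute_threshold(delta: np.ndarray, const: float = DEFAULT_CONST,
                      foreground: BinaryMask | None = None) -> float:
    """tau = mean(delta) + const.

    The mean runs over all voxels of the grid by default; pass ``foreground``
    to restrict it (background can dilute the mean on heavily padded images).
    """
    delta = np.asarray(delta)
    if delta.size == 0:
        raise ValueError("empty delta grid")
    if np.any(delta < 0):
        raise ValueError("delta must be non-negative")
    if const < 0:
        raise ValueError("const must be non-negative")
    if foreground is not None:
        sel = foreground.data.astype(bool)
        if not sel.any():
            raise ValueError("foreground mask selects no voxels")
        return float(delta[sel].mean() + const)
    return float(delta.mean() + const)


def non_correspondence_mask(fwd: DisplacementField, bwd: DisplacementField,
                            const: float = DEFAULT_CONST,
                            foreground: BinaryMask | None = None,
                            morphology: bool = False) -> ConsistencyResult:
    """Full pipeline: delta map, adaptive threshold, binary mask (delta > tau).

    ``morphology=True`` applies a binary closing then opening (3^3 structure)
    to remove speckle; off by default.
    """
    delta = inverse_consistency_error(fwd, bwd)
    tau = compute_threshold(delta, const, foreground)
    mask = delta > tau
    if morphology:
        st = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_opening(ndimage.binary_closing(mask, st), st)
    return ConsistencyResult(delta, tau, BinaryMask(mask.astype(np.uint8)))
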