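"""Displacement fields and trilinear warping (the spatial transformer).

Convention: a :class:`DisplacementField` ``u`` lives on the fixed image's
grid and maps the fixed-grid coordinate ``x`` to the moving-image coordinate
``x + u(x)``.  Displacements are stored in **voxel units of the field's own
grid** — not millimetres and not a normalized range — as component-first
arrays of shape ``(3, L, W, D)``.  Sampling outside the grid clamps to the
border both for image warping and field sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .volumes import Volume

_FIELD_NOTE = (
    "Displacement field convention: 4-D NIfTI with the last axis holding the "
    "3 displacement components in voxel units of this grid, axis order "
    "(L, W, D). The field maps fixed-grid voxel x to moving coordinate "
    "x + u(x), 0-based indices.\n"
)


@dataclass
class DisplacementField:
    """Dense per-voxel displacement, shape ``(3, L, W, D)``, voxel units."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError(f"field must have shape (3, L, W, D), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement components must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[1:]  # type: ignore[return-value]

    @classmethod
    def zero(cls, shape: Sequence[int]) -> "DisplacementField":
        return cls(np.zeros((3, *shape)))

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.u ** 2).sum(axis=0))


def identity_grid(shape: Sequence[int]) -> np.ndarray:
    """Coordinate grid of shape (3, L, W, D) with ``grid[a] == index along a``."""
    axes = [np.arange(s, dtype=np.float64) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def warp(vol: Volume | np.ndarray, field: DisplacementField) -> Volume | np.ndarray:
    """Warp ``vol`` by ``field``: output(x) = vol(x + u(x)), trilinear, clamped."""
    arr = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if arr.shape != field.shape:
        raise ValueError(f"volume shape {arr.shape} != field shape {field.shape}")
    coords = identity_grid(arr.shape) + field.u
    out = ndimage.map_coordinates(arr.astype(np.float64), coords.reshape(3, -1),
                                  order=1, mode="nearest").reshape(arr.shape)
    if isinstance(vol, Volume):
        return Volume(out, vol.spacing, vol.affine)
    return out


def sample_field(field: DisplacementField, points: np.ndarray) -> np.ndarray:
    """Trilinearly sample displacement components at N x 3 voxel coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be N x 3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    out = np.empty((pts.shape[0], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(field.u[c], pts.T, order=1, mode="nearest")
    return out


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Combine two fields: warp by the result == warp by ``outer`` then refine
    by ``inner``; ``c(x) = inner(x) + outer(x + inner(x))``."""
    if outer.shape != inner.shape:
        raise ValueError("fields must share a grid to compose")
    coords = (identity_grid(inner.shape) + inner.u).reshape(3, -1)
    sampled = np.stack([
        ndimage.map_coordinates(outer.u[c], coords, order=1, mode="nearest")
        for c in range(3)
    ]).reshape(outer.u.shape)
    return DisplacementField(inner.u + sampled)


def upsample_field(field: DisplacementField, target_shape: Sequence[int]) -> DisplacementField:
    """Trilinearly resample a field to a finer grid and rescale displacements.

    Each component is multiplied by its axis ratio (target/source) so the
    result stays in voxel units of the *target* grid.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < s for t, s in zip(target_shape, field.shape)):
        raise ValueError(f"upsample target {target_shape} smaller than {field.shape}")
    scales = np.array([t / s for t, s in zip(target_shape, field.shape)])
    comps = []
    for c in range(3):
        axes = []
        for s, t in zip(field.shape, target_shape):
            axes.append(np.linspace(0.0, s - 1.0, t) if t > 1 else np.array([(s - 1) / 2.0]))
        grid = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([g.ravel() for g in grid])
        comp = ndimage.map_coordinates(field.u[c], coords, order=1,
                                       mode="nearest").reshape(target_shape)
        comps.append(comp * scales[c])
    return DisplacementField(np.stack(comps))


def downsample_field(field: DisplacementField, target_shape: Sequence[int]) -> DisplacementField:
    """Inverse helper for tests: resample to a coarser grid, rescale likewise."""
    target_shape = tuple(int(t) for t in target_shape)
    scales = np.array([t / s for t, s in zip(target_shape, field.shape)])
    comps = []
    for c in range(3):
        axes = [np.linspace(0.0, s - 1.0, t) if t > 1 else np.array([(s - 1) / 2.0])
                for s, t in zip(field.shape, target_shape)]
        grid = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([g.ravel() for g in grid])
        comp = ndimage.map_coordinates(field.u[c], coords, order=1,
                                       mode="nearest").reshape(target_shape)
        comps.append(comp * scales[c])
    return DisplacementField(np.stack(comps))


def jacobian_folding_fraction(field: DisplacementField) -> float:
    """Fraction of interior voxels where det(J) of x + u(x) is <= 0.

    The Jacobian uses central differences, so the estimate is restricted to
    interior voxels.  0.0 means the transform is locally orientation
    preserving everywhere it can be checked.
    """
    if any(s < 3 for s in field.shape):
        raise ValueError("grid must be at least 3 voxels per axis")
    grads = np.empty((3, 3) + field.shape)
    for c in range(3):
        gx, gy, gz = np.gradient(field.u[c])
        grads[c] = np.stack([gx, gy, gz])
    for a in range(3):
        grads[a, a] += 1.0  # d(x+u)/dx
    interior = (slice(1, -1),) * 3
    j = grads[(slice(None), slice(None)) + interior]
    j = np.moveaxis(j.reshape(3, 3, -1), -1, 0)
    det = np.linalg.det(j)
    return float(np.mean(det <= 0.0))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_field(field: DisplacementField, path: str | Path) -> None:
    """Write as 4-D NIfTI (last axis = 3 components) plus a sidecar note."""
    path = Path(path)
    arr = np.moveaxis(field.u, 0, -1)
    img = nib.Nifti1Image(arr.astype(np.float32), np.eye(4))
    nib.save(img, str(path))
    note = path.with_suffix("").with_suffix("")  # strip .nii/.nii.gz
    Path(str(note) + "_convention.txt").write_text(_FIELD_NOTE)


def read_field(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("displacement NIfTI must be 4-D with 3 components last")
    return DisplacementField(np.moveaxis(arr, -1, 0))
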