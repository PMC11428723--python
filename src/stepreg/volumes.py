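"""Core grid data types and I/O.

A :class:`Volume` is a 3-D scalar grid with spacing and an optional
voxel-to-world affine; :class:`BinaryMask` annotates a volume with {0,1}
labels; :class:`LandmarkSet` holds named points in **0-based continuous voxel
coordinates** with axis order matching the array axes (L, W, D).  That
coordinate convention is used everywhere in this package, including landmark
CSV files (header ``Landmark,X,Y,Z``).

Multi-resolution pyramids are built by trilinear downsampling; the finest
level is the input volume itself, bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class Volume:
    """3-D scalar image.

    Parameters
    ----------
    data:
        3-D array of finite intensities (arbitrary units).
    spacing:
        Per-axis physical voxel size in mm; strictly positive.
    affine:
        Optional 4x4 voxel-to-world map, carried through I/O untouched.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def normalized(self) -> "Volume":
        """Min-max normalize intensities to [0, 1] (pipeline-entry convention)."""
        lo, hi = float(self.data.min()), float(self.data.max())
        if hi > lo:
            d = (self.data.astype(np.float64) - lo) / (hi - lo)
        else:
            d = np.zeros_like(self.data, dtype=np.float64)
        return Volume(d, self.spacing, self.affine)


@dataclass
class BinaryMask:
    """3-D {0,1} label grid annotating a volume of the same shape."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"BinaryMask must be 3-D, got {arr.ndim}-D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask values must be exactly 0 or 1")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LandmarkSet:
    """Named points in 0-based continuous voxel coordinates (N x 3)."""

    names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be N x 3")
        if len(self.names) != self.coords.shape[0]:
            raise ValueError("names and coords length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if len(self.names) < 1:
            raise ValueError("at least one landmark required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class Pyramid:
    """Multi-resolution stack of the same volume, coarsest first."""

    levels: list[Volume]
    factors: list[int]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.factors):
            raise ValueError("levels and factors length mismatch")
        if self.factors[-1] != 1:
            raise ValueError("finest pyramid factor must be 1")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


# ---------------------------------------------------------------------------
# NIfTI / CSV I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    """Read a 3-D NIfTI-1/2 file. No intensity rescaling is applied."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got {data.ndim}-D: {path}")
    zooms = img.header.get_zooms()[:3]
    return Volume(np.asarray(data), tuple(float(z) for z in zooms), np.asarray(img.affine))


def write_volume(vol: Volume | BinaryMask, path: str | Path) -> None:
    """Write a Volume (float) or BinaryMask (uint8) as NIfTI."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, BinaryMask):
        data, spacing, affine = vol.data.astype(np.uint8), (1.0, 1.0, 1.0), None
    else:
        data, spacing, affine = vol.data, vol.spacing, vol.affine
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV with header ``Landmark,X,Y,Z`` (voxel coordinates)."""
    df = pd.read_csv(path)
    if df.shape[1] < 4:
        raise ValueError("landmark CSV needs a name column and three coordinate columns")
    if df.shape[0] < 1:
        raise ValueError("landmark CSV must contain at least one landmark")
    name_col = df.columns[0]
    coord_cols = list(df.columns[1:4])
    coords = df[coord_cols].to_numpy()
    try:
        coords = coords.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric landmark coordinate in {path}") from exc
    names = [str(n) for n in df[name_col]]
    return LandmarkSet(names, coords)


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {"Landmark": lms.names,
         "X": lms.coords[:, 0], "Y": lms.coords[:, 1], "Z": lms.coords[:, 2]}
    )
    df.to_csv(path, index=False)


def landmarks_to_world(lms: LandmarkSet, affine: np.ndarray) -> np.ndarray:
    """Convert voxel-coordinate landmarks to world (mm) via a 4x4 affine."""
    hom = np.c_[lms.coords, np.ones(len(lms))]
    return (hom @ np.asarray(affine, dtype=float).T)[:, :3]


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _resample_trilinear(data: np.ndarray, target_shape: Sequence[int]) -> np.ndarray:
    """Trilinear resample onto ``target_shape`` with corner alignment."""
    src_shape = data.shape
    axes = []
    for s, t in zip(src_shape, target_shape):
        if t > 1:
            axes.append(np.linspace(0.0, s - 1.0, int(t)))
        else:
            axes.append(np.array([(s - 1) / 2.0]))
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndimage.map_coordinates(data.astype(np.float64), coords, order=1, mode="nearest")
    return out.reshape(tuple(int(t) for t in target_shape))


def resize_volume(vol: Volume, target_shape: Sequence[int],
                  presmooth: bool = False) -> Volume:
    """Trilinear resample onto a new grid, preserving physical extent.

    ``presmooth=True`` applies a Gaussian anti-alias filter (sigma matched to
    the downsampling ratio) before interpolation; off by default.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t <= 0 for t in target_shape):
        raise ValueError(f"target_shape must be 3 positive ints, got {target_shape}")
    data = vol.data.astype(np.float64)
    if presmooth:
        sig = [max(0.0, (s / t - 1.0) / 2.0) for s, t in zip(vol.shape, target_shape)]
        if any(s > 0 for s in sig):
            data = ndimage.gaussian_filter(data, sigma=sig)
    if target_shape == vol.shape:
        out = data
    else:
        out = _resample_trilinear(data, target_shape)
    new_spacing = tuple(sp * s / t for sp, s, t in zip(vol.spacing, vol.shape, target_shape))
    return Volume(out, new_spacing, vol.affine)


def pyramid_level_shape(full_shape: Sequence[int], factor: int) -> tuple[int, int, int]:
    return tuple(int(math.ceil(s / factor)) for s in full_shape)  # type: ignore[return-value]


def build_pyramid(vol: Volume, factors: Sequence[int] = (4, 2, 1),
                  presmooth: bool = False) -> Pyramid:
    """Build a coarse-to-fine pyramid; level shape = ceil(shape/factor).

    The finest level (factor 1) is the input volume itself.
    """
    factors = [int(f) for f in factors]
    if any(f < 1 for f in factors):
        raise ValueError("pyramid factors must be >= 1")
    if sorted(factors, reverse=True) != factors or factors[-1] != 1:
        raise ValueError("factors must be sorted descending and end at 1")
    levels = []
    for f in factors:
        if f == 1:
            levels.append(vol)
        else:
            levels.append(resize_volume(vol, pyramid_level_shape(vol.shape, f),
                                        presmooth=presmooth))
    return Pyramid(levels, factors)


def downsample_mask(mask: BinaryMask, target_shape: Sequence[int]) -> BinaryMask:
    """Nearest-neighbour mask resampling (preserves binarity)."""
    target_shape = tuple(int(t) for t in target_shape)
    if target_shape == mask.shape:
        return BinaryMask(mask.data.copy())
    idx = []
    for s, t in zip(mask.shape, target_shape):
        if t > 1:
            idx.append(np.round(np.linspace(0.0, s - 1.0, t)).astype(int))
        else:
            idx.append(np.array([(s - 1) // 2]))
    out = mask.data[np.ix_(*idx)]
    return BinaryMask(out)
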