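"""Quantitative evaluation: landmark TRE, mask overlap, case reports.

Target registration error maps each fixed-image landmark through the
estimated field (sampled at the landmark, no field inversion) and measures
the Euclidean distance to the corresponding moving-image landmark.  Distances
are reported in mm when a spacing is supplied, in voxels otherwise, with the
unit recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .transform import DisplacementField, jacobian_folding_fraction, sample_field
from .volumes import BinaryMask, LandmarkSet


@dataclass
class TREReport:
    distances: np.ndarray
    mean: float
    sd: float
    count: int
    unit: str  # "mm" or "voxel"

    def __str__(self) -> str:
        return f"TRE {self.mean:.3f} +/- {self.sd:.3f} {self.unit} (n={self.count})"


def tre(fixed_lm: LandmarkSet, moving_lm: LandmarkSet,
        field: DisplacementField | None,
        spacing: Sequence[float] | None = None) -> TREReport:
    """Landmark TRE after applying ``field`` (None = unregistered baseline).

    The field lives on the fixed grid; landmarks are matched by name, so the
    result is invariant to row order.
    """
    if set(fixed_lm.names) != set(moving_lm.names):
        raise ValueError("landmark sets must contain the same names")
    order = {n: i for i, n in enumerate(moving_lm.names)}
    mov = moving_lm.coords[[order[n] for n in fixed_lm.names]]
    if field is None:
        warped = fixed_lm.coords
    else:
        warped = fixed_lm.coords + sample_field(field, fixed_lm.coords)
    diff = warped - mov
    if spacing is not None:
        diff = diff * np.asarray(spacing, dtype=float)
        unit = "mm"
    else:
        unit = "voxel"
    d = np.linalg.norm(diff, axis=1)
    return TREReport(distances=d, mean=float(d.mean()), sd=float(d.std()),
                     count=len(d), unit=unit)


def mask_overlap(estimated: BinaryMask | np.ndarray,
                 truth: BinaryMask | np.ndarray) -> tuple[float, float, float]:
    """(Dice, precision, recall); Dice of two empty masks is 1.0 by convention."""
    a = (estimated.data if isinstance(estimated, BinaryMask) else np.asarray(estimated)).astype(bool)
    b = (truth.data if isinstance(truth, BinaryMask) else np.asarray(truth)).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    inter = float(np.logical_and(a, b).sum())
    na, nb = float(a.sum()), float(b.sum())
    dice = 1.0 if na + nb == 0 else 2.0 * inter / (na + nb)
    precision = 1.0 if na == 0 else inter / na
    recall = 1.0 if nb == 0 else inter / nb
    return dice, precision, recall


def field_error(estimated: DisplacementField, truth: DisplacementField) -> float:
    """Mean Euclidean norm of the per-voxel field difference (voxel units)."""
    if estimated.shape != truth.shape:
        raise ValueError("field shape mismatch")
    return float(np.sqrt(((estimated.u - truth.u) ** 2).sum(axis=0)).mean())


def evaluate_case(result, landmarks: tuple[LandmarkSet, LandmarkSet] | None = None,
                  truth_field: DisplacementField | None = None,
                  truth_cavity: BinaryMask | None = None,
                  spacing: Sequence[float] | None = None) -> dict:
    """Aggregate the available ground-truth comparisons into one report row.

    ``result`` is a :class:`~stepreg.network.RegistrationResult`; at least one
    of landmarks / truth_field / truth_cavity must be given.  Metrics that
    cannot be computed are reported as None.
    """
    if landmarks is None and truth_field is None and truth_cavity is None:
        raise ValueError("nothing to evaluate: supply landmarks, a truth field "
                         "or a truth cavity mask")
    row: dict = {
        "tre_mean": None, "tre_sd": None, "tre_unit": None,
        "field_error": None, "dice": None, "precision": None, "recall": None,
        "folding_fraction": jacobian_folding_fraction(result.field_fwd),
    }
    if landmarks is not None:
        rep = tre(landmarks[0], landmarks[1], result.field_fwd, spacing)
        row.update(tre_mean=rep.mean, tre_sd=rep.sd, tre_unit=rep.unit)
    if truth_field is not None:
        row["field_error"] = field_error(result.field_fwd, truth_field)
    if truth_cavity is not None:
        d, p, r = mask_overlap(result.mask_fwd, truth_cavity)
        row.update(dice=d, precision=p, recall=r)
    return row


def save_overlay(volume: np.ndarray, mask: np.ndarray | None,
                 path: str | Path, axis: int = 2) -> None:
    """Mid-slice PNG with the mask rendered in translucent red."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = volume.shape[axis] // 2
    sl = [slice(None)] * 3
    sl[axis] = idx
    img = np.asarray(volume)[tuple(sl)]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img.T, cmap="gray", origin="lower")
    if mask is not None:
        m = np.asarray(mask)[tuple(sl)].astype(float)
        overlay = np.zeros((*m.T.shape, 4))
        overlay[..., 0] = 1.0
        overlay[..., 3] = 0.45 * m.T
        ax.imshow(overlay, origin="lower")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
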