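"""Gold-standard synthetic test cases for pre-/post-operative registration.

Real longitudinal glioma MRI has no ground-truth deformation field or
non-correspondence mask, which makes quantitative evaluation of those outputs
impossible.  This generator builds fully-annotated surrogates:

* a brain-like phantom — an ellipsoidal support filled with smoothed random
  intensity structures ("blobs") over a low-frequency background;
* a smooth, invertible random deformation (Gaussian-filtered noise, tapered
  to zero at the borders, scaled to a chosen peak magnitude) with its
  numerical inverse from fixed-point iteration;
* a "tumor" texture in the preoperative image inside a spherical pathology
  mask, and a resection cavity in the follow-up image — the mapped inner
  sphere is replaced by a CSF-like low constant, creating genuine
  non-correspondence present in only one image;
* corresponding landmark pairs at high-gradient voxels away from the cavity.

Everything is a pure function of :class:`SynthConfig` (seed included), so the
case doubles as a reproducible fixture for every downstream module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .transform import DisplacementField, identity_grid, jacobian_folding_fraction, warp
from .volumes import BinaryMask, LandmarkSet, Volume

_MAX_AMP_SIGMA_RATIO = 0.6  # empirical fold-safety guard, checked explicitly below
_CSF_LEVEL = 0.04


@dataclass
class SynthConfig:
    shape: tuple[int, int, int] = (48, 48, 24)
    n_blobs: int = 40
    field_amplitude: float = 3.0
    field_smoothness: float = 6.0
    cavity_radius: float = 4.0
    noise_sd: float = 0.005
    n_landmarks: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if self.field_amplitude < 0:
            raise ValueError("field_amplitude must be >= 0")
        if self.field_smoothness <= 0:
            raise ValueError("field_smoothness must be > 0")
        if self.cavity_radius < 0:
            raise ValueError("cavity_radius must be >= 0")


@dataclass
class SyntheticCase:
    preop: Volume
    followup: Volume
    truth_field: DisplacementField
    truth_inverse: DisplacementField
    cavity_mask: BinaryMask
    pathology_mask: BinaryMask
    landmarks_preop: LandmarkSet
    landmarks_followup: LandmarkSet
    seed: int = 0
    config: SynthConfig | None = None


def make_phantom(cfg: SynthConfig) -> Volume:
    """Brain-like phantom: smooth ellipsoid support, blobs, slow background."""
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.shape
    grid = identity_grid(shape)
    center = (np.array(shape, dtype=float) - 1) / 2.0
    radii = np.maximum(np.array(shape, dtype=float) * 0.42, 1.0)
    r2 = sum(((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    support = 1.0 / (1.0 + np.exp((r2 - 1.0) / 0.08))

    blobs = np.zeros(shape)
    if cfg.n_blobs > 0:
        inside = np.argwhere(r2 < 0.7)
        picks = inside[rng.integers(0, len(inside), size=cfg.n_blobs)]
        amps = rng.uniform(0.3, 1.0, size=cfg.n_blobs)
        imp = np.zeros(shape)
        for p, a in zip(picks, amps):
            imp[tuple(p)] += a
        blobs = ndimage.gaussian_filter(imp, sigma=2.0)
        if blobs.max() > 0:
            blobs /= blobs.max()

    background = ndimage.gaussian_filter(rng.standard_normal(shape),
                                         sigma=max(min(shape) / 6.0, 1.0))
    if background.std() > 0:
        background = 0.15 * (background - background.mean()) / background.std()

    img = support * np.clip(0.25 + 0.7 * blobs + background, 0.0, None)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros(shape)
    return Volume(img)


def invert_field(field: DisplacementField, max_iter: int = 50,
                 tol: float = 1e-3) -> DisplacementField:
    """Fixed-point inverse: v_{k+1}(x) = -u(x + v_k(x))."""
    from .transform import sample_field

    grid = identity_grid(field.shape)
    pts_base = grid.reshape(3, -1).T
    v = -field.u.copy()
    for _ in range(max_iter):
        pts = pts_base + v.reshape(3, -1).T
        u_at = sample_field(field, pts).T.reshape(v.shape)
        v_new = -u_at
        change = np.abs(v_new - v).max()
        v = v_new
        if change < tol:
            break
    return DisplacementField(v)


def _border_taper(shape, margin: float) -> np.ndarray:
    win = np.ones(shape)
    for a, s in enumerate(shape):
        x = np.arange(s, dtype=float)
        d = np.minimum(x, s - 1 - x) / max(margin, 1.0)
        prof = np.clip(d, 0.0, 1.0)
        prof = prof * prof * (3 - 2 * prof)  # smoothstep
        sl = [None] * 3
        sl[a] = slice(None)
        win = win * prof[tuple(sl)]
    return win


def make_smooth_field(cfg: SynthConfig) -> tuple[DisplacementField, DisplacementField]:
    """Random smooth invertible field and its numerical inverse.

    Gaussian-filtered white noise per component, tapered to zero near the
    borders, rescaled so the peak displacement magnitude equals
    ``field_amplitude``.  The amplitude/smoothness ratio is guarded and the
    Jacobian is checked: any folding raises with advice to lower the
    amplitude.
    """
    if cfg.field_amplitude > 0 and \
            cfg.field_amplitude / cfg.field_smoothness > _MAX_AMP_SIGMA_RATIO:
        raise ValueError(
            f"field_amplitude/field_smoothness = "
            f"{cfg.field_amplitude / cfg.field_smoothness:.2f} risks folding; "
            f"keep it <= {_MAX_AMP_SIGMA_RATIO}")
    shape = cfg.shape
    if cfg.field_amplitude == 0:
        zero = DisplacementField.zero(shape)
        return zero, DisplacementField.zero(shape)
    rng = np.random.default_rng(cfg.seed + 1)
    taper = _border_taper(shape, margin=6.0)
    # A bounded number of fresh draws keeps the generator both deterministic
    # and reliable near the amplitude guard, where a single draw can
    # occasionally exceed the unit-gradient folding limit.
    fwd = None
    for _attempt in range(20):
        raw = np.stack([
            ndimage.gaussian_filter(rng.standard_normal(shape) * taper,
                                    sigma=cfg.field_smoothness)
            for _ in range(3)
        ])
        mag = np.sqrt((raw ** 2).sum(axis=0))
        peak = mag.max()
        if peak <= 0:
            return DisplacementField.zero(shape), DisplacementField.zero(shape)
        cand = DisplacementField(raw * (cfg.field_amplitude / peak))
        if jacobian_folding_fraction(cand) == 0.0:
            fwd = cand
            break
    if fwd is None:
        raise ValueError("generated field folds; reduce field_amplitude or "
                         "increase field_smoothness")
    inv = invert_field(fwd)
    return fwd, inv


def _sphere(shape, center, radius) -> np.ndarray:
    grid = identity_grid(shape)
    d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius ** 2


def _pick_landmarks(img: np.ndarray, exclude: np.ndarray, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Greedy top-gradient voxel picks with a minimum pairwise separation."""
    gmag = ndimage.gaussian_gradient_magnitude(img, sigma=1.0)
    shape = img.shape
    ok = np.ones(shape, dtype=bool)
    for a, s in enumerate(shape):
        margin = min(4, max(1, (s - 2) // 3))
        idx = identity_grid(shape)[a]
        ok &= (idx >= margin) & (idx <= s - 1 - margin)
    ok &= ~exclude
    cand = np.argwhere(ok)
    if len(cand) == 0:
        raise ValueError("no eligible landmark locations")
    order = np.argsort(gmag[tuple(cand.T)])[::-1]
    cand = cand[order]
    for sep in (4.0, 3.0, 2.0, 1.0):
        chosen: list[np.ndarray] = []
        for p in cand:
            if len(chosen) == n:
                break
            if all(np.linalg.norm(p - q) >= sep for q in chosen):
                chosen.append(p)
        if len(chosen) == n:
            return np.array(chosen, dtype=float)
    raise ValueError(f"could not place {n} landmarks with any separation")


def make_pair(cfg: SynthConfig) -> SyntheticCase:
    """Full annotated case: images, truth fields, masks, landmarks."""
    rng = np.random.default_rng(cfg.seed + 2)
    shape = cfg.shape
    phantom = make_phantom(cfg)
    fwd, inv = make_smooth_field(cfg)

    # Tumor site well inside the support so the pathology sphere fits.
    center = (np.array(shape, dtype=float) - 1) / 2.0
    offset = rng.uniform(-0.15, 0.15, size=3) * np.array(shape)
    site = center + offset
    path_radius = 2.0 * cfg.cavity_radius
    pathology = _sphere(shape, site, path_radius) if path_radius > 0 else np.zeros(shape, bool)
    cavity = _sphere(shape, site, cfg.cavity_radius) if cfg.cavity_radius > 0 else np.zeros(shape, bool)

    preop = phantom.data.copy()
    if pathology.any():
        texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
        texture = 0.75 + 0.2 * np.clip(texture / max(texture.std(), 1e-9), -1, 1)
        soft = ndimage.gaussian_filter(pathology.astype(float), sigma=1.0)
        preop = preop * (1 - soft) + soft * texture

    # followup(y) = preop(y + u_inv(y)) so that warp(followup, fwd) ~ preop
    followup = warp(preop, inv)
    if cavity.any():
        # the preop cavity sphere seen in follow-up coordinates
        grid = identity_grid(shape)
        preop_coords = grid + inv.u
        d2 = sum((preop_coords[a] - site[a]) ** 2 for a in range(3))
        cavity_follow = d2 <= cfg.cavity_radius ** 2
        followup = np.where(cavity_follow,
                            _CSF_LEVEL + 0.01 * rng.standard_normal(shape),
                            followup)

    if cfg.noise_sd > 0:
        preop = preop + rng.normal(0.0, cfg.noise_sd, shape)
        followup = followup + rng.normal(0.0, cfg.noise_sd, shape)

    exclude = ndimage.binary_dilation(cavity, iterations=3) if cavity.any() \
        else np.zeros(shape, bool)
    lm = _pick_landmarks(phantom.data, exclude, cfg.n_landmarks, rng)
    lm_follow = lm + fwd.u[:, lm[:, 0].astype(int), lm[:, 1].astype(int),
                           lm[:, 2].astype(int)].T
    names = [f"L{i + 1:03d}" for i in range(cfg.n_landmarks)]

    return SyntheticCase(
        preop=Volume(np.clip(preop, 0.0, 1.2)),
        followup=Volume(np.clip(followup, 0.0, 1.2)),
        truth_field=fwd,
        truth_inverse=inv,
        cavity_mask=BinaryMask(cavity.astype(np.uint8)),
        pathology_mask=BinaryMask(pathology.astype(np.uint8)),
        landmarks_preop=LandmarkSet(names, lm),
        landmarks_followup=LandmarkSet(names, lm_follow),
        seed=cfg.seed,
        config=cfg,
    )


def make_dataset(n_cases: int, cfg: SynthConfig) -> list[SyntheticCase]:
    """Reproducible list of cases seeded ``cfg.seed + i``."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out = []
    for i in range(n_cases):
        c = SynthConfig(shape=cfg.shape, n_blobs=cfg.n_blobs,
                        field_amplitude=cfg.field_amplitude,
                        field_smoothness=cfg.field_smoothness,
                        cavity_radius=cfg.cavity_radius, noise_sd=cfg.noise_sd,
                        n_landmarks=cfg.n_landmarks, seed=cfg.seed + i)
        out.append(make_pair(c))
    return out
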