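"""Bidirectional unsupervised training loop and inference-time registration.

Every optimization step registers the pair in both directions (preoperative
as fixed, then follow-up as fixed), recomputes the two non-correspondence
masks from the current finest fields (no gradient flows through mask
construction), evaluates the masked-NCC + smoothness objective per direction,
sums the two directional losses with equal weight, and takes one Adam step.
The loss is applied at the finest level only by default; ``deep_supervision``
adds per-level terms on the downsampled images.

One model is trained across all provided pairs (cohort mode); per-pair
instance optimization is just a one-pair cohort.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine as eng
from .consistency import (DEFAULT_CONST, const_to_voxels,
                          non_correspondence_mask)
from .losses import LossConfig, _largest_odd
from .network import (AttentionBlock, CascadeResult, LevelNet, NetworkConfig,
                      RegistrationResult, _cascade_tensors, build_level_net,
                      pathology_pyramid, stepwise_register)
from .transform import DisplacementField
from .volumes import BinaryMask, Volume, build_pyramid, pyramid_level_shape


@dataclass
class TrainConfig:
    epochs: int = 1000
    batch_size: int = 1
    learning_rate: float = 1e-4
    lambda_reg: float = 0.1
    const: float = DEFAULT_CONST
    const_units: str = "normalized"  # see consistency.const_to_voxels
    ncc_window: int = 9
    seed: int = 0
    checkpoint_interval: int = 100
    device: str = "cpu"
    deep_supervision: bool = False
    lr_schedule: str = "constant"  # or "cosine" (half-cosine decay to ~0)
    standardize_inputs: bool = True  # zero-mean/unit-var per pyramid level
    weight_decay: float = 0.0
    ema_decay: float = 0.0  # Polyak averaging of weights; 0 disables

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainLog:
    records: list[dict] = dc_field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class Model:
    """Trained state: per-direction level nets and attention blocks."""

    def __init__(self, net_cfg: NetworkConfig, grid_shape: tuple[int, int, int],
                 standardize_inputs: bool = True):
        self.net_cfg = net_cfg
        self.grid_shape = tuple(grid_shape)
        self.standardize_inputs = standardize_inputs
        rng = np.random.default_rng(net_cfg.seed)
        seeds = rng.integers(0, 2 ** 31 - 1, size=4 * net_cfg.n_levels)
        self.level_shapes = [pyramid_level_shape(grid_shape, lc.factor)
                             for lc in net_cfg.levels]
        self.nets_fwd = self._build_nets(seeds[0::4])
        self.attn_fwd = self._build_attn(seeds[1::4])
        if net_cfg.share_weights:
            self.nets_bwd = self.nets_fwd
            self.attn_bwd = self.attn_fwd
        else:
            self.nets_bwd = self._build_nets(seeds[2::4])
            self.attn_bwd = self._build_attn(seeds[3::4])

    def _build_nets(self, seeds) -> list[LevelNet]:
        nets = []
        for i, lc in enumerate(self.net_cfg.levels):
            in_ch = 2 if i == 0 else 3  # fixed+moving, plus attention at finer levels
            nets.append(build_level_net(lc, in_ch, int(seeds[i]), self.level_shapes[i]))
        return nets

    def _build_attn(self, seeds) -> list[AttentionBlock]:
        return [AttentionBlock(self.net_cfg.attention_channels, int(seeds[i]))
                for i in range(1, self.net_cfg.n_levels)]

    def parameters(self) -> list[eng.Tensor]:
        out = []
        for net in self.nets_fwd:
            out.extend(net.params)
        for blk in self.attn_fwd:
            out.extend(blk.params)
        if not self.net_cfg.share_weights:
            for net in self.nets_bwd:
                out.extend(net.params)
            for blk in self.attn_bwd:
                out.extend(blk.params)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        meta = {"net_cfg": _net_cfg_dict(self.net_cfg), "grid_shape": self.grid_shape,
                "standardize_inputs": self.standardize_inputs}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            cfg = _net_cfg_from_dict(meta["net_cfg"])
            model = cls(cfg, tuple(meta["grid_shape"]),
                        meta.get("standardize_inputs", True))
            params = model.parameters()
            for i, p in enumerate(params):
                p.data = z[f"p{i}"]
        return model


def _net_cfg_dict(cfg: NetworkConfig) -> dict:
    d = asdict(cfg)
    d["levels"] = [asdict(lc) for lc in cfg.levels]
    return d


def _net_cfg_from_dict(d: dict) -> NetworkConfig:
    from .network import LevelConfig

    levels = [LevelConfig(level_index=lc["level_index"], kernel_size=lc["kernel_size"],
                          channels=tuple(lc["channels"]), factor=lc["factor"])
              for lc in d["levels"]]
    return NetworkConfig(n_levels=d["n_levels"], levels=levels,
                         attention_channels=d["attention_channels"],
                         attention_combine=d["attention_combine"],
                         share_weights=d["share_weights"], seed=d["seed"])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _prepare_pair(preop: Volume, followup: Volume, pathology: BinaryMask,
                  net_cfg: NetworkConfig, standardize: bool = True):
    factors = [lc.factor for lc in net_cfg.levels]
    pre_n = preop.normalized()
    fol_n = followup.normalized()
    # anti-alias pre-smoothing: fine texture would alias away at factor 4
    pyr_pre = build_pyramid(pre_n, factors, presmooth=True)
    pyr_fol = build_pyramid(fol_n, factors, presmooth=True)
    if standardize:
        for pyr in (pyr_pre, pyr_fol):
            for i, lv in enumerate(pyr.levels):
                sd = lv.data.std()
                pyr.levels[i] = Volume((lv.data - lv.data.mean()) / max(sd, 1e-8),
                                       lv.spacing, lv.affine)
    shapes = [lv.shape for lv in pyr_pre.levels]
    masks = pathology_pyramid(pathology, shapes)
    return pyr_pre, pyr_fol, masks


def _direction_cascade(fixed_lvls, moving_lvls, mask_lvls, nets, attns, combine):
    """Differentiable one-direction pass; returns per-level field tensors and
    the finest warped image tensor."""
    phis, _, warped = _cascade_tensors(fixed_lvls, moving_lvls, mask_lvls,
                                       nets, attns, combine)
    return phis, warped


def train(pairs, net_cfg: NetworkConfig, train_cfg: TrainConfig,
          loss_cfg: LossConfig | None = None, verbose: bool = False):
    """Train one model over ``pairs`` = list of (preop, followup, pathology).

    Returns ``(model, TrainLog)``.  Deterministic for a fixed seed and device:
    data order, parameter init and every update depend only on the configs.
    """
    if not pairs:
        raise ValueError("empty training set")
    shapes = {p[0].shape for p in pairs} | {p[1].shape for p in pairs}
    if len(shapes) != 1:
        raise ValueError("all training pairs must share one shape")
    grid_shape = pairs[0][0].shape
    if loss_cfg is None:
        loss_cfg = LossConfig(ncc_window=train_cfg.ncc_window,
                              lambda_reg=train_cfg.lambda_reg)

    model = Model(net_cfg, grid_shape, train_cfg.standardize_inputs)
    opt = eng.Adam(model.parameters(), lr=train_cfg.learning_rate,
                   weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    prepared = [_prepare_pair(*p, net_cfg, train_cfg.standardize_inputs)
                for p in pairs]
    log = TrainLog()
    combine = net_cfg.attention_combine
    fine_window = _largest_odd(min(loss_cfg.ncc_window, min(grid_shape)))
    total_steps = max(1, train_cfg.epochs * len(prepared))
    step = 0
    const_vox = const_to_voxels(train_cfg.const, grid_shape, train_cfg.const_units)
    ema = [p.data.copy() for p in opt.params] if train_cfg.ema_decay > 0 else None

    for epoch in range(train_cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(prepared))
        ep_tot = ep_sim = ep_reg = 0.0
        ep_mask_f = ep_mask_b = 0.0
        for idx in order:
            pyr_pre, pyr_fol, masks = prepared[idx]
            fixed_f = [lv.data for lv in pyr_pre.levels]
            moving_f = [lv.data for lv in pyr_fol.levels]
            mask_lvls = [m.data for m in masks]
            phis_f, warped_f = _direction_cascade(fixed_f, moving_f, mask_lvls,
                                                  model.nets_fwd, model.attn_fwd,
                                                  combine)
            phis_b, warped_b = _direction_cascade(moving_f, fixed_f, mask_lvls,
                                                  model.nets_bwd, model.attn_bwd,
                                                  combine)
            # Non-correspondence masks from the current bidirectional fields;
            # constructed outside the graph so no gradient flows through them.
            f_fwd = DisplacementField(phis_f[-1].data.astype(np.float64))
            f_bwd = DisplacementField(phis_b[-1].data.astype(np.float64))
            res_f = non_correspondence_mask(f_fwd, f_bwd, const_vox)
            res_b = non_correspondence_mask(f_bwd, f_fwd, const_vox)

            sim_f = eng.masked_ncc_loss(fixed_f[-1], _squeeze0(warped_f),
                                        res_f.mask.data, fine_window,
                                        loss_cfg.epsilon, loss_cfg.ncc_variant)
            sim_b = eng.masked_ncc_loss(moving_f[-1], _squeeze0(warped_b),
                                        res_b.mask.data, fine_window,
                                        loss_cfg.epsilon, loss_cfg.ncc_variant)
            reg_f = eng.gradient_l2_loss(phis_f[-1])
            reg_b = eng.gradient_l2_loss(phis_b[-1])
            terms = [sim_f, sim_b, reg_f, reg_b]
            weights = [1.0, 1.0, loss_cfg.lambda_reg, loss_cfg.lambda_reg]
            if train_cfg.deep_supervision:
                for lvl in range(len(phis_f) - 1):
                    w_f = eng.grid_sample(eng.constant(moving_f[lvl][None].astype(np.float32)),
                                          phis_f[lvl])
                    w_b = eng.grid_sample(eng.constant(fixed_f[lvl][None].astype(np.float32)),
                                          phis_b[lvl])
                    win = _largest_odd(min(loss_cfg.ncc_window, min(fixed_f[lvl].shape)))
                    terms.append(eng.masked_ncc_loss(fixed_f[lvl], _squeeze0(w_f), None,
                                                     win, loss_cfg.epsilon,
                                                     loss_cfg.ncc_variant))
                    terms.append(eng.masked_ncc_loss(moving_f[lvl], _squeeze0(w_b), None,
                                                     win, loss_cfg.epsilon,
                                                     loss_cfg.ncc_variant))
                    weights.extend([0.5, 0.5])
            total = eng.weighted_sum(terms, weights)
            tval = float(total.data)
            if not np.isfinite(tval):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, pair {idx}: {tval}")
            if train_cfg.lr_schedule == "cosine":
                opt.lr = train_cfg.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * step / total_steps))
            opt.zero_grad()
            total.backward()
            opt.step()
            step += 1
            if ema is not None:
                d = train_cfg.ema_decay
                for buf, p in zip(ema, opt.params):
                    buf *= d
                    buf += (1.0 - d) * p.data

            sim_val = float(sim_f.data) + float(sim_b.data)
            reg_val = float(reg_f.data) + float(reg_b.data)
            ep_tot += float(sim_f.data) + float(sim_b.data) + \
                loss_cfg.lambda_reg * reg_val
            ep_sim += sim_val
            ep_reg += reg_val
            ep_mask_f += res_f.mask.data.mean()
            ep_mask_b += res_b.mask.data.mean()
        n = len(prepared)
        rec = {
            "epoch": epoch,
            "total": ep_tot / n,
            "similarity": ep_sim / n,
            "regularization": ep_reg / n,
            "lambda_reg": loss_cfg.lambda_reg,
            "mask_fraction_fwd": ep_mask_f / n,
            "mask_fraction_bwd": ep_mask_b / n,
            "wall_time_s": time.perf_counter() - t0,
        }
        log.records.append(rec)
        if verbose:
            print(f"epoch {epoch:4d}  total {rec['total']:+.4f}  "
                  f"sim {rec['similarity']:+.4f}  reg {rec['regularization']:.4f}",
                  flush=True)
    if ema is not None:
        # averaged weights generalize better than the last noisy iterate
        for p, buf in zip(opt.params, ema):
            p.data = buf.astype(p.data.dtype)
    return model, log


def _squeeze0(t: eng.Tensor) -> eng.Tensor:
    out = t.data[0]

    def bw(g):
        eng._acc(t, g[None])

    return eng._node(out, (t,), bw)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def register_pair(preop: Volume, followup: Volume, pathology_mask: BinaryMask,
                  model: Model, const: float = DEFAULT_CONST,
                  const_units: str = "normalized") -> RegistrationResult:
    """Run both directions through the trained cascade and attach masks.

    Pure function of the inputs and parameters; inputs must match the trained
    grid shape (resizing is the caller's job).
    """
    if preop.shape != model.grid_shape or followup.shape != model.grid_shape:
        raise ValueError(f"inputs must match the trained grid {model.grid_shape}")
    if pathology_mask.shape != model.grid_shape:
        raise ValueError("pathology mask shape mismatch")
    const = const_to_voxels(const, model.grid_shape, const_units)
    pyr_pre, pyr_fol, masks = _prepare_pair(preop, followup, pathology_mask,
                                            model.net_cfg,
                                            model.standardize_inputs)
    fwd: CascadeResult = stepwise_register(pyr_pre, pyr_fol, masks,
                                           model.nets_fwd, model.attn_fwd,
                                           model.net_cfg.attention_combine)
    bwd: CascadeResult = stepwise_register(pyr_fol, pyr_pre, masks,
                                           model.nets_bwd, model.attn_bwd,
                                           model.net_cfg.attention_combine)
    res_f = non_correspondence_mask(fwd.field, bwd.field, const)
    res_b = non_correspondence_mask(bwd.field, fwd.field, const)
    # warped outputs in normalized [0,1] intensity units regardless of the
    # network-input standardization
    from .transform import warp as _warp

    warped_f = _warp(followup.normalized().data, fwd.field)
    warped_b = _warp(preop.normalized().data, bwd.field)
    return RegistrationResult(
        field_fwd=fwd.field, field_bwd=bwd.field,
        warped_fwd=warped_f, warped_bwd=warped_b,
        mask_fwd=res_f.mask, mask_bwd=res_b.mask,
        levels_fwd=fwd.level_fields, levels_bwd=bwd.level_fields,
        attention_fwd=fwd.attention, attention_bwd=bwd.attention,
        delta_fwd=res_f.delta, delta_bwd=res_b.delta,
    )


def kfold_split(n: int, k: int, seed: int = 0) -> list[tuple[list[int], list[int]]]:
    """Simple k-fold index splitter for synthetic cohorts."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k)
    out = []
    for i in range(k):
        val = list(map(int, folds[i]))
        trn = [int(j) for f in folds[:i] + folds[i + 1:] for j in f]
        out.append((trn, val))
    return out
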