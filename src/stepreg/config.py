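"""YAML configuration loading and the desk/paper run profiles.

The ``paper`` profile mirrors the published training setup (160x160x80 grid,
1000 epochs, batch 1, Adam lr 1e-4, lambda 0.1) and needs accelerator-scale
compute.  The ``desk`` profile is the CPU-feasible surrogate used by the test
suite: 48x48x24 grids, 50 epochs, smaller feature widths, and a learning rate
raised to 1e-3 to compensate for the 20x shorter schedule.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .losses import LossConfig
from .network import LevelConfig, NetworkConfig
from .synthetic import SynthConfig
from .train import TrainConfig

PROFILES: dict[str, dict] = {
    "desk": {
        "shape": (48, 48, 24),
        "epochs": 50,
        "learning_rate": 4e-3,
        "lr_schedule": "cosine",
        # coarser levels are cheap: give them more features
        "widths": ((16, 32), (12, 24), (8, 16)),
    },
    "paper": {
        "shape": (160, 160, 80),
        "epochs": 1000,
        "learning_rate": 1e-4,
        "lr_schedule": "constant",
        "widths": (16, 32, 32),
    },
}


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return data


def build_configs(raw: dict | None = None, profile: str = "desk"):
    """Merge profile defaults with a raw YAML dict.

    Returns ``(synth_cfg, net_cfg, train_cfg, loss_cfg)``; YAML keys override
    the profile, which overrides dataclass defaults.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    raw = dict(raw or {})
    prof = PROFILES[profile]

    syn = dict(raw.get("synthetic", {}))
    syn.setdefault("shape", prof["shape"])
    syn["shape"] = tuple(syn["shape"])
    synth_cfg = SynthConfig(**syn)

    net = dict(raw.get("network", {}))
    n_levels = int(net.pop("n_levels", 3))
    widths = net.pop("widths", prof["widths"])
    if widths and not isinstance(widths[0], (list, tuple)):
        widths = [tuple(widths)] * n_levels  # same widths at every level
    else:
        widths = [tuple(w) for w in widths]
    if len(widths) != n_levels:
        raise ValueError("need one widths entry per level")
    kernels = net.pop("kernels", None)
    if kernels is not None:
        kernels = [int(k) for k in kernels]
        if len(kernels) != n_levels:
            raise ValueError("need one kernel size per level")
    else:
        from .network import _default_kernels
        kernels = _default_kernels(n_levels)
    factors = [2 ** (n_levels - 1 - i) for i in range(n_levels)]
    levels = [LevelConfig(level_index=n_levels - i, kernel_size=kernels[i],
                          channels=widths[i], factor=factors[i])
              for i in range(n_levels)]
    net_cfg = NetworkConfig(n_levels=n_levels, levels=levels, **net)

    tr = dict(raw.get("train", {}))
    tr.setdefault("epochs", prof["epochs"])
    tr.setdefault("learning_rate", prof["learning_rate"])
    tr.setdefault("lr_schedule", prof["lr_schedule"])
    cons = dict(raw.get("consistency", {}))
    if "const" in cons:
        tr.setdefault("const", float(cons["const"]))
    train_cfg = TrainConfig(**tr)

    ls = dict(raw.get("loss", {}))
    ls.setdefault("lambda_reg", train_cfg.lambda_reg)
    ls.setdefault("ncc_window", train_cfg.ncc_window)
    loss_cfg = LossConfig(**ls)
    return synth_cfg, net_cfg, train_cfg, loss_cfg
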