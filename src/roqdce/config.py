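"""Run configuration, validation, and reproducibility plumbing.

A TOML-backed configuration with two scale profiles:

* ``desk`` — CPU-sized defaults (1e5 simulated pre-training pairs,
  mini-batched training, a ~20-subject phantom cohort);
* ``paper`` — the full-scale settings (1e6 pairs, batch size 64 for the
  quantification network, voxel-wise batch size 1 for the
  super-resolution network, 100 epochs, 45 subjects); recorded in the
  config but not executed by default.

Every random stage consumes a child seed derived deterministically from
the root seed; all outputs carry the config hash.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .core import KEP_RANGE, KTRANS_RANGE, VE_RANGE
from .protocol import DISPLACEMENT_SPAN_S

__all__ = ["RunConfig", "load_config", "validate_config", "config_hash", "child_seed"]

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    profile: str = "desk"
    # time grid
    n_steps: int = 130
    dt_s: float = 2.0
    # protocol
    precontrast_time_s: float = 10.0
    acq_window_s: float = 10.0
    gap_s: float = 20.0
    # quant-net simulation and training
    sim_n_pairs: int = 100_000
    sim_noise_sigma_range: tuple[float, float] = (0.01, 0.10)
    quant_hidden: tuple[int, ...] = (256, 256, 256)
    quant_loss_lambda: float = 0.998
    quant_batch_size: int = 256
    quant_epochs: int = 30
    # phantom cohort
    n_control: int = 9
    n_pdac: int = 6
    n_cp: int = 5
    voxels_per_subject: int = 1000
    cohort_noise_sigma: float = 0.03
    tumor_fraction: float = 0.35
    screen_threshold: float = 0.7
    # SR training
    sr_hidden: tuple[int, ...] = (128, 128)
    sr_lambda1: float = 0.1
    sr_lambda2: float = 0.1
    sr_batch_size: int = 256
    sr_epochs: int = 60
    sr_warmup_epochs: int = 30
    sr_pk_constraint: bool = True
    # shared optimizer schedule
    lr0: float = 1e-3
    lr_decay_factor: float = float(np.exp(-0.1))
    warmup_epochs: int = 10
    # evaluation
    n_folds: int = 10
    sweep_deltas: tuple[float, ...] = (-6.0, -4.0, -2.0, 0.0, 2.0, 4.0)
    schema_version: int = CONFIG_SCHEMA_VERSION

    def as_dict(self) -> dict:
        return asdict(self)


#: full-scale settings layered on top of the defaults
PAPER_OVERRIDES = dict(
    profile="paper",
    sim_n_pairs=1_000_000,
    quant_batch_size=64,
    quant_epochs=100,
    n_control=22,
    n_pdac=14,
    n_cp=9,
    sr_batch_size=1,
    sr_epochs=100,
)


def with_profile(cfg: RunConfig, profile: str) -> RunConfig:
    if profile == "desk":
        return replace(cfg, profile="desk")
    if profile == "paper":
        return replace(cfg, **PAPER_OVERRIDES)
    raise ValueError(f"unknown profile {profile!r} (expected 'desk' or 'paper')")


def load_config(path=None, profile: str | None = None, seed: int | None = None) -> RunConfig:
    """Load a TOML config file; missing keys take the defaults."""
    data = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("sim_noise_sigma_range", "quant_hidden", "sr_hidden", "sweep_deltas"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    if profile is not None:
        cfg = with_profile(cfg, profile)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def child_seed(root_seed: int, stream: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{root_seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def validate_config(cfg: RunConfig) -> list[str]:
    """Range/unit/feasibility diagnostics; empty list means valid."""
    diags: list[str] = []
    if cfg.dt_s <= 0:
        diags.append(f"grid step dt_s must be positive, got {cfg.dt_s}")
    if cfg.n_steps <= 0:
        diags.append(f"n_steps must be positive, got {cfg.n_steps}")
    lo, hi = cfg.sim_noise_sigma_range
    if not 0 <= lo <= hi:
        diags.append(f"invalid noise sigma range {cfg.sim_noise_sigma_range}")
    if not 0 <= cfg.quant_loss_lambda <= 1:
        diags.append(f"loss lambda must be in [0, 1], got {cfg.quant_loss_lambda}")
    if cfg.sr_lambda1 < 0 or cfg.sr_lambda2 < 0:
        diags.append("SR loss weights must be non-negative")
    span = DISPLACEMENT_SPAN_S
    for d in cfg.sweep_deltas:
        if not span[0] <= d <= span[1]:
            diags.append(
                f"sweep displacement {d} s outside the allowed span {span} s"
            )
    n_subjects = cfg.n_control + cfg.n_pdac + cfg.n_cp
    if n_subjects < cfg.n_folds:
        diags.append(
            f"{cfg.n_folds}-fold CV infeasible with {n_subjects} subjects"
        )
    for name, rng in (("ktrans", KTRANS_RANGE), ("kep", KEP_RANGE), ("ve", VE_RANGE)):
        if rng[0] >= rng[1]:
            diags.append(f"degenerate {name} simulation range {rng}")
    if cfg.sim_n_pairs < 1:
        diags.append("sim_n_pairs must be >= 1")
    if cfg.screen_threshold <= 0:
        diags.append("screen threshold must be positive")
    return diags
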