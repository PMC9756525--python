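"""Run configuration: defaults, YAML loading, and CLI-flag precedence.

Defaults are the reference operating point (d1=128, four protein conv
layers, alpha=0.5, lambda=0.1, Adam at 5e-4 with a 20-epoch step
schedule).  Precedence: CLI flags > config file > defaults.  Unknown keys
in a config file are rejected so typos cannot silently fall back to a
default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_resolved_config"]


@dataclass
class RunConfig:
    """Union of model and optimisation hyperparameters."""

    # model
    d0: int = 768
    d1: int = 128
    n_conv_layers: int = 4
    gnn_layers: int = 3
    alpha: float = 0.5
    kernel_size: int = 7
    leaky_slope: float = 0.01
    site_routing: str = "combine"
    affinity_routing: str = "evo"
    standardize_blosum: bool = False
    # optimisation
    learning_rate: float = 5e-4
    lr_step: int = 20
    lr_gamma: float = 0.9
    epochs: int = 200
    batch_size: int = 16
    lam: float = 0.1
    seed: int = 0

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            d0=self.d0, d1=self.d1, n_conv_layers=self.n_conv_layers,
            gnn_layers=self.gnn_layers, alpha=self.alpha,
            kernel_size=self.kernel_size, leaky_slope=self.leaky_slope,
            site_routing=self.site_routing,
            affinity_routing=self.affinity_routing,
            standardize_blosum=self.standardize_blosum, seed=self.seed)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, lr_step=self.lr_step,
            lr_gamma=self.lr_gamma, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.seed, lam=self.lam)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from defaults, an optional YAML file,
    and explicit overrides (e.g. CLI flags), in increasing precedence."""
    valid = {f.name: f for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        for key, val in loaded.items():
            if key not in valid:
                raise ValueError(
                    f"{path}: unknown config key '{key}'; valid keys: "
                    f"{sorted(valid)}")
            values[key] = val
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key not in valid:
            raise ValueError(f"unknown config key '{key}'")
        values[key] = val
    # type check before constructing
    for key, val in values.items():
        ftype = valid[key].type
        if ftype in ("int", int) and not isinstance(val, int):
            raise ValueError(f"config key '{key}' must be an integer, "
                             f"got {val!r}")
        if ftype in ("float", float) and not isinstance(val, (int, float)):
            raise ValueError(f"config key '{key}' must be a number, "
                             f"got {val!r}")
        if ftype in ("str", str) and not isinstance(val, str):
            raise ValueError(f"config key '{key}' must be a string, "
                             f"got {val!r}")
        if ftype in ("bool", bool) and not isinstance(val, bool):
            raise ValueError(f"config key '{key}' must be a boolean, "
                             f"got {val!r}")
    return RunConfig(**values)


def save_resolved_config(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the fully resolved configuration for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config_resolved.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return path
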