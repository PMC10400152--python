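"""Run configuration and seed derivation for the pipeline commands.

All randomness in a pipeline run flows from one root seed; each stage
derives its own child seed from the root and the stage name, so a
subcommand rerun reproduces the state it had inside a full run.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "derive_seed", "config_hash", "load_config"]


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (always below 2**31)."""
    return (int(root_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Defaults mirror the study protocol: 10 nm binning, 10-fold CV,
    1-30 latent variables, 4x3 MLP grid, spike n=20, sweep sizes 10-50
    from a 50-sample pool."""

    library_path: str = "library.csv"
    external_paths: dict[str, str] = field(default_factory=dict)
    out_dir: str = "out"
    window_nm: float = 10.0
    k_folds: int = 10
    methods: tuple[str, ...] = ("plsr", "mlp")
    traits: tuple[str, ...] = ("N", "P", "K", "Mg", "Ca", "S", "LWC", "CHL", "LMA")
    plsr_grid: tuple[int, ...] = tuple(range(1, 31))
    mlp_hidden: tuple[int, ...] = (5, 10, 15, 20)
    mlp_l2: tuple[float, ...] = (0.005, 0.01, 0.03)
    n_spike: int = 20
    sweep_sizes: tuple[int, ...] = (10, 20, 30, 40, 50)
    sweep_pool: int = 50
    sweep_set: str = "soybean"
    seed: int = 0
    # simulation knobs (cmd_simulate)
    sim_scale: str = "demo"  # "demo" | "full"
    noise_sd: float = 0.004
    shift_magnitude: float = 1.0

    @property
    def mlp_grid(self) -> tuple[tuple[int, float], ...]:
        return tuple((h, l2) for h in self.mlp_hidden for l2 in self.mlp_l2)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (the output location is not
    part of what the run computes)."""
    payload = asdict(cfg)
    payload.pop("out_dir")
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing keys keep their defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("methods", "traits", "plsr_grid", "mlp_hidden", "mlp_l2", "sweep_sizes"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)
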