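"""Run configuration: validated, defaulted, reproducible.

A run is fully described by a YAML or JSON mapping.  Unknown keys are
rejected (typos in calibration constants are the classic silent failure),
defaults are filled in, and every run echoes its effective configuration
so outputs are reproducible bit-for-bit from the echo plus the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]

STAGES = ("simulate", "rheology", "frap", "msd", "coloc", "fret", "calcium")

#: calibration keys each stage cannot run without
REQUIRED_BY_STAGE = {
    "rheology": ("k1_pn_um", "k2_pn_um", "theta0", "droplet_diameter_um"),
    "frap": ("bleach_radius_um",),
}


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: ["simulate", "rheology"])
    inputs: dict = field(default_factory=dict)     # stage -> path
    outdir: str = "results"
    seed: int = 0

    # calibration constants
    k1_pn_um: float | None = None
    k2_pn_um: float | None = None
    theta0: float | None = None
    droplet_diameter_um: float | None = None
    medium_viscosity_pa_s: float = 1e-3
    pixel_size_um: float = 0.1
    bleach_radius_um: float | None = None
    pressure_table_path: str | None = None

    # per-module thresholds and defaults
    step_amplitude_um: float = 0.1
    min_net_displacement_um: float = 2.0
    min_mean_speed_um_s: float = 0.2
    msd_max_lag_fraction: float = 0.25
    coloc_block_length_px: int = 16
    coloc_n_permutations: int = 1000
    frap_scheme: str = "full_scale"
    calcium_n_baseline: int = 100
    calcium_smooth_window: int = 5

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        for stage in self.stages:
            for key in REQUIRED_BY_STAGE.get(stage, ()):
                if getattr(self, key) is None:
                    raise ValueError(
                        f"stage {stage!r} requires calibration key {key!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def echo(self, path: str | Path) -> None:
        """Write the effective configuration next to the results."""
        doc = {"config": self.to_dict(), "config_hash": self.config_hash()}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected by name; missing keys take their defaults;
    calibration constants required by the requested stages must be present.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
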