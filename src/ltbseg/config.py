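"""Run configuration: one serializable record tying a pipeline run together.

Every CLI simulation writes its resolved configuration (YAML) next to its
outputs so any run can be replayed bit-for-bit from the saved file and master
seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Resolved settings for a simulation or fitting run."""

    seed: int = 0
    # stimulus defaults
    image_size: int = 256
    taper_width: float = 16.0
    n_p: int = 32
    A: float = 0.25
    sigma_mp: float = 2.0
    # first-stage filter geometry
    dog_sigma_c: float = 4.0
    dog_support_halfwidth: int = 16
    # experiment settings
    n_trials_staircase: int = 250
    n_per_condition: int = 200
    pi_ladder_levels: int = 9
    contrast_ladder_levels: int = 11
    # fitting settings
    bootstrap_B: int = 200
    rho_grid: tuple = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)
    # output
    out_dir: str = "."

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rho_grid" in data:
            data["rho_grid"] = tuple(data["rho_grid"])
        return cls(**data)
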