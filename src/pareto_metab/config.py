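"""Run configuration shared by the CLI pipeline.

Every numeric knob of the workflow lives here with its documented range
and default; the config is serialised verbatim into each stage's
manifest so runs can be reproduced bit-for-bit (deterministic stages)
or re-seeded (stochastic ones).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    # solver / tolerances
    solver: str = "highs"
    tau_feas: float = 1e-9
    tau_obj: float = 1e-6
    tau_pds: float = 1e-6
    # sampling
    grid_levels: int = 10
    primary_objective: str = "biomass"
    # cell-line fitting
    alpha: float = 0.5
    top_fraction: float = 0.01
    abundance_kernel: str = "spearman"
    exchange_kernel: str = "ccc"
    # target identification
    n_bins: int = 20
    score_cutoff: float = 0.8
    proximity_cutoff: float = 0.5
    proximity_tol: float = 0.25
    # perturbation
    knock_fraction: float = 0.0
    # reproducibility
    seed: int = 1

    _RANGES = {
        "tau_feas": (0.0, 1e-3),
        "tau_obj": (0.0, 1e-2),
        "tau_pds": (0.0, 1e-2),
        "grid_levels": (2, 10_000),
        "alpha": (0.0, 1.0),
        "top_fraction": (1e-9, 1.0),
        "n_bins": (3, 10_000),
        "score_cutoff": (0.0, 1.0),
        "proximity_cutoff": (0.0, 1.0),
        "proximity_tol": (0.0, 1.0),
        "knock_fraction": (0.0, 1.0),
    }

    def __post_init__(self):
        for name, (lo, hi) in self._RANGES.items():
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"config field {name}={val} outside [{lo}, {hi}]")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")

    def to_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if not f.name.startswith("_")
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


__all__ = ["RunConfig"]
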