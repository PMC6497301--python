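"""Run configuration: every tunable threshold in one round-trippable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All numeric knobs with their standard defaults.

    epsilon: flux-activation threshold for consistency/extraction.
    slack_threshold: |alpha| below which a gene counts as consistent.
    n_steps: grid size of the C sweep.
    essentiality_threshold: relative growth drop calling a gene essential.
    growth_fraction: minimum biomass fraction during exchange maximization.
    biomass_fraction: pinned biomass fraction in the drug-response proxy.
    rho_min / alpha_fdr: growth-correlated reaction selection.
    z_core / z_nonexpressed: expression discretization thresholds.
    """

    solver: str = "highs"
    epsilon: float = 1e-4
    slack_threshold: float = 1e-6
    n_steps: int = 500
    essentiality_threshold: float = 0.01
    growth_fraction: float = 0.9
    biomass_fraction: float = 0.5
    rho_min: float = 0.9
    alpha_fdr: float = 0.05
    z_core: float = 5.0
    z_nonexpressed: float = 0.0
    c_brk_tol: float = 1e-3
    changepoint_penalty: Optional[float] = None
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
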