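"""Measured phenotype tables used by calibration and the benchmark harness.

Per sample the container can hold: a measured growth rate (hr^-1) or a
doubling time (hr), exchange rates in fmol cell^-1 hr^-1 (uptake
positive; the sign flips when the rate becomes an uptake bound), a cell
volume in fL, an essential-gene set or dependency scores (negative
score = essential, the CERES convention), drug records (target reaction
plus measured IC50), and oncogene / tumor-suppressor / loss-of-function
annotation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import pandas as pd

from .model import doubling_time_to_growth

__all__ = ["DrugRecord", "SamplePhenotype", "PhenotypeData"]


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    target_reaction: str
    ic50: float


@dataclass
class SamplePhenotype:
    sample_id: str
    growth_rate: Optional[float] = None          # hr^-1
    doubling_time: Optional[float] = None        # hr
    exchange_rates: Dict[str, float] = field(default_factory=dict)  # fmol/cell/hr
    cell_volume: Optional[float] = None          # fL/cell
    essential_genes: Set[str] = field(default_factory=set)
    dependency_scores: Dict[str, float] = field(default_factory=dict)
    drugs: List[DrugRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.growth_rate is not None and self.growth_rate <= 0:
            raise ValueError("growth rate must be positive where present")
        if self.cell_volume is not None and self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def mu(self) -> Optional[float]:
        """Measured growth rate, deriving it from the doubling time if needed."""
        if self.growth_rate is not None:
            return self.growth_rate
        if self.doubling_time is not None:
            return doubling_time_to_growth(self.doubling_time)
        return None

    def essential_set(self) -> Set[str]:
        """Essential genes, from the explicit set plus negative dependency scores."""
        out = set(self.essential_genes)
        out |= {g for g, s in self.dependency_scores.items() if s < 0}
        return out


@dataclass
class PhenotypeData:
    samples: Dict[str, SamplePhenotype] = field(default_factory=dict)
    oncogenes: Set[str] = field(default_factory=set)
    tumor_suppressors: Set[str] = field(default_factory=set)
    lof_genes: Set[str] = field(default_factory=set)

    def __getitem__(self, sample_id: str) -> SamplePhenotype:
        return self.samples[sample_id]

    def add(self, sample: SamplePhenotype) -> None:
        self.samples[sample.sample_id] = sample

    # -- TSV I/O (documented headers) -------------------------------------
    def write_growth_tsv(self, path) -> None:
        rows = [
            {"sample": s.sample_id, "growth_rate": s.mu}
            for s in self.samples.values()
            if s.mu is not None
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_exchange_tsv(self, path) -> None:
        rows = []
        for s in self.samples.values():
            for rid, rate in s.exchange_rates.items():
                rows.append(
                    {
                        "sample": s.sample_id,
                        "exchange_id": rid,
                        "rate_fmol_per_cell_hr": rate,
                        "cell_volume_fl": s.cell_volume,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_growth_tsv(path) -> "PhenotypeData":
        df = pd.read_csv(path, sep="\t")
        pd_obj = PhenotypeData()
        for _, row in df.iterrows():
            pd_obj.add(
                SamplePhenotype(str(row["sample"]), growth_rate=float(row["growth_rate"]))
            )
        return pd_obj
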