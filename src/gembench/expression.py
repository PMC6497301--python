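"""Expression profiles: raw values, z-score views, discretized states.

Raw expression is nonnegative and in arbitrary units (the expression
scaling constant C of the bound-construction stage absorbs the unit).
The discretized view follows the core/moderate/nonexpressed convention
used by FASTCORE-family extractors: genes with z > 5 are core evidence,
genes with z < 0 are non-expressed, everything between is moderate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CORE",
    "MODERATE",
    "NONEXPRESSED",
    "ExpressionProfile",
    "discretize_expression",
    "read_expression_tsv",
    "write_expression_tsv",
]

CORE = "core"
MODERATE = "moderate"
NONEXPRESSED = "nonexpressed"

#: Default discretization thresholds on the z-score scale.
Z_CORE_THRESHOLD = 5.0
Z_NONEXPRESSED_THRESHOLD = 0.0


@dataclass
class ExpressionProfile:
    """Per-sample gene expression with optional z-score and state views."""

    sample_id: str
    values: Dict[str, float]
    zscores: Optional[Dict[str, float]] = None

    def __post_init__(self):
        for g, v in self.values.items():
            if v < 0:
                raise ValueError(f"expression of {g!r} is negative ({v})")

    @property
    def genes(self) -> List[str]:
        return list(self.values)

    def with_plain_zscores(self) -> "ExpressionProfile":
        """Attach (x - mean)/sd z-scores computed across this sample's genes.

        A plain stand-in for platform-calibrated z-scores (e.g. Barcode);
        adequate for synthetic data, not a normalization method.
        """
        x = np.array([self.values[g] for g in self.values], dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x))
        if sd == 0:
            sd = 1.0
        z = {g: (self.values[g] - mu) / sd for g in self.values}
        return ExpressionProfile(self.sample_id, dict(self.values), z)

    def states(
        self,
        hi: float = Z_CORE_THRESHOLD,
        lo: float = Z_NONEXPRESSED_THRESHOLD,
    ) -> Dict[str, str]:
        if self.zscores is None:
            raise ValueError("no z-score view attached; call with_plain_zscores()")
        return discretize_expression(self.zscores, hi=hi, lo=lo)

    def scaled(self, factor: float) -> "ExpressionProfile":
        return ExpressionProfile(
            self.sample_id,
            {g: v * factor for g, v in self.values.items()},
            dict(self.zscores) if self.zscores is not None else None,
        )


def discretize_expression(
    z: Dict[str, float],
    hi: float = Z_CORE_THRESHOLD,
    lo: float = Z_NONEXPRESSED_THRESHOLD,
) -> Dict[str, str]:
    """Map z-scores to {core, moderate, nonexpressed} states.

    core iff z > hi; nonexpressed iff z < lo; otherwise moderate.
    NaN z-scores are omitted with a warning.
    """
    states: Dict[str, str] = {}
    for g, v in z.items():
        if not np.isfinite(v):
            warnings.warn(f"gene {g!r} has non-finite z-score; omitted")
            continue
        if v > hi:
            states[g] = CORE
        elif v < lo:
            states[g] = NONEXPRESSED
        else:
            states[g] = MODERATE
    return states


def read_expression_tsv(path) -> List[ExpressionProfile]:
    """Read a genes-by-samples TSV (first column = gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        ExpressionProfile(str(col), {str(g): float(v) for g, v in df[col].items()})
        for col in df.columns
    ]


def write_expression_tsv(profiles: List[ExpressionProfile], path) -> None:
    genes = sorted({g for p in profiles for g in p.values})
    df = pd.DataFrame(
        {p.sample_id: [p.values.get(g, 0.0) for g in genes] for p in profiles},
        index=pd.Index(genes, name="gene"),
    )
    df.to_csv(path, sep="\t")
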