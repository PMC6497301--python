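"""Metabolic model container, serialization, media and unit conversions.

The central data structure is :class:`MetabolicModel`: a stoichiometric
matrix ``S`` (metabolites x reactions), per-reaction flux bounds in
mmol gDW^-1 hr^-1, GPR rules, and a biomass objective.  Exchange
reactions are the single-metabolite columns of ``S``; the sign
convention is the COBRA one (negative flux = uptake, positive =
secretion).

Two on-disk dialects are supported: a plain JSON dialect that
round-trips bit-exactly, and SBML Level 3 + FBC (read and written
through cobrapy, so only the semantic content is preserved).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .gpr import GprNode, evaluate_gpr, gpr_genes, parse_gpr

__all__ = [
    "ModelValidationError",
    "MetabolicModel",
    "MediumSpec",
    "read_model",
    "write_model",
    "apply_medium",
    "convert_uptake_rate",
    "doubling_time_to_growth",
    "CELL_SPECIFIC_VOLUME_ML_PER_GDW",
]

#: Cell specific volume (mL gDW^-1) used to convert per-cell exchange
#: rates to per-dry-weight rates.  A mammalian-cell literature value;
#: configurable because other cell types differ.
CELL_SPECIFIC_VOLUME_ML_PER_GDW = 4.3


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class MetabolicModel:
    """An immutable-by-convention genome-scale metabolic model.

    Parameters
    ----------
    metabolite_ids, reaction_ids, gene_ids
        Identifier lists; order fixes the rows/columns of ``S``.
    S
        Dense stoichiometric matrix, shape (n_metabolites, n_reactions).
    lb, ub
        Flux bounds, mmol gDW^-1 hr^-1.
    gpr
        Per-reaction GPR rule string ('' when none).
    objective_id
        Reaction id of the biomass/objective reaction.
    """

    metabolite_ids: List[str]
    reaction_ids: List[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gene_ids: List[str]
    gpr: List[str]
    objective_id: str
    model_id: str = "model"
    _gpr_trees: Optional[List[Optional[GprNode]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def exchange_ids(self) -> List[str]:
        """Reactions whose stoichiometric column touches exactly one metabolite."""
        counts = np.count_nonzero(self.S, axis=0)
        return [r for r, c in zip(self.reaction_ids, counts) if c == 1]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}")

    def gpr_tree(self, i: int) -> Optional[GprNode]:
        if self._gpr_trees is None:
            self._gpr_trees = [parse_gpr(r) for r in self.gpr]
        return self._gpr_trees[i]

    def genes_of_reaction(self, i: int) -> frozenset:
        return gpr_genes(self.gpr_tree(i))

    def reactions_of_gene(self, gene: str) -> List[int]:
        """Indices of reactions whose GPR references ``gene`` (the set R_j)."""
        return [i for i in range(self.n_reactions) if gene in self.genes_of_reaction(i)]

    def reaction_enabled(self, i: int, knocked_out) -> bool:
        """GPR satisfiability of reaction ``i`` with ``knocked_out`` genes absent."""
        present = set(self.gene_ids) - set(knocked_out)
        return evaluate_gpr(self.gpr_tree(i), present)

    def validate(self) -> None:
        n, m = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n, m):
            raise ModelValidationError(
                f"S shape {self.S.shape} != ({n}, {m})"
            )
        if len(self.lb) != m or len(self.ub) != m or len(self.gpr) != m:
            raise ModelValidationError("lb/ub/gpr length mismatch with reactions")
        if np.any(self.lb > self.ub + 1e-12):
            bad = self.reaction_ids[int(np.argmax(self.lb - self.ub))]
            raise ModelValidationError(f"lb > ub for reaction {bad!r}")
        if self.reaction_ids and self.objective_id not in self.reaction_ids:
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        gene_set = set(self.gene_ids)
        for rid, rule in zip(self.reaction_ids, self.gpr):
            for g in gpr_genes(parse_gpr(rule)):
                if g not in gene_set:
                    raise ModelValidationError(
                        f"GPR of {rid!r} references unknown gene {g!r}"
                    )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gene_ids=list(self.gene_ids),
            gpr=list(self.gpr),
            objective_id=self.objective_id,
            model_id=self.model_id,
        )

    def with_bounds(self, lb: np.ndarray, ub: np.ndarray) -> "MetabolicModel":
        m = self.copy()
        m.lb = np.asarray(lb, dtype=float)
        m.ub = np.asarray(ub, dtype=float)
        m.validate()
        return m

    def subset(self, keep_reaction_ids) -> "MetabolicModel":
        """Submodel restricted to ``keep_reaction_ids`` (order preserved).

        Metabolites no longer touched by any kept reaction are dropped.
        """
        keep = [r for r in self.reaction_ids if r in set(keep_reaction_ids)]
        cols = [self.reaction_index(r) for r in keep]
        S = self.S[:, cols]
        rows = np.flatnonzero(np.count_nonzero(S, axis=1) > 0)
        gprs = [self.gpr[c] for c in cols]
        genes = sorted(set().union(*[gpr_genes(parse_gpr(g)) for g in gprs]) or set())
        return MetabolicModel(
            metabolite_ids=[self.metabolite_ids[r] for r in rows],
            reaction_ids=keep,
            S=S[rows, :],
            lb=self.lb[cols].copy(),
            ub=self.ub[cols].copy(),
            gene_ids=genes,
            gpr=gprs,
            objective_id=self.objective_id
            if self.objective_id in keep
            else (keep[0] if keep else self.objective_id),
            model_id=self.model_id + "_sub",
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolite_ids == other.metabolite_ids
            and self.reaction_ids == other.reaction_ids
            and np.array_equal(self.S, other.S)
            and np.array_equal(self.lb, other.lb)
            and np.array_equal(self.ub, other.ub)
            and self.gene_ids == other.gene_ids
            and self.gpr == other.gpr
            and self.objective_id == other.objective_id
        )


@dataclass(frozen=True)
class MediumSpec:
    """Maximum uptake magnitudes per exchange reaction (mmol gDW^-1 hr^-1, >=0).

    ``cell_specific`` flags a medium built from measured exometabolomic
    rates, as opposed to a general in-silico growth medium.
    """

    uptake: Dict[str, float]
    cell_specific: bool = False

    def __post_init__(self):
        for k, v in self.uptake.items():
            if v < 0:
                raise ValueError(f"uptake magnitude for {k!r} must be >= 0, got {v}")

    def filled_from(self, general: "MediumSpec") -> "MediumSpec":
        """Fill exchange rates missing from this medium with the general ones."""
        merged = dict(general.uptake)
        merged.update(self.uptake)
        return MediumSpec(uptake=merged, cell_specific=self.cell_specific)


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of ``model`` with uptake bounds set from ``medium``.

    For every keyed exchange reaction the lower bound becomes
    ``-magnitude`` (negative flux = uptake); unkeyed exchanges are left
    unchanged.  Idempotent for a fixed medium.
    """
    exch = set(model.exchange_ids)
    out = model.copy()
    for rid, mag in medium.uptake.items():
        if rid not in exch:
            raise KeyError(f"medium keys must be exchange reactions; {rid!r} is not")
        out.lb[out.reaction_index(rid)] = -float(mag)
    out.validate()
    return out


def convert_uptake_rate(
    c_met: float, v_cell: float, specific_volume: float = CELL_SPECIFIC_VOLUME_ML_PER_GDW
) -> float:
    """Convert a per-cell exchange rate to a per-dry-weight flux bound.

    Parameters
    ----------
    c_met : measured exchange rate, fmol cell^-1 hr^-1 (uptake positive).
    v_cell : cell volume, fL cell^-1.
    specific_volume : cell specific volume, mL gDW^-1 (default 4.3).

    Returns
    -------
    Uptake bound in mmol gDW^-1 hr^-1: ``specific_volume * c_met / v_cell``.
    """
    if v_cell <= 0:
        raise ValueError(f"cell volume must be positive, got {v_cell}")
    return specific_volume * c_met / v_cell


def doubling_time_to_growth(dt: float) -> float:
    """Growth rate (hr^-1) from a doubling time (hr): ln(2)/dt."""
    if dt <= 0:
        raise ValueError(f"doubling time must be positive, got {dt}")
    return math.log(2.0) / dt


# -- serialization ---------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    reactions = []
    for i, rid in enumerate(model.reaction_ids):
        col = model.S[:, i]
        mets = {
            model.metabolite_ids[j]: float(col[j]) for j in np.flatnonzero(col)
        }
        reactions.append(
            {
                "id": rid,
                "mets": mets,
                "lb": float(model.lb[i]),
                "ub": float(model.ub[i]),
                "gpr": model.gpr[i],
            }
        )
    return {
        "id": model.model_id,
        "metabolites": list(model.metabolite_ids),
        "genes": list(model.gene_ids),
        "reactions": reactions,
        "objective": model.objective_id,
    }


def _model_from_dict(d: dict) -> MetabolicModel:
    try:
        mets = list(d["metabolites"])
        genes = list(d.get("genes", []))
        reactions = d["reactions"]
        objective = d["objective"]
    except KeyError as e:
        raise ModelValidationError(f"model JSON missing key {e}")
    met_idx = {m: j for j, m in enumerate(mets)}
    n, m = len(mets), len(reactions)
    S = np.zeros((n, m))
    lb = np.zeros(m)
    ub = np.zeros(m)
    rids, gprs = [], []
    for i, r in enumerate(reactions):
        rids.append(r["id"])
        for mid, coef in r["mets"].items():
            if mid not in met_idx:
                raise ModelValidationError(
                    f"reaction {r['id']!r} references unknown metabolite {mid!r}"
                )
            S[met_idx[mid], i] = float(coef)
        lb[i] = float(r["lb"])
        ub[i] = float(r["ub"])
        gprs.append(r.get("gpr", ""))
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=lb,
        ub=ub,
        gene_ids=genes,
        gpr=gprs,
        objective_id=objective,
        model_id=d.get("id", "model"),
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (for SBML I/O and cross-checks)."""
    import cobra

    cm = cobra.Model(model.model_id)
    cmets = {
        mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids
    }
    for g in model.gene_ids:
        cm.genes.append(cobra.Gene(g))
    rxns = []
    for i, rid in enumerate(model.reaction_ids):
        rx = cobra.Reaction(
            rid, lower_bound=float(model.lb[i]), upper_bound=float(model.ub[i])
        )
        rxns.append(rx)
    cm.add_reactions(rxns)
    for i, rx in enumerate(rxns):
        col = model.S[:, i]
        rx.add_metabolites(
            {cmets[model.metabolite_ids[j]]: float(col[j]) for j in np.flatnonzero(col)}
        )
        if model.gpr[i]:
            rx.gene_reaction_rule = model.gpr[i]
    cm.objective = model.objective_id
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy Model to a MetabolicModel."""
    mets = [m.id for m in cm.metabolites]
    met_idx = {m: j for j, m in enumerate(mets)}
    rids = [r.id for r in cm.reactions]
    n, m = len(mets), len(rids)
    S = np.zeros((n, m))
    lb = np.zeros(m)
    ub = np.zeros(m)
    gprs = []
    for i, r in enumerate(cm.reactions):
        for met, coef in r.metabolites.items():
            S[met_idx[met.id], i] = float(coef)
        lb[i], ub[i] = r.lower_bound, r.upper_bound
        gprs.append(r.gene_reaction_rule or "")
    objective = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    if objective is None:
        raise ModelValidationError("SBML model has no objective reaction")
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=lb,
        ub=ub,
        gene_ids=[g.id for g in cm.genes],
        gpr=gprs,
        objective_id=objective,
        model_id=cm.id or "model",
    )


def read_model(path, dialect: str = "json") -> MetabolicModel:
    """Read a model from ``path`` in the named dialect ('json' or 'sbml')."""
    path = Path(path)
    if dialect == "json":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as e:
                raise ModelValidationError(f"cannot parse {path}: {e}")
        return _model_from_dict(d)
    if dialect == "sbml":
        import cobra.io

        return from_cobra(cobra.io.read_sbml_model(str(path)))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path, dialect: str = "json") -> None:
    """Write a model to ``path`` in the named dialect."""
    path = Path(path)
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if dialect == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
        return
    raise ValueError(f"unknown dialect {dialect!r}")
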