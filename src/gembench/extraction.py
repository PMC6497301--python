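"""Context-specific subnetwork extraction (FASTCORE family).

Given a flux-consistent parent network and a set of *core* reactions
that the context model must contain, FASTCORE finds a flux-consistent
subnetwork containing every core reaction while adding approximately
the minimal number of non-core reactions, by alternating two LPs:
LP-7 activates as many not-yet-supported core reactions as possible,
and a weighted L1 minimization (LP-9) sparsifies the non-core support
of the resulting mode.

The weighted variant used by the reconstruction pipeline additionally
takes per-reaction penalties derived from discretized expression:
moderately-expressed reactions cost nothing to include, non-expressed
reactions carry full penalty, and the biomass reaction together with a
parsimonious flux mode supporting it is forced into the core so the
extracted model always grows when the parent does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import numpy as np

from .consistency import DEFAULT_EPSILON, fastcc
from .expression import CORE, MODERATE, NONEXPRESSED
from .lp import fba, pfba, solve_lp
from .model import MetabolicModel

__all__ = [
    "CoreSpec",
    "ContextModel",
    "core_from_states",
    "fastcore",
    "fastcormics_modified",
]


@dataclass
class CoreSpec:
    """Reaction sets steering extraction."""

    core: Set[str] = field(default_factory=set)
    non_penalized: Set[str] = field(default_factory=set)
    forced: Set[str] = field(default_factory=set)

    def resolve(self, model: MetabolicModel) -> None:
        known = set(model.reaction_ids)
        for name, s in (("core", self.core), ("non_penalized", self.non_penalized),
                        ("forced", self.forced)):
            unknown = s - known
            if unknown:
                raise KeyError(f"{name} set contains unknown reactions: {sorted(unknown)}")

    @property
    def all_core(self) -> Set[str]:
        return self.core | self.forced


@dataclass
class ContextModel:
    """An extracted submodel plus provenance."""

    model: MetabolicModel
    parent_id: str
    core_spec: CoreSpec
    method: str
    epsilon: float
    C: Optional[float] = None
    provenance: Dict = field(default_factory=dict)

    @property
    def reaction_ids(self) -> List[str]:
        return self.model.reaction_ids

    def provenance_dict(self) -> Dict:
        d = {
            "parent": self.parent_id,
            "method": self.method,
            "epsilon": self.epsilon,
            "C": self.C,
            "core": sorted(self.core_spec.core),
            "forced": sorted(self.core_spec.forced),
            "non_penalized": sorted(self.core_spec.non_penalized),
            "n_reactions": len(self.reaction_ids),
        }
        d.update(self.provenance)
        return d


def core_from_states(
    model: MetabolicModel,
    states: Dict[str, str],
    include_biomass: bool = True,
    warn_empty: bool = True,
) -> CoreSpec:
    """Map gene states to a reaction CoreSpec through the GPR rules.

    A reaction is core iff its GPR is satisfied when exactly the
    core-state genes are present.  Reactions whose GPR is satisfied by
    core+moderate genes (but not by core alone) are non-penalized.  The
    biomass reaction joins the forced set.
    """
    covered = set(states) & set(model.gene_ids)
    if not covered:
        raise ValueError("states cover no model gene")
    core_genes = {g for g, s in states.items() if s == CORE}
    soft_genes = core_genes | {g for g, s in states.items() if s == MODERATE}
    spec = CoreSpec()
    from .gpr import evaluate_gpr

    for i, rid in enumerate(model.reaction_ids):
        tree = model.gpr_tree(i)
        if tree is None:
            continue
        if evaluate_gpr(tree, core_genes):
            spec.core.add(rid)
        elif evaluate_gpr(tree, soft_genes):
            spec.non_penalized.add(rid)
    if include_biomass:
        spec.forced.add(model.objective_id)
    if not spec.core and warn_empty:
        import warnings

        warnings.warn("expression states yield an empty core reaction set")
    return spec


# -- FASTCORE internals ----------------------------------------------------

def _lp7(S, lb, ub, J, eps):
    from .consistency import _lp7 as base

    return base(S, lb, ub, J, eps)


def _lp9(S, lb, ub, K: List[int], P: List[int], weights: np.ndarray, eps: float):
    """Minimize the weighted L1 norm over penalty reactions while forcing
    every reaction in K to carry flux >= eps.

    min sum_{i in P} w_i t_i   s.t.  S v = 0, bounds, v_k >= eps (k in K),
                                     -t_i <= v_i <= t_i.
    """
    n = S.shape[1]
    p = len(P)
    S2 = np.hstack([S, np.zeros((S.shape[0], p))])
    lb2 = np.concatenate([lb, np.zeros(p)])
    big = max(np.max(np.abs(lb)), np.max(np.abs(ub)), 1.0)
    ub2 = np.concatenate([ub, np.full(p, big)])
    lb2 = lb2.copy()
    for k in K:
        lb2[k] = max(lb2[k], eps)
    rows = []
    for row, i in enumerate(P):
        r1 = np.zeros(n + p); r1[i] = 1.0; r1[n + row] = -1.0   # v_i - t_i <= 0
        r2 = np.zeros(n + p); r2[i] = -1.0; r2[n + row] = -1.0  # -v_i - t_i <= 0
        rows.extend([r1, r2])
    c = np.zeros(n + p)
    for row, i in enumerate(P):
        c[n + row] = weights[i]
    A = np.vstack(rows) if rows else None
    b = np.zeros(2 * p) if rows else None
    status, x, _ = solve_lp(S2, lb2, ub2, c, "min", A, b)
    if status != "optimal":
        return None
    return x[:n]


def _support(v, eps):
    return set(np.flatnonzero(np.abs(v) >= 0.99 * eps))


def _find_sparse_mode(S, lb, ub, J, P, weights, eps, singleton):
    if not J:
        return set()
    Ji = [sorted(J)[0]] if singleton else sorted(J)
    v = _lp7(S, lb, ub, Ji, eps)
    if v is None:
        return set()
    K = sorted(_support(v, eps) & set(Ji))
    if not K:
        return set()
    v = _lp9(S, lb, ub, K, sorted(P), weights, eps)
    if v is None:
        return set()
    return _support(v, eps)


def _fastcore_indices(
    model: MetabolicModel,
    core_idx: Set[int],
    weights: np.ndarray,
    eps: float,
) -> Set[int]:
    """Weighted FASTCORE iteration over reaction indices."""
    n = model.n_reactions
    S = model.S.copy()
    lb = model.lb.copy()
    ub = model.ub.copy()
    irreversible = set(np.flatnonzero(model.lb >= 0))

    def penalty_set(A):
        return {i for i in range(n) if i not in core_idx and i not in A}

    flipped = False
    singleton = False
    J = sorted(core_idx & irreversible)
    A = _find_sparse_mode(S, lb, ub, J, penalty_set(set()), weights, eps, False)
    if set(J) - A:
        missing = sorted(set(J) - A)
        raise ValueError(
            "inconsistent core: reactions cannot be activated: "
            + ", ".join(model.reaction_ids[i] for i in missing)
        )
    J = sorted(core_idx - A)
    while J:
        P = penalty_set(A)
        supp = _find_sparse_mode(S, lb, ub, J, P, weights, eps, singleton)
        A |= supp
        if set(J) & A:
            J = sorted(set(J) - A)
            flipped = False
            singleton = False
        else:
            Ji = [J[0]] if singleton else J
            rev = [i for i in Ji if i not in irreversible]
            if flipped or not rev:
                if singleton:
                    raise ValueError(
                        f"cannot activate core reaction {model.reaction_ids[J[0]]!r}"
                    )
                flipped = False
                singleton = True
            else:
                for i in rev:
                    lb[i], ub[i] = -ub[i], -lb[i]
                    S[:, i] = -S[:, i]
                flipped = True
    return A


def fastcore(
    model: MetabolicModel,
    core: CoreSpec,
    epsilon: float = DEFAULT_EPSILON,
) -> ContextModel:
    """Extract a minimal flux-consistent subnetwork containing the core.

    Non-penalized reactions cost nothing to include; every other
    non-core reaction costs 1.  Ties among equal-cost additions break
    lexicographically by reaction id (the LP candidate ordering), making
    extraction deterministic.
    """
    core.resolve(model)
    core_ids = core.all_core
    # core reactions must be unblocked in the parent
    parent_blocked = fastcc(model, epsilon).blocked
    bad = sorted(core_ids & parent_blocked)
    if bad:
        raise ValueError(f"core contains blocked reactions: {bad}")
    if not core_ids:
        empty = model.subset([])
        return ContextModel(empty, model.model_id, core, "fastcore", epsilon)
    # deterministic candidate order: lexicographic by reaction id
    order = sorted(range(model.n_reactions), key=lambda i: model.reaction_ids[i])
    reordered = model.subset([model.reaction_ids[i] for i in order])
    idx = {rid: i for i, rid in enumerate(reordered.reaction_ids)}
    weights = np.ones(reordered.n_reactions)
    for rid in core.non_penalized:
        weights[idx[rid]] = 0.0
    core_idx = {idx[r] for r in core_ids}
    A = _fastcore_indices(reordered, core_idx, weights, epsilon)
    keep = [reordered.reaction_ids[i] for i in sorted(A)]
    # restore the parent's reaction order
    keep_in_parent = [r for r in model.reaction_ids if r in set(keep)]
    sub = model.subset(keep_in_parent)
    return ContextModel(sub, model.model_id, core, "fastcore", epsilon)


def fastcormics_modified(
    model: MetabolicModel,
    core: CoreSpec,
    states: Dict[str, str],
    epsilon: float = DEFAULT_EPSILON,
) -> ContextModel:
    """Expression-weighted FASTCORE with forced biomass support.

    Extends :func:`fastcore` with (i) the biomass reaction plus a
    parsimonious flux mode supporting it pre-seeded into the core, so
    the output is always functional when the parent grows, and (ii)
    penalties from gene states: reactions satisfiable with moderately-
    expressed genes are non-penalized, reactions only satisfiable with
    non-expressed genes carry full penalty.
    """
    core.resolve(model)
    grow = fba(model)
    if not grow.optimal or grow.objective_value <= 0:
        raise ValueError("parent model cannot produce biomass; nothing to force")
    support_sol = pfba(model)
    support = {
        rid for rid, v in support_sol.fluxes.items() if abs(v) > 1e-9
    }
    spec = CoreSpec(
        core=set(core.core),
        non_penalized=set(core.non_penalized),
        forced=set(core.forced) | {model.objective_id} | support,
    )
    # expression evidence: core-state reactions are required, reactions
    # satisfiable with moderate genes are non-penalized
    state_spec = (
        core_from_states(model, states, include_biomass=False, warn_empty=False)
        if states
        else CoreSpec()
    )
    spec.core |= state_spec.core
    spec.non_penalized |= state_spec.non_penalized
    spec.non_penalized -= spec.all_core
    ctx = fastcore(model, spec, epsilon)
    ctx.method = "fastcormics_modified"
    ctx.provenance["biomass_support"] = sorted(support)
    out_growth = fba(ctx.model)
    ctx.provenance["growth"] = out_growth.objective_value if out_growth.optimal else 0.0
    return ctx
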