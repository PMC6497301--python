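"""Linear programming layer: FBA, pFBA, FVA, gene deletion, essentiality.

All LPs are steady-state flux problems

    opt  c.v   s.t.  S.v = 0,  lb <= v <= ub  (+ optional extra rows)

solved with the HiGHS solvers behind :func:`scipy.optimize.linprog`.
Extra inequality rows (``A_ub v <= b_ub``) carry expression-derived
bound constraints; extra equality rows pin the objective during the
parsimonious second stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .model import MetabolicModel

__all__ = [
    "FluxDistribution",
    "SolverError",
    "fba",
    "pfba",
    "fva",
    "single_gene_deletion",
    "essential_genes",
    "ESSENTIALITY_THRESHOLD",
]

#: Relative growth drop above which a knockout is called essential (1%).
ESSENTIALITY_THRESHOLD = 0.01

#: Numerical feasibility tolerance used when validating solutions.
FEAS_TOL = 1e-9


class SolverError(RuntimeError):
    """LP solver failed in a way that is not plain infeasibility."""


@dataclass
class FluxDistribution:
    """Solution of a flux LP."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def vector(self, reaction_ids: List[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_lp(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    sense: str = "max",
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    A_eq_extra: Optional[np.ndarray] = None,
    b_eq_extra: Optional[np.ndarray] = None,
) -> Tuple[str, Optional[np.ndarray], Optional[float]]:
    """Solve opt c.v s.t. S v = 0, bounds, optional extra rows.

    Returns (status, x, objective) with objective in the requested sense.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    sign = -1.0 if sense == "max" else 1.0
    A_eq = sp.csr_matrix(S)
    b_eq = np.zeros(S.shape[0])
    if A_eq_extra is not None:
        A_eq = sp.vstack([A_eq, sp.csr_matrix(np.atleast_2d(A_eq_extra))], format="csr")
        b_eq = np.concatenate([b_eq, np.atleast_1d(b_eq_extra)])
    kwargs = {}
    if A_ub is not None and len(A_ub):
        kwargs["A_ub"] = sp.csr_matrix(np.atleast_2d(A_ub))
        kwargs["b_ub"] = np.atleast_1d(b_ub)
    res = scipy.optimize.linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        **kwargs,
    )
    status = _STATUS.get(res.status, "numerical")
    if status == "optimal":
        return "optimal", res.x, sign * res.fun
    if status in ("infeasible", "unbounded"):
        return status, None, None
    raise SolverError(f"LP solver failure: {res.message}")


def _objective_vector(model: MetabolicModel, objective: str) -> np.ndarray:
    c = np.zeros(model.n_reactions)
    c[model.reaction_index(objective)] = 1.0
    return c


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
) -> FluxDistribution:
    """Flux balance analysis: optimize one reaction's flux at steady state."""
    objective = objective or model.objective_id
    c = _objective_vector(model, objective)
    status, x, obj = solve_lp(model.S, model.lb, model.ub, c, sense, A_ub, b_ub)
    if status != "optimal":
        return FluxDistribution({}, np.nan, status)
    return FluxDistribution(dict(zip(model.reaction_ids, x)), float(obj), "optimal")


def pfba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
) -> FluxDistribution:
    """Parsimonious FBA: among flux states attaining the FBA optimum,
    return one minimizing the total absolute flux (L1 norm).

    Two-stage LP.  Stage one fixes the optimal objective value; stage
    two splits every flux into nonnegative forward/backward parts and
    minimizes their sum.
    """
    objective = objective or model.objective_id
    first = fba(model, objective, "max", A_ub, b_ub)
    if not first.optimal:
        return first
    n = model.n_reactions
    obj_idx = model.reaction_index(objective)
    # variables: p (forward), q (backward); v = p - q
    lb2 = np.concatenate([np.maximum(model.lb, 0.0), np.maximum(-model.ub, 0.0)])
    ub2 = np.concatenate([np.maximum(model.ub, 0.0), np.maximum(-model.lb, 0.0)])
    S2 = np.hstack([model.S, -model.S])
    c2 = np.ones(2 * n)
    eq = np.zeros(2 * n)
    eq[obj_idx] = 1.0
    eq[n + obj_idx] = -1.0
    A_ub2 = None
    b_ub2 = None
    if A_ub is not None and len(A_ub):
        A = np.atleast_2d(A_ub)
        A_ub2 = np.hstack([A, -A])
        b_ub2 = np.atleast_1d(b_ub)
    status, x, _ = solve_lp(
        S2, lb2, ub2, c2, "min", A_ub2, b_ub2,
        A_eq_extra=eq, b_eq_extra=np.array([first.objective_value]),
    )
    if status != "optimal":
        # exact objective pin can be marginally infeasible; retry as a
        # one-sided bound relaxed by a hair
        slack = abs(first.objective_value) * 1e-9 + 1e-12
        row = (-eq)[None, :]
        rhs = np.array([-(first.objective_value - slack)])
        if A_ub2 is not None:
            row = np.vstack([A_ub2, row])
            rhs = np.concatenate([b_ub2, rhs])
        status, x, _ = solve_lp(S2, lb2, ub2, c2, "min", row, rhs)
        if status != "optimal":
            return FluxDistribution({}, np.nan, status)
    v = x[:n] - x[n:]
    return FluxDistribution(dict(zip(model.reaction_ids, v)), float(v[obj_idx]), "optimal")


def fva(
    model: MetabolicModel,
    reactions: Optional[List[str]] = None,
    objective_fraction: float = 0.0,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
) -> Dict[str, Tuple[float, float]]:
    """Flux variability analysis: per-reaction [min, max] flux.

    With ``objective_fraction`` > 0 the biomass flux is constrained to at
    least that fraction of its optimum.  With fraction 0 this is the
    blocked-reaction oracle: a reaction is blocked iff min = max = 0.
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    reactions = reactions if reactions is not None else list(model.reaction_ids)
    rows = [] if A_ub is None else [np.atleast_2d(A_ub)]
    rhs = [] if b_ub is None else [np.atleast_1d(b_ub)]
    if objective_fraction > 0:
        base = fba(model, A_ub=A_ub, b_ub=b_ub)
        if not base.optimal:
            raise SolverError("FVA requires an optimal base FBA when fraction > 0")
        row = np.zeros(model.n_reactions)
        row[model.reaction_index(model.objective_id)] = -1.0
        rows.append(row[None, :])
        rhs.append(np.array([-objective_fraction * base.objective_value]))
    A = np.vstack(rows) if rows else None
    b = np.concatenate(rhs) if rhs else None
    out: Dict[str, Tuple[float, float]] = {}
    for rid in reactions:
        c = _objective_vector(model, rid)
        lo_status, _, lo = solve_lp(model.S, model.lb, model.ub, c, "min", A, b)
        hi_status, _, hi = solve_lp(model.S, model.lb, model.ub, c, "max", A, b)
        if lo_status != "optimal" or hi_status != "optimal":
            raise SolverError(f"FVA subproblem for {rid!r}: {lo_status}/{hi_status}")
        out[rid] = (float(lo), float(hi))
    return out


def knockout_bounds(model: MetabolicModel, genes) -> Tuple[np.ndarray, np.ndarray]:
    """Bounds with every reaction disabled whose GPR fails without ``genes``."""
    lb, ub = model.lb.copy(), model.ub.copy()
    ko = set(genes)
    for i in range(model.n_reactions):
        if model.gpr[i] and not model.reaction_enabled(i, ko):
            lb[i] = ub[i] = 0.0
    return lb, ub


def single_gene_deletion(model: MetabolicModel, gene: str) -> float:
    """Maximal growth after knocking out ``gene`` (0 when infeasible)."""
    if gene not in model.gene_ids:
        raise KeyError(f"unknown gene {gene!r}")
    lb, ub = knockout_bounds(model, [gene])
    sol = fba(model.with_bounds(lb, ub))
    if not sol.optimal:
        return 0.0
    return max(sol.objective_value, 0.0)


def essential_genes(
    model: MetabolicModel, threshold: float = ESSENTIALITY_THRESHOLD
) -> set:
    """Genes whose knockout reduces maximal growth by more than ``threshold``.

    The default calls a gene essential when growth drops by more than 1%
    of the wild-type optimum.
    """
    wt = fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise ValueError("wild-type growth must be positive to define essentiality")
    g0 = wt.objective_value
    out = set()
    for g in model.gene_ids:
        gk = single_gene_deletion(model, g)
        if (g0 - gk) / g0 > threshold:
            out.add(g)
    return out
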