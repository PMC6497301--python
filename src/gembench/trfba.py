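"""Expression-constrained FBA (TRFBA-style) and the reconstruction pipeline.

The core idea: gene expression caps metabolic capacity.  For every gene
j with expression E_j, the summed flux through the reactions its GPR
touches is bounded by a scaled expression level,

    sum_{i in R_j} v_i  <=  C * E_j,

applied on the irreversible-split network so the sum adds nonnegative
flux magnitudes.  C (mmol gDW^-1 hr^-1 per expression unit) is the
single scaling constant converting expression units into flux units.

Growth is monotone nondecreasing in C.  Sweeping C from 0 to C_brk
(the smallest C at which growth reaches its unconstrained optimum)
yields a flux matrix whose rows can be correlated with predicted
growth: reactions with strong Spearman correlation across the sweep
are *growth-correlated* and become the core of a context-specific
extraction.  Two calibrations of C are provided:

* C_corr — expression-only: at each sweep point a QP replaces the
  inequality with an equality plus slack alpha_j and minimizes
  ||alpha||^2; the count N_alpha of near-zero slacks is tracked and the
  first sudden change of the series (piecewise-constant change-point
  detection) marks C_corr.
* C_opt — phenotype-aided: C_opt = (C_brk / G_max) * G_measured, the
  linear interpolation justified by the monotone growth-vs-C curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.stats import spearmanr

from .expression import ExpressionProfile
from .extraction import ContextModel, CoreSpec, fastcormics_modified
from .lp import FluxDistribution, fba, pfba
from .model import MediumSpec, MetabolicModel, apply_medium
from .stats import bh_adjust

__all__ = [
    "TrfbaConstraints",
    "build_trfba_model",
    "find_c_brk",
    "CSweepResult",
    "sweep_c",
    "GrowthCorrelatedSet",
    "growth_correlated_reactions",
    "qp_slack_minimize",
    "count_small_slacks",
    "detect_change_points",
    "detect_c_corr",
    "compute_c_opt",
    "TRFBACore",
    "TRFBACoreResults",
]

#: Slack magnitude below which a gene counts as flux/expression consistent.
SLACK_THRESHOLD = 1e-6

#: Default number of points discretizing [0, C_brk].
DEFAULT_N_STEPS = 500


# -- irreversible split + constraint structure -----------------------------

class TrfbaConstraints:
    """Irreversible split of a model plus per-gene expression rows.

    Precomputes the split network and the gene->split-reaction incidence
    matrix once; individual C values then only change the right-hand
    side C*E.
    """

    def __init__(self, model: MetabolicModel, expr: ExpressionProfile):
        for g, v in expr.values.items():
            if v < 0:
                raise ValueError(f"negative expression for gene {g!r}")
        self.parent = model
        n = model.n_reactions
        cols, lb2, ub2, rids2, gprs2 = [], [], [], [], []
        fwd = np.zeros(n, dtype=int)
        bwd = np.full(n, -1, dtype=int)
        for i in range(n):
            fwd[i] = len(cols)
            cols.append(model.S[:, i])
            lb2.append(max(model.lb[i], 0.0))
            ub2.append(max(model.ub[i], 0.0))
            rids2.append(model.reaction_ids[i] + "__f")
            gprs2.append(model.gpr[i])
            if model.lb[i] < 0:
                bwd[i] = len(cols)
                cols.append(-model.S[:, i])
                lb2.append(max(-model.ub[i], 0.0))
                ub2.append(-model.lb[i])
                rids2.append(model.reaction_ids[i] + "__b")
                gprs2.append(model.gpr[i])
        self.split = MetabolicModel(
            metabolite_ids=list(model.metabolite_ids),
            reaction_ids=rids2,
            S=np.column_stack(cols),
            lb=np.array(lb2),
            ub=np.array(ub2),
            gene_ids=list(model.gene_ids),
            gpr=gprs2,
            objective_id=model.objective_id + "__f",
            model_id=model.model_id + "_irrev",
        )
        self.fwd, self.bwd = fwd, bwd
        # covered genes: expression known, nonempty R_j
        genes, E, rows = [], [], []
        n_split = self.split.n_reactions
        for g in model.gene_ids:
            if g not in expr.values:
                continue
            R = model.reactions_of_gene(g)
            if not R:
                continue
            row = np.zeros(n_split)
            for i in R:
                row[fwd[i]] = 1.0
                if bwd[i] >= 0:
                    row[bwd[i]] = 1.0
            genes.append(g)
            E.append(expr.values[g])
            rows.append(row)
        self.genes = genes
        self.E = np.array(E)
        self.M = np.vstack(rows) if rows else np.zeros((0, n_split))
        if not genes:
            raise ValueError("expression covers no gene with reaction associations")

    # -- constrained solves ------------------------------------------------
    def constraint_rows(self, C: float) -> Tuple[np.ndarray, np.ndarray]:
        if C < 0:
            raise ValueError("C must be nonnegative")
        return self.M, C * self.E

    def growth(self, C: Optional[float]) -> float:
        """Maximal biomass flux at scaling constant C (None = unconstrained)."""
        if C is None:
            sol = fba(self.split)
        else:
            A, b = self.constraint_rows(C)
            sol = fba(self.split, A_ub=A, b_ub=b)
        return sol.objective_value if sol.optimal else 0.0

    def pfba_net_fluxes(self, C: Optional[float]) -> Tuple[np.ndarray, float, str]:
        """Parsimonious net fluxes in parent reaction space at C."""
        if C is None:
            sol = pfba(self.split)
        else:
            A, b = self.constraint_rows(C)
            sol = pfba(self.split, A_ub=A, b_ub=b)
        if not sol.optimal:
            return np.full(self.parent.n_reactions, np.nan), np.nan, sol.status
        x = sol.vector(self.split.reaction_ids)
        net = x[self.fwd]
        has_b = self.bwd >= 0
        net[has_b] -= x[self.bwd[has_b]]
        return net, sol.objective_value, "optimal"

    def slack_minimize(self, C: float) -> Tuple[np.ndarray, np.ndarray]:
        """Minimize ||alpha||^2 with sum_{i in R_j} v_i + alpha_j = C*E_j.

        Returns (alpha per covered gene, witness split-flux vector).
        Equivalent reduced form: min ||M v - C E||^2 over steady-state,
        box-bounded v; alpha = C E - M v.
        """
        if not hasattr(self, "_qp"):
            self._qp = _BoxEqLsqSolver(
                self.M, self.split.S, self.split.lb, self.split.ub
            )
        d = C * self.E
        v = self._qp.solve(d)
        return d - self.M @ v, v


def build_trfba_model(
    model: MetabolicModel, expr: ExpressionProfile, C: float
) -> Tuple[MetabolicModel, np.ndarray, np.ndarray]:
    """Irreversible-split model plus per-gene constraint rows at C.

    Returns (split_model, A_ub, b_ub) such that feasible split fluxes v
    satisfy A_ub v <= b_ub, one row per expression-covered gene.
    """
    tc = TrfbaConstraints(model, expr)
    A, b = tc.constraint_rows(C)
    return tc.split, A, b


# -- QP stage --------------------------------------------------------------

class _BoxEqLsqSolver:
    """min ||M v - d||^2  s.t.  S v = 0,  lb <= v <= ub  (convex QP).

    ADMM with the box constraint split off: the v-update is an
    equality-constrained least squares solved through a KKT system that
    is factorized once (M, S fixed; only d changes between calls), the
    z-update is a clip.  Warm-started between successive right-hand
    sides, which makes a C sweep cheap.  The objective value is unique
    by convexity even when v is not.
    """

    def __init__(self, M: np.ndarray, S: np.ndarray, lb: np.ndarray, ub: np.ndarray):
        import scipy.linalg

        self.M, self.lb, self.ub = M, lb, ub
        n = S.shape[1]
        # orthonormal basis of the row space of S: removes redundant
        # metabolite rows so the KKT matrix is nonsingular
        if S.size and np.any(S):
            _, sv, Vt = np.linalg.svd(S, full_matrices=False)
            r = int(np.sum(sv > sv[0] * 1e-12)) if len(sv) else 0
            self.E = Vt[:r]
        else:
            self.E = np.zeros((0, n))
        scale = float(np.linalg.norm(M, ord="fro") ** 2) / max(n, 1)
        self.rho = max(scale, 1.0)
        r = self.E.shape[0]
        K = np.zeros((n + r, n + r))
        K[:n, :n] = 2.0 * M.T @ M + self.rho * np.eye(n)
        K[:n, n:] = self.E.T
        K[n:, :n] = self.E
        self._lu = scipy.linalg.lu_factor(K)
        self._n = n
        self._z = np.clip(np.zeros(n), lb, ub)
        self._u = np.zeros(n)

    def solve(self, d: np.ndarray, tol: float = 1e-11, max_iter: int = 50000) -> np.ndarray:
        import scipy.linalg

        n = self._n
        z, u = self._z.copy(), self._u.copy()
        Mtd2 = 2.0 * self.M.T @ d
        rhs = np.zeros(n + self.E.shape[0])
        scale = max(1.0, float(np.linalg.norm(d)))
        v = z
        for _ in range(max_iter):
            rhs[:n] = Mtd2 + self.rho * (z - u)
            v = scipy.linalg.lu_solve(self._lu, rhs)[:n]
            z_old = z
            z = np.clip(v + u, self.lb, self.ub)
            u = u + v - z
            r_prim = float(np.max(np.abs(v - z)))
            r_dual = self.rho * float(np.max(np.abs(z - z_old)))
            if r_prim < tol * scale and r_dual < tol * scale:
                break
        else:
            warnings.warn("QP slack stage hit the ADMM iteration limit")
        self._z, self._u = z, u  # warm start for the next right-hand side
        return z


def _solve_box_eq_lsq(M, d, S, lb, ub) -> np.ndarray:
    return _BoxEqLsqSolver(M, S, lb, ub).solve(d)


def qp_slack_minimize(
    model: MetabolicModel, expr: ExpressionProfile, C: float
) -> Dict[str, float]:
    """Per-gene slack alpha from the Euclidean-norm slack QP at C."""
    tc = TrfbaConstraints(model, expr)
    alpha, _ = tc.slack_minimize(C)
    return dict(zip(tc.genes, alpha))


def count_small_slacks(alpha: Sequence[float], threshold: float = SLACK_THRESHOLD) -> int:
    """N_alpha: number of slack variables with |alpha| below threshold."""
    a = np.asarray(list(alpha), dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("slack vector contains non-finite values")
    return int(np.sum(np.abs(a) < threshold))


# -- C_brk and sweep -------------------------------------------------------

def find_c_brk(
    model: MetabolicModel,
    expr: ExpressionProfile,
    tol: float = 1e-3,
    rel_width: float = 1e-3,
    constraints: Optional[TrfbaConstraints] = None,
) -> float:
    """Smallest C at which constrained growth reaches (1 - tol) of the
    unconstrained optimum, located by doubling + bisection.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    tc = constraints or TrfbaConstraints(model, expr)
    g_max = tc.growth(None)
    if g_max <= 0:
        raise ValueError("unconstrained growth must be positive")
    target = (1.0 - tol) * g_max
    hi = 1.0
    for _ in range(200):
        if tc.growth(hi) >= target:
            break
        hi *= 2.0
    else:
        raise ValueError("growth never reaches the unconstrained optimum; "
                         "model and expression profile are inconsistent")
    lo = 0.0
    while hi - lo > rel_width * hi:
        mid = 0.5 * (lo + hi)
        if tc.growth(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class CSweepResult:
    """Stepwise sweep of the scaling constant C over [0, C_brk]."""

    c_grid: np.ndarray              # ascending, includes 0 and C_brk
    V: np.ndarray                   # parent reactions x steps, pFBA net fluxes
    growth: np.ndarray              # hr^-1 per step
    slacks: np.ndarray              # genes x steps (alpha), or empty
    n_alpha: np.ndarray             # small-slack count per step
    c_brk: float
    g_max: float                    # unconstrained growth optimum
    genes: List[str]
    reaction_ids: List[str]
    statuses: List[str]

    def flux_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=self.reaction_ids, columns=self.c_grid)

    def write_tsv(self, path_prefix: str) -> None:
        self.flux_frame().to_csv(f"{path_prefix}_fluxes.tsv", sep="\t")
        pd.DataFrame({"C": self.c_grid, "growth": self.growth,
                      "n_alpha": self.n_alpha}).to_csv(
            f"{path_prefix}_growth.tsv", sep="\t", index=False)


def sweep_c(
    model: MetabolicModel,
    expr: ExpressionProfile,
    n_steps: int = DEFAULT_N_STEPS,
    c_brk: Optional[float] = None,
    compute_slacks: bool = True,
    slack_threshold: float = SLACK_THRESHOLD,
    constraints: Optional[TrfbaConstraints] = None,
) -> CSweepResult:
    """Evaluate parsimonious fluxes, growth and (optionally) QP slacks on
    an n_steps grid over [0, C_brk]."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    tc = constraints or TrfbaConstraints(model, expr)
    if c_brk is None:
        c_brk = find_c_brk(model, expr, constraints=tc)
    grid = np.linspace(0.0, c_brk, n_steps)
    n_rxn = model.n_reactions
    V = np.zeros((n_rxn, n_steps))
    g = np.zeros(n_steps)
    n_genes = len(tc.genes)
    A = np.zeros((n_genes, n_steps)) if compute_slacks else np.zeros((0, n_steps))
    n_alpha = np.zeros(n_steps, dtype=int)
    statuses = []
    for k, C in enumerate(grid):
        net, growth, status = tc.pfba_net_fluxes(C)
        statuses.append(status)
        V[:, k] = net
        g[k] = growth
        if compute_slacks:
            alpha, _ = tc.slack_minimize(C)
            A[:, k] = alpha
            n_alpha[k] = count_small_slacks(alpha, slack_threshold)
    bad = [s for s in statuses if s != "optimal"]
    if bad:
        warnings.warn(f"{len(bad)} sweep steps did not solve to optimality")
    return CSweepResult(
        c_grid=grid, V=V, growth=g, slacks=A, n_alpha=n_alpha,
        c_brk=float(c_brk), g_max=float(tc.growth(None)),
        genes=list(tc.genes), reaction_ids=list(model.reaction_ids),
        statuses=statuses,
    )


# -- growth-correlated reactions ------------------------------------------

@dataclass
class GrowthCorrelatedSet:
    """Reactions whose sweep fluxes track predicted growth."""

    table: pd.DataFrame  # reaction_id, rho, p, q
    rho_min: float
    alpha_fdr: float

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.table["reaction_id"])

    def __len__(self) -> int:
        return len(self.table)


def growth_correlated_reactions(
    sweep: CSweepResult,
    rho_min: float = 0.9,
    alpha_fdr: float = 0.05,
) -> GrowthCorrelatedSet:
    """Spearman-correlate each reaction's sweep fluxes with growth,
    BH-adjust over the tested reactions, and keep |rho| >= rho_min with
    q < alpha_fdr (sign-agnostic)."""
    ok = [k for k, s in enumerate(sweep.statuses) if s == "optimal"]
    if len(ok) < 10:
        raise ValueError("sweep has fewer than 10 usable steps")
    g = sweep.growth[ok]
    if np.ptp(g) <= 0:
        raise ValueError("growth is constant across the sweep; no signal to correlate")
    rows = []
    for i, rid in enumerate(sweep.reaction_ids):
        flux = sweep.V[i, ok]
        if np.ptp(flux) < 1e-12:
            continue  # constant flux: Spearman undefined
        rho, p = spearmanr(flux, g)
        if not np.isfinite(rho):
            continue
        rows.append((rid, float(rho), float(p)))
    if not rows:
        return GrowthCorrelatedSet(
            pd.DataFrame(columns=["reaction_id", "rho", "p", "q"]), rho_min, alpha_fdr
        )
    df = pd.DataFrame(rows, columns=["reaction_id", "rho", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    keep = df[(df["q"] < alpha_fdr) & (df["rho"].abs() >= rho_min)]
    return GrowthCorrelatedSet(keep.reset_index(drop=True), rho_min, alpha_fdr)


# -- change-point detection and C calibration ------------------------------

def _rss(x: np.ndarray) -> float:
    return float(np.sum((x - x.mean()) ** 2)) if len(x) else 0.0

def _best_split(x: np.ndarray) -> Tuple[int, float]:
    """Best single split index (start of right segment) and its RSS gain."""
    total = _rss(x)
    best_i, best_gain = -1, 0.0
    for i in range(1, len(x)):
        gain = total - _rss(x[:i]) - _rss(x[i:])
        if gain > best_gain + 1e-15:
            best_i, best_gain = i, gain
    return best_i, best_gain


def detect_change_points(
    x: Sequence[float], penalty: Optional[float] = None
) -> List[int]:
    """Binary segmentation for piecewise-constant means.

    Recursively splits at the RSS-minimizing index while the RSS gain
    exceeds ``penalty``.  The default penalty is 2 * sigma^2 * log(n)
    with sigma^2 estimated from first differences, which accepts no
    split on a constant series.  Returned indices mark the first element
    of each new segment, ascending.
    """
    x = np.asarray(list(x), dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("series too short for change-point detection")
    if penalty is None:
        sigma2 = float(np.var(np.diff(x)) / 2.0)
        penalty = 2.0 * sigma2 * np.log(n)
    out: List[int] = []

    def recurse(lo, hi):
        seg = x[lo:hi]
        if len(seg) < 2:
            return
        i, gain = _best_split(seg)
        if i < 0 or gain <= max(penalty, 1e-12):
            return
        out.append(lo + i)
        recurse(lo, lo + i)
        recurse(lo + i, hi)

    recurse(0, n)
    return sorted(out)


def detect_c_corr(
    n_alpha: Sequence[float],
    c_grid: Sequence[float],
    penalty: Optional[float] = None,
    which: str = "first",
) -> float:
    """C at the first (default) or last sudden change of the N_alpha series."""
    cps = detect_change_points(n_alpha, penalty=penalty)
    if not cps:
        raise ValueError(
            "no change point in the N_alpha series; fall back to C_opt or a manual C"
        )
    idx = cps[0] if which == "first" else cps[-1]
    return float(np.asarray(c_grid)[idx])


def compute_c_opt(c_brk: float, g_max: float, g_measured: float) -> float:
    """Phenotype-calibrated scaling constant: (C_brk / G_max) * G_measured."""
    if g_max <= 0:
        raise ValueError("G_max must be positive")
    if g_measured < 0:
        raise ValueError("measured growth must be nonnegative")
    return c_brk / g_max * g_measured


# -- pipeline: Model / Results objects -------------------------------------

class TRFBACore:
    """Context-specific reconstruction model (fit() -> TRFBACoreResults).

    Parameters
    ----------
    model : parent metabolic network (flux-consistent part is used as-is).
    expression : one sample's expression profile.
    medium : optional uptake-bound specification applied before anything else.
    growth_measured : optional measured growth rate (hr^-1); switches the
        final calibration from C_corr to C_opt.
    n_steps, rho_min, alpha_fdr, slack_threshold, epsilon : algorithm knobs.
    """

    def __init__(
        self,
        model: MetabolicModel,
        expression: ExpressionProfile,
        medium: Optional[MediumSpec] = None,
        growth_measured: Optional[float] = None,
        n_steps: int = DEFAULT_N_STEPS,
        rho_min: float = 0.9,
        alpha_fdr: float = 0.05,
        slack_threshold: float = SLACK_THRESHOLD,
        epsilon: float = 1e-4,
        changepoint_penalty: Optional[float] = None,
    ):
        self.model = apply_medium(model, medium) if medium is not None else model
        self.expression = expression
        self.growth_measured = growth_measured
        self.n_steps = n_steps
        self.rho_min = rho_min
        self.alpha_fdr = alpha_fdr
        self.slack_threshold = slack_threshold
        self.epsilon = epsilon
        self.changepoint_penalty = changepoint_penalty

    def fit(self, compute_slacks: bool = True) -> "TRFBACoreResults":
        stage = "constraint construction"
        try:
            tc = TrfbaConstraints(self.model, self.expression)
            stage = "C sweep"
            sweep = sweep_c(
                self.model, self.expression, n_steps=self.n_steps,
                compute_slacks=compute_slacks,
                slack_threshold=self.slack_threshold, constraints=tc,
            )
            stage = "growth-correlated reaction identification"
            gcs = growth_correlated_reactions(sweep, self.rho_min, self.alpha_fdr)
            stage = "subnetwork extraction"
            expr_z = (
                self.expression
                if self.expression.zscores is not None
                else self.expression.with_plain_zscores()
            )
            states = expr_z.states()
            spec = CoreSpec(core=set(gcs.reaction_ids))
            spec.core &= set(self.model.reaction_ids)
            ctx = fastcormics_modified(self.model, spec, states, self.epsilon)
            stage = "C calibration"
            if self.growth_measured is not None:
                c_final = compute_c_opt(sweep.c_brk, sweep.g_max, self.growth_measured)
                calibration = "C_opt"
                c_corr = None
            else:
                c_final = detect_c_corr(
                    sweep.n_alpha, sweep.c_grid, penalty=self.changepoint_penalty
                )
                calibration = "C_corr"
                c_corr = c_final
            stage = "final constrained model"
            sub_expr = ExpressionProfile(
                self.expression.sample_id,
                {g: self.expression.values[g]
                 for g in ctx.model.gene_ids if g in self.expression.values},
                None,
            )
            sub_tc = TrfbaConstraints(ctx.model, sub_expr)
            predicted = sub_tc.growth(c_final)
            parent_predicted = tc.growth(c_final)
        except Exception as e:
            raise RuntimeError(f"reconstruction failed at stage: {stage}") from e
        ctx.C = c_final
        ctx.provenance.update(
            {
                "sample": self.expression.sample_id,
                "calibration": calibration,
                "c_brk": sweep.c_brk,
                "g_max": sweep.g_max,
                "n_steps": self.n_steps,
                "rho_min": self.rho_min,
                "alpha_fdr": self.alpha_fdr,
                "slack_threshold": self.slack_threshold,
                "epsilon": self.epsilon,
            }
        )
        return TRFBACoreResults(
            spec_model=self,
            sweep=sweep,
            growth_correlated=gcs,
            context_model=ctx,
            c_final=c_final,
            c_corr=c_corr,
            calibration=calibration,
            predicted_growth=predicted,
            parent_predicted_growth=parent_predicted,
        )


@dataclass
class TRFBACoreResults:
    """Fitted reconstruction: sweep diagnostics, core set, extracted model."""

    spec_model: TRFBACore
    sweep: CSweepResult
    growth_correlated: GrowthCorrelatedSet
    context_model: ContextModel
    c_final: float
    c_corr: Optional[float]
    calibration: str
    predicted_growth: float
    parent_predicted_growth: float

    @property
    def c_brk(self) -> float:
        return self.sweep.c_brk

    @property
    def g_max(self) -> float:
        return self.sweep.g_max

    def summary(self) -> str:
        lines = [
            "Context-specific reconstruction results",
            "=" * 44,
            f"sample:                  {self.spec_model.expression.sample_id}",
            f"parent reactions:        {self.spec_model.model.n_reactions}",
            f"extracted reactions:     {len(self.context_model.reaction_ids)}",
            f"growth-correlated core:  {len(self.growth_correlated)}",
            f"C_brk:                   {self.c_brk:.6g}",
            f"G_max (hr^-1):           {self.g_max:.6g}",
            f"calibration:             {self.calibration}",
            f"C used:                  {self.c_final:.6g}",
            f"predicted growth (hr^-1):{self.predicted_growth: .6g}",
        ]
        if self.spec_model.growth_measured is not None:
            lines.append(
                f"measured growth (hr^-1): {self.spec_model.growth_measured:.6g}"
            )
        return "\n".join(lines)
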