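"""Benchmark harness: five comparison and four consistency tests, a
direction-aware scoring matrix, and hierarchical clustering of methods.

The nine benchmarks (numbered as in the report matrix):
1 growth-rate prediction error, 2 metabolite uptake/secretion rates,
3 drug response, 4 essential genes, 5 OG/TS/LOF enrichment,
6 fraction of blocked reactions, 7 resolution power,
8 robustness to missing data (cross-validation), 9 robustness to noise.

Methods enter through :class:`MethodPlugin`; reference algorithms that
are not part of this package can be evaluated by wrapping pre-built
models in a plugin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .consistency import blocked_fraction
from .expression import ExpressionProfile
from .extraction import ContextModel
from .lp import fba
from .model import MediumSpec, MetabolicModel
from .stats import bh_adjust, correlate, hypergeom_enrichment, jaccard

__all__ = [
    "growth_error",
    "predict_exchange_rate",
    "simulate_drug_response",
    "og_ts_fold_enrichment",
    "resolution_power",
    "cross_validate",
    "CrossValidationReport",
    "noise_series",
    "MethodPlugin",
    "BenchmarkReport",
    "score_methods",
    "BENCHMARK_NAMES",
]

BENCHMARK_NAMES = {
    1: "growth_rate",
    2: "uptake_secretion",
    3: "drug_response",
    4: "essential_genes",
    5: "og_ts_lof_enrichment",
    6: "blocked_fraction",
    7: "resolution_power",
    8: "robustness_missing",
    9: "robustness_noise",
}

#: Whether a larger raw statistic means a better method, per benchmark.
BENCHMARK_HIGHER_IS_BETTER = {
    1: False,  # relative growth error
    2: True,   # correlation with measured exchange rates
    3: True,   # correlation with measured IC50 (magnitude)
    4: True,   # -log10 enrichment p
    5: True,   # fold enrichment of OGs (combined score)
    6: False,  # fraction of blocked reactions
    7: True,   # within-type minus between-type Jaccard
    8: True,   # -log10 recovery p
    9: True,   # noise-discrimination score
}


# -- comparison statistics -------------------------------------------------

def growth_error(growth_exp: float, growth_pred: float) -> float:
    """Relative growth prediction error |exp - pred| / exp."""
    if growth_exp <= 0:
        raise ValueError("measured growth must be positive")
    return abs(growth_exp - growth_pred) / growth_exp


def predict_exchange_rate(
    model: MetabolicModel,
    exchange_id: str,
    growth_fraction: float = 0.9,
    reset_uptake: Optional[float] = None,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
) -> float:
    """Maximal flux of one exchange reaction at >= ``growth_fraction`` of
    maximal growth.

    When the model was constrained with a cell-specific medium, pass the
    general-medium uptake magnitude as ``reset_uptake`` so the tested
    exchange is not pinned by the very measurement being predicted.
    """
    if exchange_id not in model.exchange_ids:
        raise KeyError(f"{exchange_id!r} is not an exchange reaction")
    m = model
    if reset_uptake is not None:
        m = model.copy()
        m.lb[m.reaction_index(exchange_id)] = -abs(reset_uptake)
    base = fba(m, A_ub=A_ub, b_ub=b_ub)
    if not base.optimal or base.objective_value <= 0:
        raise ValueError("model does not grow; exchange prediction undefined")
    rows = np.zeros((1, m.n_reactions))
    rows[0, m.reaction_index(m.objective_id)] = -1.0
    rhs = np.array([-growth_fraction * base.objective_value])
    if A_ub is not None:
        rows = np.vstack([np.atleast_2d(A_ub), rows])
        rhs = np.concatenate([np.atleast_1d(b_ub), rhs])
    sol = fba(m, objective=exchange_id, sense="max", A_ub=rows, b_ub=rhs)
    if not sol.optimal:
        raise ValueError(f"exchange maximization infeasible for {exchange_id!r}")
    return sol.objective_value


def simulate_drug_response(
    model: MetabolicModel,
    target_reaction: str,
    biomass_fraction: float = 0.5,
) -> Optional[float]:
    """Proxy drug-response statistic: maximal flux through the target
    reaction with biomass fixed to ``biomass_fraction`` of its optimum.

    Returns None (non-predictable) when the target is absent from the
    model or the pinned problem is infeasible.
    """
    if target_reaction not in model.reaction_ids:
        return None
    sol = fba(model)
    if not sol.optimal or sol.objective_value <= 0:
        return None
    m = model.copy()
    i = m.reaction_index(m.objective_id)
    m.lb[i] = m.ub[i] = biomass_fraction * sol.objective_value
    out = fba(m, objective=target_reaction, sense="max")
    return out.objective_value if out.optimal else None


def og_ts_fold_enrichment(
    predicted_genes: Set[str],
    annotated_set: Set[str],
    model_genes: Set[str],
    tail: str = "right",
) -> Tuple[float, float]:
    """Fold enrichment of an annotation among predicted genes, plus its
    hypergeometric tail p (right for oncogenes, left for TS/LOF)."""
    predicted = set(predicted_genes)
    model_genes = set(model_genes)
    if not predicted <= model_genes:
        raise ValueError("predicted genes must be a subset of model genes")
    ann_in_model = annotated_set & model_genes
    if not ann_in_model:
        raise ValueError("no annotated genes in the model")
    if not predicted:
        raise ValueError("empty predicted set: enrichment undefined")
    frac_pred = len(predicted & ann_in_model) / len(predicted)
    frac_model = len(ann_in_model) / len(model_genes)
    fold = frac_pred / frac_model
    p = hypergeom_enrichment(
        len(predicted & ann_in_model), len(predicted),
        len(ann_in_model), len(model_genes), tail=tail,
    )
    return fold, p


def resolution_power(models_by_type: Dict[str, Sequence[Set[str]]]) -> float:
    """Mean within-type pairwise Jaccard minus mean between-type Jaccard.

    Input: reaction-id sets of extracted subnetworks grouped by context
    type.  Larger is better (similar within a type, distinct across)."""
    within, between = [], []
    types = sorted(models_by_type)
    for t in types:
        sets = list(models_by_type[t])
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                within.append(jaccard(sets[i], sets[j]))
    for a in range(len(types)):
        for b in range(a + 1, len(types)):
            for sa in models_by_type[types[a]]:
                for sb in models_by_type[types[b]]:
                    between.append(jaccard(sa, sb))
    w = float(np.mean(within)) if within else 1.0
    x = float(np.mean(between)) if between else 0.0
    return w - x


# -- plugins ---------------------------------------------------------------

@dataclass
class MethodPlugin:
    """Harness contract for a reconstruction method.

    ``build`` maps (model, expression, medium, phenotype) to either a
    ContextModel (subnetwork extractors) or a MetabolicModel
    (bound-setting methods that retain the parent network).
    """

    name: str
    build: Callable
    produces_subnetwork: bool = True
    requires_phenotype: bool = False

    def reactions(self, result) -> Set[str]:
        if isinstance(result, ContextModel):
            return set(result.model.reaction_ids)
        return set(result.reaction_ids)


# -- robustness ------------------------------------------------------------

@dataclass
class CrossValidationReport:
    n_models: int
    removed_per_fold: List[int]
    recovered_per_fold: List[int]
    pooled_p: float
    growth_per_fold: List[float] = field(default_factory=list)
    failed_folds: int = 0


def cross_validate(
    plugin: MethodPlugin,
    model: MetabolicModel,
    expression: ExpressionProfile,
    core_reactions: Optional[Set[str]] = None,
    medium: Optional[MediumSpec] = None,
    phenotype=None,
    k: int = 5,
    repeats: int = 15,
    removal_fraction: float = 0.2,
    seed: int = 0,
) -> CrossValidationReport:
    """Repeated k-fold robustness to missing input data.

    Extractors: each fold removes ``removal_fraction`` of the input core
    reactions; recovery = removed reactions present in the output model,
    with a pooled hypergeometric p-value against chance recovery from
    the non-core candidate pool.  Bound-setters: each fold removes the
    same fraction of expression genes and the growth prediction per
    fold is recorded.  k * repeats models are always built.
    """
    rng = np.random.default_rng(seed)
    removed_counts, recovered_counts, growths = [], [], []
    failures = 0
    total_hits = total_sel = total_K = total_N = 0
    n_models = 0
    for _ in range(repeats):
        if plugin.produces_subnetwork:
            if not core_reactions:
                raise ValueError("extractor cross-validation needs core reactions")
            core = sorted(core_reactions)
            perm = rng.permutation(len(core))
            folds = np.array_split(perm, k)
        else:
            genes = sorted(expression.values)
            perm = rng.permutation(len(genes))
            folds = np.array_split(perm, k)
        for fold in folds:
            n_models += 1
            if plugin.produces_subnetwork:
                removed = {core[i] for i in fold}
                kept_core = set(core) - removed
                try:
                    result = plugin.build(
                        model, expression, medium, phenotype, core=kept_core
                    )
                except Exception:
                    failures += 1
                    continue
                out = plugin.reactions(result)
                hits = removed & out
                removed_counts.append(len(removed))
                recovered_counts.append(len(hits))
                candidates = set(model.reaction_ids) - kept_core
                total_hits += len(hits)
                total_sel += len(out - kept_core)
                total_K += len(removed)
                total_N += len(candidates)
            else:
                dropped = {genes[i] for i in fold}
                sub_expr = ExpressionProfile(
                    expression.sample_id,
                    {g: v for g, v in expression.values.items() if g not in dropped},
                )
                try:
                    result = plugin.build(model, sub_expr, medium, phenotype)
                    growths.append(_growth_of(result))
                except Exception:
                    failures += 1
                    continue
    if plugin.produces_subnetwork and total_N > 0:
        sel = min(total_sel, total_N)
        hits = min(total_hits, min(sel, total_K))
        pooled_p = hypergeom_enrichment(hits, sel, min(total_K, total_N), total_N)
    else:
        pooled_p = float("nan")
    return CrossValidationReport(
        n_models=n_models,
        removed_per_fold=removed_counts,
        recovered_per_fold=recovered_counts,
        pooled_p=pooled_p,
        growth_per_fold=growths,
        failed_folds=failures,
    )


def _growth_of(result) -> float:
    m = result.model if isinstance(result, ContextModel) else result
    sol = fba(m)
    return sol.objective_value if sol.optimal else 0.0


def noise_series(
    expr: ExpressionProfile, n_sets: int = 20, seed: int = 0
) -> List[Tuple[ExpressionProfile, float]]:
    """Permutation-noise series spanning Spearman R from ~0 to 1.

    Each perturbed profile is a permutation of the original values
    (the value multiset, hence the distribution, is preserved exactly).
    Noise level is the number of shuffled positions, bisected per target
    so the achieved correlations are approximately evenly spaced; the
    series is returned sorted by achieved R ascending, ending in the
    untouched original (R = 1).
    """
    genes = sorted(expr.values)
    n = len(genes)
    if n < 20:
        raise ValueError("need at least 20 genes for a graded noise series")
    x = np.array([expr.values[g] for g in genes])
    rng = np.random.default_rng(seed)

    def candidate(k: int) -> Tuple[np.ndarray, float]:
        # permute a random subset of k positions among themselves
        y = x.copy()
        if k >= 2:
            pos = rng.choice(n, size=k, replace=False)
            y[pos] = x[pos[rng.permutation(k)]]
        rho, _ = correlate(x, y)
        return y, float(rho)

    targets = np.linspace(0.0, 1.0, n_sets)
    out: List[Tuple[ExpressionProfile, float]] = []
    used: Set[float] = {1.0}
    n_tries = 80
    for t in targets[:-1]:
        # subset size roughly matching the target, then best-of-n_tries
        k0 = int(round((1.0 - t) * n))
        best = None
        for _ in range(n_tries):
            k = int(np.clip(k0 + rng.integers(-2, 3), 2, n))
            y, rho = candidate(k)
            if rho in used:
                continue
            if best is None or abs(rho - t) < abs(best[1] - t):
                best = (y, rho)
        if best is None:  # pathological ties; take any fresh shuffle
            best = candidate(n)
        used.add(best[1])
        out.append(
            (
                ExpressionProfile(
                    f"{expr.sample_id}_noise{len(out)}", dict(zip(genes, best[0]))
                ),
                best[1],
            )
        )
    # the last set is exactly the original profile (R = 1)
    out.append(
        (ExpressionProfile(f"{expr.sample_id}_noise{n_sets-1}",
                           dict(zip(genes, x))), 1.0)
    )
    out.sort(key=lambda pair: pair[1])
    return out


# -- scoring and clustering ------------------------------------------------

@dataclass
class BenchmarkReport:
    """Method x benchmark score matrix with details and a linkage tree."""

    raw: pd.DataFrame       # methods x benchmarks (1..9), raw statistics
    scores: pd.DataFrame    # methods x benchmarks, rank-normalized to [0,1]
    linkage: Optional[np.ndarray]
    details: Dict = field(default_factory=dict)
    missing: Dict[str, List[int]] = field(default_factory=dict)

    def to_newick(self) -> str:
        if self.linkage is None:
            return "(" + ",".join(self.scores.index) + ");"
        tree = sch.to_tree(self.linkage)
        labels = list(self.scores.index)

        def rec(node):
            if node.is_leaf():
                return labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"

    def write(self, prefix: str) -> None:
        import json

        self.scores.to_csv(f"{prefix}_scores.tsv", sep="\t")
        self.raw.to_csv(f"{prefix}_raw.tsv", sep="\t")
        with open(f"{prefix}_details.json", "w") as fh:
            json.dump(_jsonable(self.details), fh, indent=1)
        with open(f"{prefix}_tree.nwk", "w") as fh:
            fh.write(self.to_newick() + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def score_methods(
    raw: pd.DataFrame,
    higher_is_better: Optional[Dict[int, bool]] = None,
    details: Optional[Dict] = None,
) -> BenchmarkReport:
    """Rank-normalize raw benchmark statistics and cluster the methods.

    ``raw`` has method rows and benchmark-number columns (1..9); NaN
    marks a benchmark a method could not attempt and scores 0.  Per
    benchmark, methods are ranked direction-aware (best = 1, worst = 0,
    midrank ties); the score rows are then clustered with average
    linkage on Euclidean distance.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 methods to score")
    hib = higher_is_better or BENCHMARK_HIGHER_IS_BETTER
    missing: Dict[str, List[int]] = {}
    scores = pd.DataFrame(0.0, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        vals = raw[col]
        ok = vals.notna()
        for m in raw.index[~ok]:
            missing.setdefault(m, []).append(int(col))
        if ok.sum() == 0:
            continue
        v = vals[ok].astype(float)
        ranks = v.rank(method="average", ascending=not hib.get(int(col), True))
        # best rank -> highest score
        n = len(v)
        scores.loc[ok, col] = (n - ranks) / max(n - 1, 1)
    if scores.to_numpy().std() == 0:
        warnings.warn("all methods scored identically; degenerate clustering")
    linkage = None
    if len(scores) >= 2:
        linkage = sch.linkage(scores.to_numpy(), method="average", metric="euclidean")
    return BenchmarkReport(raw=raw, scores=scores, linkage=linkage,
                           details=details or {}, missing=missing)
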