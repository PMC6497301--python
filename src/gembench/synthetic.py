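"""Deterministic synthetic fixtures: toy networks, expression panels,
phenotypes with planted ground truth.

The toy network emulates the shape of a genome-scale model at a scale
where brute-force oracles stay tractable: a handful of parallel linear
pathways feeding a biomass reaction that requires the terminal
metabolite of every pathway, uptake exchanges in front, a secretion
branch (overflow metabolism), GPR rules mixing single genes, isozymes
(OR) and enzyme complexes (AND), and an optional planted dead-end
branch whose reactions are blocked by construction.

Everything is a pure function of the spec (same spec => identical
fixture).  Planted quantities double as test oracles: the blocked set,
the essential genes, the per-sample growth-limiting gene and the
per-sample scaling constant C* that generated the "measured" growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .expression import ExpressionProfile
from .lp import essential_genes, fba, pfba
from .model import CELL_SPECIFIC_VOLUME_ML_PER_GDW, MetabolicModel
from .phenotype import DrugRecord, PhenotypeData, SamplePhenotype
from .stats import correlate

__all__ = [
    "FixtureSpec",
    "make_toy_model",
    "make_expression_panel",
    "make_phenotypes",
    "make_random_model",
]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_pathways: int = 3
    pathway_length: int = 4
    fraction_gene_associated: float = 1.0
    n_samples: int = 20
    expression_correlation: float = 0.9
    n_blocked: int = 0
    uptake_bound: float = 10.0
    cell_volume: float = 430.0  # fL, chosen so unit round-trips are exact
    essentiality_noise: int = 0
    limiting_gene: Optional[str] = None  # default: first single-gene step
    secretion_branch: bool = True  # overflow branch SEC/EX_sec off pathway 0


# -- toy model -------------------------------------------------------------

def make_toy_model(spec: FixtureSpec) -> MetabolicModel:
    """Build the parallel-pathway toy network described in the module docs.

    Reaction naming: EX_upt_p (uptake exchanges), R_p_k (pathway steps),
    SEC / EX_sec (secretion branch on pathway 0), BIOMASS, and B_k for
    the planted dead-end branch.  GPR pattern per step k: k % 3 == 1 ->
    isozyme pair (or), k % 3 == 2 -> complex (and), else single gene.
    """
    mets: List[str] = []
    rids: List[str] = []
    cols: List[Dict[str, float]] = []
    lbs: List[float] = []
    ubs: List[float] = []
    gprs: List[str] = []
    genes: List[str] = []
    big = 1000.0

    def add_rxn(rid, stoich, lb, ub, gpr=""):
        rids.append(rid)
        cols.append(stoich)
        lbs.append(lb)
        ubs.append(ub)
        gprs.append(gpr)
        for m in stoich:
            if m not in mets:
                mets.append(m)

    n_assoc_total = spec.n_pathways * spec.pathway_length
    n_assoc = int(round(spec.fraction_gene_associated * n_assoc_total))
    step_counter = 0
    for p in range(spec.n_pathways):
        add_rxn(f"EX_upt_{p}", {f"M_{p}_0": -1.0}, -spec.uptake_bound, big)
        for k in range(1, spec.pathway_length + 1):
            gpr = ""
            if step_counter < n_assoc:
                if k % 3 == 1:
                    ga, gb = f"g_{p}_{k}a", f"g_{p}_{k}b"
                    genes += [ga, gb]
                    gpr = f"{ga} or {gb}"
                elif k % 3 == 2:
                    ga, gb = f"g_{p}_{k}a", f"g_{p}_{k}b"
                    genes += [ga, gb]
                    gpr = f"{ga} and {gb}"
                else:
                    g = f"g_{p}_{k}"
                    genes.append(g)
                    gpr = g
            add_rxn(
                f"R_{p}_{k}",
                {f"M_{p}_{k-1}": -1.0, f"M_{p}_{k}": 1.0},
                0.0,
                big,
                gpr,
            )
            step_counter += 1
    if spec.secretion_branch:
        # overflow secretion branch off pathway 0
        add_rxn("SEC", {f"M_0_{spec.pathway_length - 1}": -1.0, "M_by": 1.0}, 0.0, big)
        add_rxn("EX_sec", {"M_by": -1.0}, 0.0, big)
    # biomass consumes the terminal metabolite of every pathway
    add_rxn(
        "BIOMASS",
        {f"M_{p}_{spec.pathway_length}": -1.0 for p in range(spec.n_pathways)},
        0.0,
        big,
    )
    # planted dead-end branch: B_1 .. B_n ending in an orphan metabolite
    prev = f"M_{0}_{spec.pathway_length}"
    for k in range(1, spec.n_blocked + 1):
        add_rxn(f"B_{k}", {prev: -1.0, f"D_{k}": 1.0}, 0.0, big)
        prev = f"D_{k}"

    met_idx = {m: j for j, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rids)))
    for i, stoich in enumerate(cols):
        for m, coef in stoich.items():
            S[met_idx[m], i] = coef
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=np.array(lbs),
        ub=np.array(ubs),
        gene_ids=sorted(set(genes)),
        gpr=gprs,
        objective_id="BIOMASS",
        model_id=f"toy_seed{spec.seed}",
    )


def planted_blocked_reactions(spec: FixtureSpec) -> Set[str]:
    return {f"B_{k}" for k in range(1, spec.n_blocked + 1)}


def limiting_gene_candidates(model: MetabolicModel, spec: FixtureSpec) -> List[str]:
    """Single-gene (non-isozyme, non-complex) steps: planting a low value
    there makes that gene's constraint the unique growth bottleneck."""
    return [g for g in model.gene_ids
            if not (g.endswith("a") or g.endswith("b"))]


# -- expression panel ------------------------------------------------------

def _pairwise_mean_spearman(values: np.ndarray) -> float:
    n = values.shape[0]
    rs = []
    for i in range(n):
        for j in range(i + 1, n):
            rho, _ = correlate(values[i], values[j])
            rs.append(rho)
    return float(np.mean(rs)) if rs else 1.0


def make_expression_panel(
    model: MetabolicModel, spec: FixtureSpec
) -> List[ExpressionProfile]:
    """Correlated per-sample expression with a planted bottleneck gene.

    Each gene gets a log-normal baseline; samples perturb it by a shared
    multiplicative log-normal noise whose scale is bisected so the mean
    pairwise Spearman correlation lands within +-0.05 of the target.
    Each sample's designated growth-limiting gene is then forced far
    below every other expressed gene.
    """
    if not model.gene_ids:
        raise ValueError("model has no genes")
    genes = list(model.gene_ids)
    n_genes = len(genes)
    rng = np.random.default_rng(spec.seed)
    baseline = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    z = rng.standard_normal((spec.n_samples, n_genes))
    limiters = limiting_gene_candidates(model, spec)
    if not limiters:
        limiters = genes
    # one designated bottleneck gene, planted at a sample-specific low
    # value: it limits growth in every sample while leaving the panel's
    # rank structure (hence inter-sample correlation) intact
    limiter = spec.limiting_gene or limiters[0]
    assigned = [limiter] * spec.n_samples

    def build(sigma: float) -> np.ndarray:
        vals = baseline[None, :] * np.exp(sigma * z)
        for s, gene in enumerate(assigned):
            gi = genes.index(gene)
            others = np.delete(vals[s], gi)
            vals[s, gi] = 0.05 * float(np.min(others)) * (1.0 + 0.5 * (s / max(spec.n_samples, 1)))
        return vals

    if spec.n_samples < 2:
        vals = build(0.5)
    else:
        lo, hi = 0.0, 5.0
        vals = None
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            vals = build(mid)
            r = _pairwise_mean_spearman(vals)
            if abs(r - spec.expression_correlation) <= 0.02:
                break
            if r > spec.expression_correlation:
                lo = mid
            else:
                hi = mid
        achieved = _pairwise_mean_spearman(vals)
        if abs(achieved - spec.expression_correlation) > 0.05:
            raise ValueError(
                f"cannot reach correlation target {spec.expression_correlation} "
                f"with {n_genes} genes (achieved {achieved:.3f})"
            )
    return [
        ExpressionProfile(
            f"sample_{s:02d}", {g: float(vals[s, gi]) for gi, g in enumerate(genes)}
        )
        for s in range(spec.n_samples)
    ]


# -- phenotypes ------------------------------------------------------------

def make_phenotypes(
    model: MetabolicModel,
    panel: List[ExpressionProfile],
    spec: FixtureSpec,
) -> Tuple[PhenotypeData, Dict[str, float]]:
    """Phenotypes generated from planted ground truth.

    Measured growth of sample s is the model's own growth under
    expression constraints at a planted scaling constant C*_s (an
    ascending fraction of the sample's C_brk), so phenotype-calibrated
    C recovery is exact by construction.  Exchange rates are the
    parsimonious uptake fluxes at C*, back-converted to per-cell units
    with the planted cell volume.  Returns (phenotypes, planted C* map).
    """
    from .trfba import TrfbaConstraints, find_c_brk

    rng = np.random.default_rng(spec.seed + 1)
    n = len(panel)
    data = PhenotypeData()
    c_star: Dict[str, float] = {}
    ex_ids = model.exchange_ids
    drug_targets = [f"R_{p}_1" for p in range(spec.n_pathways)
                    if f"R_{p}_1" in model.reaction_ids]
    for s, prof in enumerate(panel):
        tc = TrfbaConstraints(model, prof)
        c_brk = find_c_brk(model, prof, constraints=tc)
        q = 0.2 + 0.7 * (s / max(n - 1, 1))
        cs = q * c_brk
        c_star[prof.sample_id] = cs
        growth = tc.growth(cs)
        net, _, status = tc.pfba_net_fluxes(cs)
        rates = {}
        if status == "optimal":
            for rid in ex_ids:
                v = net[model.reaction_index(rid)]
                if v < -1e-9:  # uptake
                    rates[rid] = -v * spec.cell_volume / CELL_SPECIFIC_VOLUME_ML_PER_GDW
        drugs = []
        for t in drug_targets:
            fmax = _max_flux_at_biomass_fraction(model, t, 0.5)
            if fmax is not None:
                drugs.append(DrugRecord(f"drug_{t}", t, ic50=1.0 / (1.0 + fmax)))
        data.add(
            SamplePhenotype(
                prof.sample_id,
                growth_rate=growth if growth > 0 else None,
                exchange_rates=rates,
                cell_volume=spec.cell_volume,
                drugs=drugs,
            )
        )
    ess = essential_genes(model)
    noise = set()
    if spec.essentiality_noise > 0:
        non_ess = sorted(set(model.gene_ids) - ess)
        noise = set(rng.choice(non_ess,
                               size=min(spec.essentiality_noise, len(non_ess)),
                               replace=False))
    for s in data.samples.values():
        s.essential_genes = set(ess) | noise
    # annotation sets with planted enrichment: oncogenes biased toward
    # pathway (growth-supporting) genes, TS/LOF toward isozyme spares
    pathway_genes = sorted(g for g in model.gene_ids if not g.endswith("b"))
    spare_genes = sorted(g for g in model.gene_ids if g.endswith("b"))
    data.oncogenes = set(pathway_genes[: max(2, len(pathway_genes) // 3)])
    data.tumor_suppressors = set(spare_genes[: max(1, len(spare_genes) // 2)])
    data.lof_genes = set(spare_genes[len(spare_genes) // 2:])
    return data, c_star


def _max_flux_at_biomass_fraction(model, target, fraction):
    sol = fba(model)
    if not sol.optimal or sol.objective_value <= 0:
        return None
    m = model.copy()
    i = m.reaction_index(m.objective_id)
    m.lb[i] = m.ub[i] = fraction * sol.objective_value
    out = fba(m, objective=target, sense="max")
    return out.objective_value if out.optimal else None


# -- random networks for consistency-oracle stress tests -------------------

def make_random_model(
    seed: int, n_reactions: int = 20, n_metabolites: Optional[int] = None
) -> MetabolicModel:
    """Random sparse stoichiometry for blocked-set oracle stress tests.

    Small integer coefficients, ~30% reversible reactions, a few
    exchange columns so something can flow.  No GPRs.
    """
    rng = np.random.default_rng(seed)
    n_met = n_metabolites or max(3, n_reactions // 2)
    S = np.zeros((n_met, n_reactions))
    n_exchange = max(2, n_reactions // 5)
    for i in range(n_reactions):
        if i < n_exchange:
            S[rng.integers(n_met), i] = -1.0
        else:
            k = int(rng.integers(2, 4))
            rows = rng.choice(n_met, size=min(k, n_met), replace=False)
            for j, r in enumerate(rows):
                coef = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
                S[r, i] = coef
    rev = rng.random(n_reactions) < 0.3
    lb = np.where(rev, -10.0, 0.0)
    lb[:n_exchange] = -10.0
    ub = np.full(n_reactions, 10.0)
    rids = [f"EX_{i}" if i < n_exchange else f"R_{i}" for i in range(n_reactions)]
    return MetabolicModel(
        metabolite_ids=[f"m{j}" for j in range(n_met)],
        reaction_ids=rids,
        S=S,
        lb=lb,
        ub=ub,
        gene_ids=[],
        gpr=[""] * n_reactions,
        objective_id=rids[0],
        model_id=f"rand{seed}",
    )
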