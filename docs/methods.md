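# Methods

This note documents the models and procedures implemented in gembench,
their assumptions, the tunable parameters, the synthetic data the tests
run on, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Network model and conventions

A metabolic network is a stoichiometric matrix S (metabolites ×
reactions) with flux bounds lb ≤ v ≤ ub in mmol gDW⁻¹ hr⁻¹, boolean
GPR rules over genes, and a biomass objective reaction. Steady state
means S·v = 0 exactly (the right-hand side is zero; no accumulation
terms). Exchange reactions are the single-metabolite columns of S;
negative flux is uptake, positive is secretion (the COBRA community
convention). Measured phenotype tables store uptake as positive
magnitudes and the sign is applied when a bound is set, so the unit
conversion stays positive:

- **Per-cell to per-dry-weight conversion.** An exchange rate measured
  in fmol cell⁻¹ hr⁻¹ becomes a flux bound via
  `v = s · C_met / V_c`, with cell volume `V_c` in fL and the cell
  specific volume `s = 4.3 mL gDW⁻¹` — a mammalian-cell literature
  value kept as a configurable constant because other cell types
  differ.
- **Doubling time to growth rate**: μ = ln 2 / t_d.
- A cell-specific medium missing some exchange rates is filled from
  the general medium before application.

Open question resolved: measured secretion rates are *not* used to
constrain secretion bounds; only uptake bounds are set. Rationale:
secretion capacity is an output of the model under test, and pinning it
would leak the measurement being predicted into the prediction.

## LP layer

FBA, pFBA, FVA and gene deletions are LPs over S·v = 0 plus bounds,
solved with HiGHS (scipy.optimize.linprog). pFBA is the standard
two-stage LP: fix the biomass optimum, split every flux into
nonnegative forward/backward parts, minimize their sum (no integer
variables). Knockout infeasibility maps to growth 0. A gene is
essential when its knockout drops maximal growth by more than 1 % of
the wild type. Feasibility/optimality tolerances are the solver's
(≈1e−9); the validation tests assert |S·v|∞ ≤ 1e−9 on returned
solutions.

## Consistency (FASTCC)

A reaction is blocked when it cannot carry |v| ≥ ε in any feasible
steady state (ε default 1e−4, shared with extraction). The scan uses
the support-maximization LP (maximize the number of candidate reactions
pushed to flux ≥ ε in one solve) and revisits reversible reactions
after flipping their orientation, rather than solving two LPs per
reaction. The per-reaction FVA brute force is kept as the test oracle,
and cobrapy's FASTCC is a second, independent cross-check. The
"unconstrained" network state opens every exchange symmetrically to
±1000 mmol gDW⁻¹ hr⁻¹.

## Extraction (weighted FASTCORE)

FASTCORE alternates (i) a support-maximization LP activating
not-yet-supported core reactions and (ii) a weighted L1 minimization
that sparsifies the non-core support of the found mode. Determinism:
candidate reactions are processed in lexicographic id order, which
fixes tie-breaks among equal-cost additions.

The pipeline's extractor layers expression on top of FASTCORE:

- gene states from z-scores — core if z > 5, non-expressed if z < 0,
  moderate between (the FASTCORE/FASTCORMICS thresholds);
- reactions whose GPR is satisfied by core-state genes are required;
  reactions satisfiable with moderate genes are non-penalized (weight
  0 in the L1 step); everything else, including reactions with no GPR
  or no data, costs 1;
- the biomass reaction plus the support of one parsimonious flux mode
  through it is pre-seeded into the core, which guarantees the
  extracted model grows whenever the parent does.

This forced-functionality design is this package's own realization of
an expression-weighted, biomass-supported FASTCORE; it reproduces the
properties the pipeline needs (functional output, non-penalized set,
biomass support) but is not claimed to match any specific prior
implementation detail.

When no z-score view is supplied, a plain (x − mean)/sd transform
within the sample is used and is explicitly a stand-in, not a
normalization method: with it, no gene typically exceeds z = 5, so the
required core comes entirely from the growth-correlated set and
expression contributes only the non-penalized tier. That is the
intended behavior on synthetic data.

## Expression-to-bound constraints and the C sweep

Constraints are built on the irreversible-split network so that the
per-gene sum adds nonnegative flux magnitudes (a net-flux sum would let
a reversible reaction cancel its own contribution). Genes without
expression values, or without associated reactions, are unconstrained.

- **C_brk** is located by doubling plus bisection (relative width
  1e−3) as the smallest C whose constrained growth reaches (1 − tol)
  of the unconstrained optimum, tol default 1e−3. Growth is monotone
  in C because the constraint right-hand sides scale linearly with C.
- **Sweep**: 500 grid points over [0, C_brk] by default (the smallest
  grid for which the growth-correlated set was stable on the fixtures;
  the step-size stability test compares grids by Jaccard similarity).
  Fluxes at each point come from pFBA — raw FBA has alternate optima
  that would make the flux–growth correlation ill-defined.
- **Growth-correlated reactions**: Spearman ρ of flux vs growth per
  reaction across the grid, BH adjustment over the tested reactions,
  keep q < 0.05 and |ρ| ≥ 0.9. The ρ cutoff is a design choice (the
  selection needs an explicit strength threshold, not just FDR
  control); it is sign-agnostic so anticorrelated (e.g. overflow)
  reactions are kept. Constant-flux reactions are excluded (ρ
  undefined).

## QP slack stage and C_corr

At a given C the inequality per gene becomes an equality with slack:
Σ_{i∈R_j} v_i + α_j = C·E_j, and the QP minimizes Σ α_j² subject to
steady state and bounds. Eliminating α reduces this to a box- and
equality-constrained least squares in v, solved by ADMM: the v-update
is an equality-constrained least squares through a KKT system
factorized once per (model, expression) — only the right-hand side
changes along the sweep — and iterations warm-start from the previous
grid point. Redundant metabolite rows are removed by an SVD row-space
basis so the KKT matrix is nonsingular. Stopping criterion 1e−11 on
primal and dual residuals; the objective is unique by convexity even
where v is not. The equality-with-slack form is applied to every
covered gene (the alternative — keeping inequalities for some genes —
is not what the slack-consistency statistic measures).

N_α counts slacks with |α| < 1e−6. The change point of the N_α series
is found by binary segmentation of piecewise-constant means on RSS;
the default penalty 2·σ̂²·log n (σ̂² from first differences) accepts no
split on a constant series and recovers noiseless steps exactly. The
*first* change point is reported as C_corr; a `which="last"` flag
exposes the alternative reading of "the maximum point at which the
flux consistency shifts".

## C_opt

With a measured growth rate, `C_opt = (C_brk / G_max) × G_measured`.
This is exact whenever growth is linear through the origin up to
C_brk, which holds when only expression constraints bind (the feasible
region scales with C); on the synthetic networks the calibration
therefore recovers the planted constant almost exactly, and on any
monotone growth curve it preserves growth rankings.

## Benchmarks and scoring

The nine benchmark statistics are computed as follows: growth error
|μ_exp − μ_pred|/μ_exp; exchange-rate prediction maximizes the tested
exchange at ≥ 90 % of maximal growth (resetting that exchange's bound
to its general-medium value when a cell-specific medium was applied);
the drug-response proxy maximizes the target reaction's flux with
biomass pinned to 50 % of optimum and is correlated against measured
IC50 without sign flipping (documented so users can invert); essential
genes use the 1 % knockout threshold and hypergeometric enrichment
against screen-derived sets (dependency score < 0 = essential);
oncogene enrichment uses the right tail and tumor-suppressor/LOF the
left tail; blocked fraction uses FASTCC; resolution power is mean
within-type minus mean between-type pairwise Jaccard over extracted
reaction sets; cross-validation removes 20 % of input core reactions
(or expression genes for bound-setters) per fold, 5 folds × 15
repeats = 75 models, with a pooled hypergeometric recovery p; the
noise protocol builds 20 permutation-perturbed profiles whose Spearman
correlations to the original are approximately evenly spaced in [0, 1]
(a best-of-candidates search over partial permutations; the value
multiset is preserved exactly, so the marginal distribution is
unchanged).

Scoring is rank-based and direction-aware: per benchmark, methods are
ranked (midrank ties), normalized to [0, 1] with the best method at 1;
a benchmark a method cannot attempt scores 0 and is flagged. Score
rows are clustered with average linkage on Euclidean distance and the
tree is serialized as Newick. The rank-combination shape (e.g. the
essential-gene benchmark summarizing mean −log₁₀ p and the fraction of
significant samples) is a documented reimplementation choice: the
clustering layer only needs relative scores.

## Synthetic fixtures

The toy generator emulates the *shape* of genome-scale inputs at oracle
scale (default 18–25 reactions, ~20 genes, 20 samples; brute-force
subnetwork enumeration, per-reaction FVA and GPR truth tables all
finish in seconds): parallel linear pathways with uptake exchanges, a
biomass reaction requiring every pathway's terminal metabolite, an
overflow secretion branch, GPRs mixing single genes, isozymes and
complexes, and an optional dead-end branch whose reactions are blocked
by construction. Expression panels share a log-normal baseline with
multiplicative noise bisected to hit a target mean pairwise Spearman
correlation (default 0.9, emulating the high inter-cell-line
correlation of real panels), plus one designated bottleneck gene
planted far below all others at a sample-specific level. Phenotypes are
generated *from the model itself*: measured growth is the constrained
growth at a planted per-sample C\*, exchange rates are back-converted
parsimonious fluxes, essential genes come from in-silico deletions,
drug IC50s are inverse in the target's achievable flux.

What this does not emulate: distributional artifacts of microarray or
RNA-seq pipelines, GPR complexity of real reconstructions (thousands of
genes, nested isozyme/complex rules), thermodynamically infeasible
loops at scale, or any disagreement between phenotype and model beyond
injected label noise. Passing tests therefore demonstrate algorithmic
correctness (oracle equivalence, calibration recovery, bookkeeping,
monotonicity) — not predictive performance on real cancer data.

## Numerical choices and degenerate inputs

- ε (flux activation) 1e−4; stable on fixtures across [1e−6, 1e−3].
- LP tolerances: HiGHS defaults, validated to 1e−9.
- ADMM: ρ set from ‖M‖²_F/n, residual tolerance 1e−11, iteration cap
  50 000 (a warning, not an error, on hitting the cap).
- Change-point penalty: 2·σ̂²·log n unless overridden.
- Degenerate cases: empty models are valid (empty report/extraction);
  Jaccard of two empty sets is defined as 1 with a warning; a constant
  growth sweep or constant N_α series raises instead of guessing;
  knockout infeasibility is growth 0; an empty extraction core yields
  an empty model with a warning, not an error.
- All randomness (fixtures, noise series, CV folds) flows from
  explicit integer seeds; reruns are bit-identical.

## Known limitations

- The regulatory layer of expression-constrained FBA (target/regulator
  expression coupling) is deliberately out of scope; only the
  expression-to-upper-bound constraint is implemented.
- FASTCORE is approximately minimal in general; the exact-minimality
  tests restrict to chain/parallel topologies where the LP iteration
  provably attains the brute-force minimum.
- The QP stage returns one optimal flux witness; the witness (unlike
  the objective and α) is not unique.
- The harness evaluates third-party reconstruction methods only
  through the plugin contract; no other algorithm is reimplemented
  here.
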