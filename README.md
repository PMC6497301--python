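# gembench

Context-specific genome-scale metabolic model (GEM) reconstruction from
transcriptomics, plus the benchmark harness used to evaluate such
methods.

## The problem

A general human (or microbial) GEM contains every reaction known to
occur in any cell type, so it predicts the same phenotype for every
context. Context-specific reconstruction tailors the general network to
one cell line or tissue using omics data. Two broad families exist:
*bound-setting* methods that keep the network but constrain fluxes with
expression (TRFBA, PRIME, E-flux), and *extraction* methods that carve
out a subnetwork supported by expression evidence (FASTCORE,
FASTCORMICS, GIMME, iMAT, ...). This package implements a hybrid of the
two, aimed at cancer cell-line modeling where growth rates, CRISPR
essentiality screens and exometabolomics are the natural validation
data — and a quantitative benchmark suite for comparing any such method.

## The method

Expression caps metabolic capacity. For every gene *j* with expression
*E_j*, on the irreversible-split network the summed flux through the
reactions whose GPR (gene–protein–reaction rule) mentions *j* is
bounded:

```
sum_{i in R_j} v_i  <=  C * E_j
```

with a single scaling constant *C* (mmol gDW⁻¹ hr⁻¹ per expression
unit). Predicted growth is monotone nondecreasing in *C*: at *C* = 0
every gene-associated reaction is shut, and above a breakpoint *C_brk*
the constraints stop binding and growth equals the unconstrained flux
balance analysis (FBA) optimum *G_max*. The pipeline:

1. **C sweep.** Evaluate parsimonious FBA on a 500-point grid over
   [0, *C_brk*], recording fluxes and growth.
2. **Growth-correlated reactions.** Reactions whose sweep fluxes track
   predicted growth (Spearman |ρ| ≥ 0.9, Benjamini–Hochberg q < 0.05)
   form the core of the context model.
3. **Extraction.** A weighted FASTCORE variant pulls the core into a
   flux-consistent subnetwork: moderately expressed reactions cost
   nothing to add, non-expressed ones carry full penalty, and the
   biomass reaction plus a parsimonious flux mode supporting it is
   forced in, so the extracted model always grows.
4. **Calibration of C.**
   - *C_corr* (expression only): at each sweep point a QP converts the
     inequality to an equality with slack α_j and minimizes ‖α‖²; the
     count *N_α* of slacks below 1e−6 is tracked across the grid and
     the first sudden change (piecewise-constant change-point
     detection) marks *C_corr*.
   - *C_opt* (with a measured growth rate):
     `C_opt = (C_brk / G_max) × G_measured`, the linear form implied by
     the monotone growth-vs-C curve.

The harness scores any method (through a small plugin contract) on nine
benchmarks — growth-rate error, uptake/secretion-rate correlation, drug
response (max target-reaction flux at 50 % biomass vs IC50), essential
genes (FBA knockouts vs screens, hypergeometric enrichment),
oncogene/tumor-suppressor enrichment, blocked-reaction fraction
(FASTCC), resolution power (Jaccard within vs between context types),
robustness to missing data (repeated 5-fold cross-validation, 75
models) and robustness to noise (20 permutation-perturbed expression
sets spanning Spearman R ≈ 0…1) — then rank-normalizes the scores and
clusters methods hierarchically.

Everything runs on synthetic toy networks with planted ground truth
(blocked reactions, essential genes, the per-sample C that generated
"measured" growth), so the full pipeline is testable offline.

## Worked example

```python
from gembench import FixtureSpec, make_toy_model, make_expression_panel, TRFBACore

spec = FixtureSpec(seed=1)                   # 3 pathways x 4 steps, 20 samples
model = make_toy_model(spec)
panel = make_expression_panel(model, spec)
res = TRFBACore(model, panel[0], n_steps=100).fit()
print(res.summary())
```

prints

```
Context-specific reconstruction results
============================================
sample:                  sample_00
parent reactions:        18
extracted reactions:     16
growth-correlated core:  16
C_brk:                   12.4922
G_max (hr^-1):           10
calibration:             C_corr
C used:                  0.126184
predicted growth (hr^-1): 0.100937
```

Reading this: the sweep found the expression constraints stop limiting
growth at *C_brk* ≈ 12.5; 16 of 18 parent reactions correlate with
growth across the sweep (the planted dead-end side branch is excluded);
without phenotype data the slack-consistency change point picks
*C* ≈ 0.126, at which the extracted, re-constrained model predicts a
growth rate of ≈ 0.10 hr⁻¹. Supplying `growth_measured=` switches the
calibration to *C_opt* and the prediction lands on the measured value.

A thin CLI wraps the library: `gembench fixtures`, `gembench
reconstruct`, `gembench bench`, `gembench report` (see `--help`).

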