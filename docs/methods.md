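# Methods

## Overview

`hbmix` couples two population-level analyses of a urinary biomarker panel
(n individuals × p biomarkers, concentrations in µg/L with per-biomarker
limits of quantification):

* a **conditional-dependence network** on preprocessed concentrations,
  whose densely connected groups ("communities") are interpreted as
  real-life co-exposure mixtures; and
* a **hazard-index screen**, which scales raw concentrations by
  health-based guidance values and sums the resulting hazard quotients
  within each community.

The two branches deliberately share inputs but not transforms: the network
needs Gaussian-like, standardized, dilution-adjusted data, while hazard
quotients must be computed on raw-scale concentrations in the guidance
value's own units. Changing network preprocessing options therefore never
changes a hazard index.

## Data preparation for the network

Applied in order; each step is deterministic.

1. **LOQ filter.** A biomarker is dropped when strictly more than 40% of
   its non-missing values are below the LOQ (`max_censored_fraction`,
   default 0.40). Values at exactly the cutoff are kept. Biomarkers with
   no data are reported with reason "no data".
2. **Natural-log transform.** Urinary concentration distributions are
   right-skewed; logs bring them near normality. LOQs are transformed
   consistently.
3. **Censored imputation.** Each below-LOQ cell is replaced by the mean of
   a normal distribution conditional on the same individual's observed
   biomarkers, truncated above at log(LOQ):
   `E[X | obs, X < c] = m − s·φ(α)/Φ(α)`, `α = (c − m)/s`,
   where (m, s) are the conditional moments. Per-biomarker means and SDs
   are estimated by censored-normal maximum likelihood (Tobit likelihood,
   Nelder–Mead on (µ, log σ)); correlations come from pairwise-complete
   observed cells, shrunk toward the identity (intensity 0.1) and
   eigenvalue-clipped at 1e−6 so conditioning stays well-posed. Imputed
   values never exceed log(LOQ). A seeded draw from the truncated
   conditional is available (`random_draw=True`) for sensitivity analyses;
   the default single conditional-mean imputation is deterministic.
   Known moments can be supplied via `params` when an external estimate
   exists.
4. **Missing imputation.** Cells missing for other reasons (e.g.
   insufficient sample volume) are filled by iterated linear-regression
   single imputation (scikit-learn's `IterativeImputer` with an OLS
   estimator, no posterior sampling) — deterministic regression
   prediction from the observed biomarkers. Individuals with every
   biomarker missing are rejected.
5. **Outlier winsorization.** Per biomarker, values with robust z-score
   (median / 1.4826·MAD) beyond ±4 (`z_cut`) are clipped to the boundary.
   Winsorization preserves rank order and is conservative; the count of
   clipped cells is reported. Biomarkers with MAD = 0 are skipped with a
   warning.
6. **Standardize → adjust → re-standardize.** Biomarkers are scaled to
   mean 0, SD 1 (sample SD), then replaced by OLS residuals on an
   intercept, one-hot sex / smoking / education, age (years), BMI (kg/m²)
   and log creatinine (g/L), then re-standardized so the network input has
   unit scale. Log creatinine is the dilution correction: concentrations
   are modeled on the log scale and urine dilution acts multiplicatively,
   so the regression removes it exactly. Residuals are exactly orthogonal
   to every design column; rank-deficient designs fall back to the
   minimum-norm solution with a warning.

The order (adjusting after standardization, then re-standardizing) is a
design choice; on an uncensored, complete, covariate-free panel the whole
chain collapses to log + standardize.

## Network estimation

**Graphical lasso.** The precision matrix Ω is the maximizer of
`log det Ω − tr(SΩ) − λ‖Ω‖₁(off-diag)` for the empirical correlation
matrix S. Edges are off-diagonal entries with |Ω_ij| > 1e−8 (numerical
zero guard); partial correlations are `−Ω_ij/√(Ω_ii Ω_jj)`. The penalty
path holds 10 equally spaced values from λ_max = max|S_ij| (provably empty
graph) down to 0.1·λ_max. λ = 0 returns the unpenalized MLE S⁻¹ directly.

Solvers: the default LARS inner solver reproduces an independent ADMM
optimizer of the same objective to ~1e−13 per entry and is used for all
reported fits; coordinate descent (tol 1e−3, 100 iterations) is used only
inside StARS subsampling, where only the edge pattern matters — on
block-structured data it yields identical edge sets at ~20× the speed.

**StARS penalty selection.** For each λ the model is refit on
`n_subsamples = 20` subsamples drawn without replacement, of size
⌊10√n⌋ (capped at 0.8n). Per edge, the instability is `2·f̂(1 − f̂)` with
f̂ the subsample selection frequency — 0 when the edge is always or never
present, 0.5 at maximal disagreement. The per-λ instability D(λ) averages
over all p(p−1)/2 pairs and is monotonized by a running maximum from the
sparse end of the path. The selected penalty is the *smallest* λ (densest
graph) whose monotonized D stays ≤ 0.1 (`threshold`); if no penalty
qualifies, λ_max is returned with a warning. Subsampling is driven by a
mandatory seed; duplicated-row data (identical subsample correlation
matrices) provably yields zero instability.

**Walktrap communities.** Implemented from the random-walk agglomeration
description: each node's 4-step (`steps`) transition-probability profile
P^t defines the distance `r²_ij = Σ_k (P^t_ik − P^t_jk)²/d_k`; communities
merge bottom-up by the Ward-style criterion
`Δσ = |C₁||C₂|/(|C₁|+|C₂|)·r²(C₁,C₂)/n`, restricted to community pairs
joined by at least one edge (disconnected components can never merge).
The dendrogram is cut at the partition of maximum Newman modularity, ties
resolved toward fewer communities. Isolated nodes and groups smaller than
`min_size = 3` are reported as singletons: a pair of biomarkers is a
dependency, not a community. The default graph is unweighted (presence of
a conditional dependency); |partial correlation| weights are optional.
The implementation matches igraph's walktrap partition on planted
block-model graphs (adjusted Rand index 1.0 in the test conditions).

## Guidance values and hazard indices

The packaged database holds 18 entries (16 parent substances; cadmium has
two age bands, DEHP two metabolite sums) with value, units (µg/L, µg/g
creatinine, or µmol/mol creatinine), optional age range, population
(general / occupational), value type (HBM-GV, HBM-I, BMGV, BE) and source
tier: 1 = HBM4EU-derived, 2 = European regulatory agency, 3 = other
national regulatory agency, 4 = biomonitoring equivalent. The published
tally for this panel counts 17 parent substances for these 20 biomarkers;
the table resolves to 16 distinct parents, a discrepancy we document
rather than hide — the package asserts the biomarker-level count (20),
which is unambiguous.

Matching: candidate entries must contain the query biomarker in their
component set (sum queries must match the set exactly) and, where an age
band exists, contain the query age. General-population entries are
preferred; occupational entries (here: 1-hydroxypyrene and total chromium
BMGVs) are used only when nothing else exists and are flagged
`occupational_fallback`. Among candidates the best (lowest) source tier
wins, then the lowest value. Absence of a match is a normal result — most
biomarkers have no guidance value.

Unit conversion is dimensional analysis with creatinine molar mass
113.12 g/mol: µg/L ÷ creatinine (g/L) → µg/g creatinine;
µg/g creatinine × 113.12/MW → µmol/mol creatinine. Analyte molecular
weights ship alongside the database. All conversions are invertible.

Hazard quotients use raw-scale concentrations with censored cells at their
imputed value (exp of the log-scale conditional mean) by default; LOQ/2
substitution is available as a policy switch, since published practice
varies. Sum entries (DINCH, NMP) divide the summed metabolite
concentrations by the sum guidance value; DEHP computes both sums and
keeps the higher quotient per individual. Components are attached to the
community holding the majority of their member biomarkers (ties: first
member, with a warning). A community's HI sums its weighted members'
quotients; communities with fewer than two weighted members are reported
but flagged "not interpretable as mixture". Exceedance uses strictly
HQ > 1 / HI > 1. Geometric means exclude zeros (undefined otherwise) and
report the excluded count. Driver analysis reports each component's share
of the mean overall HI and the leave-out ratio
mean(HI) / mean(HI without the component).

## The synthetic generator

Real panels of this kind are individual-level health data and non-public,
so the generator is the package's test bed. It emulates:

* log-normal marginals — log concentrations are Gaussian with
  configurable per-biomarker location (default: spread over
  log 0.2 … log 20 µg/L) and scale (default log-SD 1.0, a geometric SD of
  ~2.7, typical for urinary biomarkers);
* planted partial-correlation blocks: within a block every pairwise
  partial correlation has magnitude `rho` (default 0.3); between blocks
  partial correlations are exactly zero. An all-positive
  equi-partial-correlation block of size k is positive definite only for
  rho < 1/(k−1) — a mathematical constraint, not an implementation one —
  so the default "auto" sign plants +rho where feasible and −rho
  otherwise (configurable); graph topology, which is what the network
  stage estimates, is identical either way;
* covariates of a children/adolescent survey population (sex, age 3–17,
  BMI, smoking, education) with optional log-scale effect sizes (default
  zero), and first-morning-void creatinine (log-normal, geometric mean
  1 g/L, log-SD 0.5) entering every biomarker multiplicatively with
  exponent 1 — the shared dilution the covariate adjustment must remove;
* left-censoring at a per-biomarker LOQ placed at the requested quantile
  of the realized concentrations (default 0.10), and missingness either
  cell-wise (default rate 0.02) or as whole biomarker columns missing for
  a subset of samples.

Defaults (n = 515, p = 51, eight blocks of 3–6) mirror the scale of a
national HBM survey subsample. The generator does **not** emulate:
measurement error and batch effects, non-Gaussian dependence (tail
dependence, nonlinear relations), informative missingness, real
concentration scales relative to guidance values, or age/sex-specific
exposure structure. Passing tests therefore demonstrate that the pipeline
recovers the structure it assumes, with realistic censoring, dilution and
sample size — not that any particular real population is safe or at risk;
synthetic exceedance fractions are artifacts of the arbitrary
concentration scales.

## Numerical choices and edge cases

* Positive definiteness of every planted precision matrix is verified at
  construction; infeasible sign/rho/block combinations raise.
* Glasso final fits: LARS mode, tol 1e−6; duality-gap convergence
  failures surface as warnings carrying the achieved gap.
* Conditional imputation guards: singular conditioning covariances fall
  back to least-squares pseudo-solutions (warned); samples with nothing
  observed fall back to the marginal truncated mean; Φ(α) underflow
  clamps to the truncation bound.
* Walktrap merge ties break on (Δσ, community indices) and modularity
  ties toward fewer communities, making partitions deterministic and
  invariant (up to relabeling) under biomarker permutation.
* Standardization uses the sample SD (ddof = 1); zero-variance biomarkers
  raise with the biomarker named.
* All stochastic steps (generator, StARS subsampling, truncated draws)
  take explicit seeds; identical seeds give byte-identical outputs.

## Problem sizes

The test suite and the acceptance script use: 20 random 3×3/4×4 matrices
for the optimizer-equivalence check; n = 500, p = 50, blocks
(6, 5, 4, 4, 3), 20 generator seeds for community recovery (median
adjusted Rand index ≥ 0.8); n = 800 × 3 biomarkers for the closed-form
truncated-mean check and n = 500 × 12 (30% censoring) for the
imputation-RMSE comparison; and one full study-scale pipeline run
(n = 515, p = 51). The whole suite runs in a few minutes on one CPU.

## Known limitations

* Dose additivity without mode-of-action grouping: the HI sums quotients
  across unrelated endpoints, a deliberately conservative first-tier
  screen. Synergy/antagonism, point-of-departure indices and
  mode-of-action grouping are out of scope.
* Guidance-value coverage (20 of 51 biomarkers) biases community HIs
  downward; the coverage table makes the gap explicit per community.
* StARS subsample counts/sizes follow the method's published defaults;
  the instability threshold 0.1 is a convention, not a significance
  level.
* The censored-imputation moment estimates (pairwise-complete
  correlations) are attenuated at heavy censoring; the 40% exclusion rule
  bounds the damage.
* Only urine is supported; combining matrices (e.g. blood + urine) is
  future work.
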