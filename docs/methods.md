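# Methods

This note records the statistical model, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer would want to audit.

## Data model

The unit of analysis is a cohort of participants with:

- **Mood items**: 30 ordinal items scored 0–4, five items per dimension
  (tension/anxiety TA, depression DD, anger AH, fatigue FI, confusion CB,
  vigor V). The five negative dimensions define "distress"; vigor is
  protective and never a screening candidate.
- **Coded covariates** D1–D12 (age group, marital status, menopause type,
  parity, education, employment, income, caregiver, insurance, surgical
  approach, tumor stage, treatment modality), stored as ordinal integer
  codes because the Gaussian network treats each as a single numeric node.
- **Psychosocial totals**: self-perceived burden (SPBS, 10 items 1–5,
  banded none <20 / mild 20–29 / moderate 30–39 / severe ≥40), neuroticism
  (BFI-N, 8 items 1–5, items 2/5/7 reversed), psychological capital (PPQ,
  26 items 1–5, items 8/10/12/14/25 reversed), illness perception (IPQR,
  8 scored items 0–10, items 3/4/7 reversed), and financial toxicity
  (COST-PROM, 11 items 0–4, items 2/3/4/5/8/9/10 reversed; *lower* totals
  mean worse toxicity).
- **Quality-of-life domains** E1–E12 on the standard 0–100 scale:
  functional domains score (1 − (RS − 1)/range)·100 (best functioning →
  100), symptom and global domains ((RS − 1)/range)·100 (worst burden →
  100), RS being the domain item mean and range the item range minus one.

Cronbach's α uses the population (n) variance denominator; the estimate is
invariant to that choice because the denominator cancels. The total
distress score defaults to the total-mood-disturbance convention (negative
dimensions minus vigor) with a switch for the plain negative sum; only the
direction of the total is externally constrained, not its formula.

## Synthetic cohort generator

Ordinal items arise from a latent Gaussian copula. The ground truth is a
sparse partial-correlation matrix Ω on the latent scale: full cliques
within each dimension block (weights drawn uniformly from a configured
range, seeded) plus explicit cross-block edges. The implied precision
I − Ω must be positive definite; if not, the diagonal is inflated uniformly
and Ω re-standardized, which shrinks all weights by a common factor, and
the build fails (naming the worst block) if the required inflation exceeds
a bound. A k-clique of equal partial correlations w is positive definite
only for w < 1/(k−1), so five-item blocks keep weights modest (default
0.12–0.18); the implied *marginal* correlations then fall in the 0.2–0.4
range typical of mood inventories.

Latent draws are thresholded into 0–4 categories by per-item cutpoints.
Cutpoints come from a graded-response family c_k = (k − 0.5 − μ)/σ: the
positive-response rate at the ≥2 cutoff pins one threshold and σ is solved
(bracketed bisection) so the implied mean Σ_k P(score ≥ k) matches the
target. Default marginal targets are the training-set means and positive
rates of the sixteen high-prevalence items; remaining negative items get
sub-50% prevalence (mean 1.35, rate 0.42) and vigor items moderate
endorsement (mean 2.0, rate 0.60).

Psychosocial totals and QoL domains are linear-plus-noise functions of
per-dimension latent factor means (e.g., burden loads 0.55 on fatigue,
neuroticism 0.40/0.25 on tension/depression, toxicity −0.35 on fatigue
because of its reversed direction), scaled to each instrument's range and
clipped; the generating loadings are kept in the dataset metadata for
recovery tests. Covariates are independent categorical draws matching
realistic cohort margins. Missingness is completely at random (MCAR) only —
the testable special case of the missing-at-random assumption the analysis
makes; rates are configurable because real-data missingness summaries are
not available.

**What the generator does not emulate**: informative missingness,
differential item functioning, acquiescence or response styles,
longitudinal structure, covariate–symptom confounding (covariates are
independent of symptoms by default, which is what the residual-network
invariance checks exploit), and item-level QoL responses (domains are
generated directly). Passing tests therefore certify the estimation
machinery under a correctly specified copula, not robustness to these
real-data features. Ordinal thresholding attenuates observed correlations
relative to the latent truth, so recovery tests compare against the latent
structure with stated tolerances.

## Preprocessing

- **Split**: uniform random partition with ⌊n·0.7⌋ training participants
  (the 0.7 default reproduces the 290/125 training/validation sizes at
  n = 415); seeded and serialized.
- **Imputation**: single-chain predictive mean matching. Columns cycle in
  fixed order for 10 iterations; each missing cell gets a least-squares
  linear prediction from the other columns and copies a random one of the
  5 nearest observed donors, so imputed ordinal values stay in the observed
  support. One completed dataset feeds the network pipeline (the m > 1 /
  pooling machinery of full multiple imputation is out of scope; nothing
  downstream pools).
- **Nonparanormal transform**: ties-averaged ranks scaled by 1/(n+1),
  Winsorized at δ_n = 1/(4 n^{1/4} √(π log n)), then mapped through the
  standard-normal quantile function. Rank-preserving per column; constant
  columns are rejected by name.
- **Correlation input**: Spearman on raw ordinal data for screening;
  nonparanormal + Pearson for network estimation (the input choice is
  recorded in every network's metadata because the source procedure does
  not pin it). If the smallest eigenvalue falls below 1e−6 the matrix is
  repaired by eigenvalue clipping and re-standardization, with the repair
  flag and maximum perturbation logged.

## Node screening

Candidates are negative-dimension items with positive-response rate
strictly above 0.50 at the ≥2 cutoff (the cutoff itself is a recorded
assumption; rates implied by the calibration targets are consistent with
≥2 rather than ≥1). Three tracks run on training data only:

- **Track A (Spearman)**: |ρ| ≥ 0.30 against the core distress indicator
  *and* positive rate ≥ 0.50. The core indicator is the leave-one-out
  negative-item total (total minus the candidate item), avoiding item-total
  inflation; a plain-total variant is configurable.
- **Track B (CV lasso)**: 10-fold cross-validated L1 linear regression of
  the continuous distress total on the standardized candidates, keeping
  items with nonzero coefficients at the minimum-CV-error penalty.
- **Track C (repeated CV logistic)**: stability selection — each of 100
  repetitions draws a random half of the training participants, runs
  stratified 10-fold CV over a 10-point log C grid inside the subsample,
  picks the strongest penalty within one standard error of the best mean
  accuracy, refits, and records the support; items retained if selected in
  ≥60% of repetitions. The half-subsampling and one-SE rule are this
  package's choices: penalties minimizing CV error are prediction-optimal
  but over-select, and without resampling the repetitions differ only in
  fold seeds, making selection frequencies nearly degenerate at {0, 1}.

Votes combine as 1·A + 2·B + 2·C with retention at vote ≥ 3 — the smallest
threshold at which no single track suffices but both penalized tracks do.
Redundant pairs (|ρ| > 0.80) are then pruned worst-first, keeping the item
more correlated with the core indicator (ties: higher variance, then
column order).

One structural caveat, documented deliberately: when the regression
outcome is the total of the very items being screened, the outcome is an
exact linear function of the predictors, and the penalized tracks select
densely — their discriminating power then comes from collinearity among
redundant items rather than from outcome association. The screen's overall
selectivity in that regime is concentrated in the prevalence filter,
track A, and redundancy pruning, which matches the reported behaviour of
the procedure this pipeline operationalizes (the candidate-to-final
reduction is attributed to redundancy control). The track functions
themselves accept arbitrary outcome vectors and behave as expected with
uncontaminated outcomes (pure-noise items fall below the 60% frequency
rule).

The frozen node set is fixed before any validation data are touched
(enforced by the interface: `screen_nodes` receives only training data).
Validation reports the AUC — Mann–Whitney rank formulation with tie
handling — of the frozen-node sum score against the median-dichotomized
distress total, plus per-node means and positive rates in both splits.

## Network estimation

The graphical-lasso solver is implemented in-package (numba-compiled block
coordinate descent with the covariance-update formulation) and
cross-checked in the test suite against an independent solver on shared
inputs. The diagonal is unpenalized, so the penalty at which the graph
empties equals the largest absolute off-diagonal input correlation; the
grid runs log-spaced from that λ_max down to 0.01·λ_max in 100 steps with
warm starts. Soft thresholding yields exact zeros, so edge support needs no
epsilon. Model selection evaluates EBIC with the penalized estimate's
profile Gaussian likelihood (no post-selection refit), E = nonzero
upper-triangle entries, γ = 0.50 everywhere by default; EBIC ties resolve
to the sparser (larger-penalty) model. Convergence failure at any penalty
raises, naming the penalty.

Residual networks regress each symptom on reference-coded covariate
dummies (first category by coded order is the reference; aliased designs
raise with the offending columns), then re-estimate on nonparanormal-
transformed residuals with γ = 0.50. Extended networks concatenate symptom
and external columns into one joint estimation, with node classes
(symptom/external) recorded in metadata.

## Stability and comparison

- **Edge bootstrap**: B = 1000 resamples with replacement, full pipeline
  refit per resample, 2.5/97.5 percentile bounds per edge.
- **Case dropping**: drop proportions 0.05–0.75 in steps of 0.05, B = 1000
  subsamples without replacement per proportion, Pearson correlation
  between subsample and full-sample centrality. CS = the largest drop
  proportion at which ≥95% of correlations are ≥0.7 (0 if none). Both
  strength and expected influence are supported; they coincide on
  all-positive networks.
- **Comparison test**: groups from a median split (ties to the low group).
  M = maximum absolute edge difference, S = |GS_low − GS_high|. The null
  distribution shuffles group labels with the full EBIC-glasso pipeline
  refit for both groups at every permutation (n_perm = 1000 default);
  p = (1 + #{perm ≥ obs})/(1 + n_perm), never exactly zero.

## Validation problem sizes

The simulation benchmarks use sizes chosen to estimate each operating
characteristic with useful precision: edge recovery and null selection use
50 replicates at n = 415 and p = 16 (sensitivity ≥ 0.8, specificity ≥ 0.6,
empty-graph rate ≥ 0.9 under independence); the permutation test's size
uses 200 replicate datasets of two 150-participant groups from one 8-node
ordinal generating network at n_perm = 200, with a 30-point penalty grid
for the refits; screening recall uses 20 planted-signal cohorts at n = 290
with 25 stability repetitions (the 60% retention rule and all thresholds at
their defaults). Bootstrap-based tests use reduced B with correspondingly
coarse assertions.

## Known limitations

- Single-chain PMM does not propagate imputation uncertainty; with the
  low MCAR rates simulated this biases nothing the tests measure, but
  real analyses with substantial missingness should pool over chains.
- Ordinal data enter the network through rank-based transforms rather than
  polychoric correlations; with five well-populated categories the
  difference is small, but polychoric input would be the natural extension
  for skewed items.
- CV-chosen lasso penalties over-select by design; only track C corrects
  for this (via stability selection). Track B inherits the liberal
  behaviour and is best read as a redundancy filter.
- The permutation comparison refits the full pipeline per permutation, so
  its cost scales linearly in n_perm × group fits; the penalty-grid size is
  exposed in configuration for exactly this reason.
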