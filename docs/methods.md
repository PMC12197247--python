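# Methods

`cavsat` implements a causal-inference workflow for comparing combined
anticoagulation + venoprotective therapy (CAV, rivaroxaban + aescin) with
standard anticoagulation (SAT, rivaroxaban alone) in retrospective deep-vein-
thrombosis inpatient cohorts, where treatment was assigned by clinicians and
the arms are heavily unbalanced (roughly 7:1). This note records the models,
the defaults and why, the numerical choices, and the known limitations.

## Outcome metrics

Six derived outcomes per admission, from day-1 symptom score `s1`, discharge
score `s0`, length of stay `LOS` (days) and total cost `C` (CNY):

| metric | definition | units |
|---|---|---|
| IPR | (s1 − s0)/s1 × 100 | percent (0–100 scale) |
| DIR | IPR / LOS | percent per day |
| CER | C / (s1 − s0) | CNY per score point |
| DIC | C / DIR | CNY |
| CLE | CER / LOS | CNY per day |
| LOS | LOS | days |

`dir·los = ipr` and `cle·los = cer` are exact identities and are enforced in
tests. A record with `s1 = s0` has undefined CER/DIC and is excluded (with a
logged reason); worsening (`s0 > s1`) is *retained* with negative IPR — only
the division-by-zero case forces exclusion, and there is no documented basis
for dropping negative improvement.

## Synthetic cohort generator

No public patient-level data exist for this problem, so the generator is a
first-class module: every downstream stage is validated against cohorts with
known structure and injectable true effects.

**Covariates.** 17 baseline variables (age, gender, height, weight, Wells
score, and 12 admission labs). Continuous variables use truncated normals
(location/scale set from the reported medians and IQRs of the real cohort,
IQR/1.35 as the normal-equivalent SD; lower bounds keep labs positive),
gender is Bernoulli, and the Wells score a discretized gamma. Marginals are
independent by default — the joint correlation structure of the real data is
unknown, and the confounding channel below already induces arm-wise
covariate correlation.

**Assignment.** Logistic propensity on z-scored covariates. Nonzero slopes
sit exactly on the covariates that were significantly imbalanced in the real
cohort: APTT (−0.60), PLT (−0.35), WBC (−0.35), TT (+0.50) and male gender
(+0.65). The intercept is calibrated by bisection on a fixed internal
covariate sample so that the marginal treated share equals the requested
fraction (default 48/396 ≈ 0.121). A degenerate assignment (a single arm)
raises an error naming the active coefficients.

**Outcomes.** The improvement *fraction* `f` (IPR = 100·f) is linear in
z-scored APTT and WBC with additive Gaussian noise, clipped to [−0.30, 0.98];
treatment shifts it additively by `effect_ipr_pp`/100 (default 6.4 pp, the
headline effect size). Discharge score is `s1·(1 − f)`, so the injected
effect lands directly in IPR percentage points. With probability
`zero_improvement_rate` (default 0.02) a patient improves by exactly zero in
both arms, feeding the exclusion pathway. LOS is a truncated-normal baseline
plus an additive treatment shift (default +0.15 days). Cost is log-normal,
increasing in LOS (elasticity 0.7), day-1 severity and APTT, with a
multiplicative treatment factor (default 1.02): costs are positive and
right-skewed, and the APTT loading gives the baseline–outcome network its
strongest expected edge (APTT–DIC).

**Potential outcomes and ground truth.** Both potential outcomes are drawn
for every record with shared noise; the observed outcome is selected by the
assigned arm, so the consistency axiom holds exactly. `ground_truth`
computes the true average causal effect of each metric by Monte-Carlo
contrast of the two potential-outcome arms on a fresh covariate sample
(default 10⁵ draws), excluding undefined draws and reporting the exclusion
rate and MC standard errors. Because it never touches assignment, the truth
is invariant to the treated fraction.

**Seeding.** One global integer seed spawns one `SeedSequence` substream per
record (each record consumes a fixed block of raw variates), so cohorts are
bit-reproducible and the first *k* records never change when the cohort
grows.

**What the generator does not emulate:** longitudinal trajectories,
missing data, site effects, and the real joint covariate dependence. Passing
recovery tests therefore demonstrate internal validity of the estimation
chain under this DGP, not performance on the real hospital data.

## Matching

All four methods produce 1:1 pairs without replacement on the 17 covariates.

- **Propensity model** — main-effects logistic regression (continuous
  covariates z-scored, gender 0/1), the field default when the model is
  otherwise unspecified. Constant covariates are dropped with a warning;
  perfect separation (fitted probabilities at the 10⁻⁸ boundary or |slope| >
  30) triggers an L2-stabilized refit with a warning.
- **Nearest-neighbour caliper** — greedy in descending treated propensity
  (hardest first), eligibility |Δ logit PS| ≤ 0.2 × pooled SD of the logit
  scores (the standard Austin recommendation; exposed as config). Unmatched
  treated are dropped — this is the only method that loses treated units.
- **Mahalanobis** — *global* greedy (smallest available distance first, ties
  broken by treated then control position) on standardized covariates with
  pooled within-arm covariance; ridge-regularized when near-singular, with
  an error naming collinear covariates when regularization fails.
  `diagonal=True` replaces the metric with plain Euclidean distance on
  z-scores, which is the degenerate case the genetic matcher reduces to.
- **Optimal with exact constraints** — Hungarian assignment minimizing total
  |Δ logit PS| within strata of the exact variables (default: gender, which
  the real analysis balanced exactly). A stratum with fewer controls than
  treated is relaxed into a final unconstrained assignment with a warning.
- **Genetic** — evolutionary search over positive diagonal weights `w` of
  the distance `sqrt(Σ w_j (z_tj − z_cj)²)`; each candidate induces a
  global-greedy match scored by (max post-match SMD, mean post-match SMD),
  minimized lexicographically. The all-ones vector is always in the initial
  population, so the result is never worse than the equal-weights match.
  Geometric crossover and log-normal mutation; reproducible by seed.

Balance uses the absolute standardized mean difference, pooled-variance
form for continuous covariates and the proportion form for binary ones;
zero pooled SD with equal means gives 0, with unequal means +inf and a
warning.

A note on balance improvement: with confounded assignment every method
reduces mean SMD in ≈99% of seeded replicates. On *unconfounded* data the
PS-free methods can worsen mean SMD through pure control-subsampling noise
(greedy Mahalanobis does so in roughly a fifth of replicates); the
improvement property is asserted where imbalance actually exists.

## Ensemble weighting

Each matched dataset is scored on five dimensions: mean SMD (weight 0.25),
max SMD (0.15), predictive performance (0.25), Rosenbaum robustness (0.30)
and treated-arm retention (0.05). Predictive performance is the average
out-of-fold R² (pooled SSE/SST) of random-forest regressions of each
outcome on the covariates + arm indicator under five-fold arm-stratified
CV; negative R² values are reported but floored at zero before
normalization so the composite stays convex. Robustness is the fraction of
the six outcomes whose Γ = 1.5 upper-bound signed-rank p stays below 0.05.
Per dimension, each method receives its share of the cross-method total
(inverse shares `1/(smd + 10⁻⁶)` for the two SMD dimensions); the
dimension-weighted sum of shares is renormalized to the final weights. This
normalization makes the weights sum to one, permutation-equivariant,
scale-free in the SMDs, and monotone in each dimension.

## Counterfactual effects

- **T-learner** — one random-forest regressor per arm (default 500 trees,
  unlimited depth, √p features per split — reproducibility over tuning),
  predicting both potential outcomes for every matched record; ITE = ŷ₁ −
  ŷ₀, ATE/ATT/ATC are subpopulation means, so `ate = (n_t·att + n_c·atc)/n`
  exactly. Training rows are canonically sorted before fitting so estimates
  are invariant to record order at a fixed seed.
- **Double residual** — out-of-fold (5-fold, arm-stratified) random-forest
  predictions of outcome (regressor) and treatment (classifier
  probability); the effect is the through-origin least-squares slope of
  outcome residuals on treatment residuals (an intercept variant is
  available by flag). An error is raised when residual treatment variation
  collapses below 10⁻¹².
- **Variable importance** — impurity importances averaged over the two arm
  forests, normalized to sum to one per outcome.
- **Aggregation** — the same ensemble weights combine ATE, ATT, ATC and the
  DR effect across methods (Σ w_m v_m), exactly linear.

Outcome models use only the 17 baseline covariates — no post-treatment
variables.

## Rosenbaum sensitivity

Hidden bias of odds Γ bounds the probability that a matched-pair difference
is positive between 1/(1+Γ) and Γ/(1+Γ). With signed-rank statistic T over
nonzero differences (mid-ranks on |d|), the bounds use the normal
approximation E± = p±Σr, Var± = p±(1−p±)Σr², one-sided in the direction of
each outcome's hypothesized benefit (IPR, DIR, CLE positive; DIC
sign-flipped; LOS and CER have no a-priori direction and are oriented by
the observed mean, doubled to two-sided in the robustness score). No
continuity correction is applied; exact 2ⁿ enumeration of the bounding
distribution is kept as a test oracle, where the uncorrected approximation
is accurate to ≲0.02 by n ≈ 10 but can differ by up to ~0.09 at n = 5.

The Γ-attenuated point estimate is the largest shift τ at which the
upper-bound p-value crosses 0.5, found by bisection on [min d, max d] to
10⁻⁸ of the range; at Γ = 1 it equals the Hodges–Lehmann estimate (median
of Walsh averages). The default sweep is Γ = 1.0 to 2.0 in steps of 0.1,
with monotonicity of both bounds asserted on every sweep.

## Correlation network

Spearman correlation by default (skewed labs, ratio-type outcomes; Pearson
by flag) over the 17 covariates and 6 outcomes; edges where |r| > 0.3
strictly. Node classes are baseline/outcome; baseline node importance is
the column sum of the normalized variable-importance table, outcome node
importance its degree in the thresholded graph (no formula for the real
analysis's node sizing is available, so degree is used as the transparent
choice). Both full-cohort and matched-sample scopes are supported.

## Pipeline

Multi-method matching is triggered exactly when the arm ratio exceeds 2:1;
otherwise the analysis runs on the single unmatched sample with a logged
skip and a unit weight. All stage seeds derive from one global seed through
hashed substreams, making reports byte-identical across reruns (no
timestamps are written). All artifacts are plain CSV/JSON/GraphML.

## Problem sizes used for validation

Chosen to make the validation suite informative at interactive runtimes:
the parameter-recovery study uses 20 seeded cohorts of n = 800 with 50-tree
CV forests and 150-tree T-learner forests and a 5×10 genetic search; the
determinism check runs the full pipeline twice at n = 400 with 60/40/40-tree
forests; `scripts/acceptance.py` runs 10 effect and 10 null recovery
replicates at n = 800. Forest size affects only Monte-Carlo noise in these
checks, not the estimand.

## Known limitations

- The composite-weight normalization ("share of the cross-method sum") is
  one reasonable realization of "weights inversely proportional to the
  SMDs"; the exact published weights (0.362/0.239/0.219/0.180) are not
  recoverable without the original data and are used only as fixed inputs
  to the aggregation layer.
- The published 95% CIs have no stated construction and are not reproduced.
- Rosenbaum bounds apply to matched pairs only; weighting estimators and
  (Λ,Δ) amplifications are out of scope.
- Greedy matchers reproduce no external package's tie-breaking; results are
  internally deterministic but not bitwise comparable to R's MatchIt.
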