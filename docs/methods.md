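# Methods

## Problem setting

An observational registry records, per patient: a treatment indicator Z,
overall survival OS in months, a censoring flag, and baseline /
treatment-path covariates X (age, sex, WHO performance score 0–4, RPA
prognostic class III–V, surgery, radiotherapy, chemotherapy; any covariate
may be missing). Treatment is not randomized: prognosis drives both
assignment and survival, so naive arm comparisons are confounded. The goal
is a *patient-level* effectiveness statement — a binary response label per
treated patient and an interpretable model of which patient classes
respond.

## Response labeling by matched survival gain

**Covariate screening.** Each candidate covariate is tested in a univariate
Cox proportional-hazards model (partial likelihood, Breslow ties, fit via
lifelines) against observed survival, with death as the event. Categorical
covariates are dummy-coded and tested by a joint Wald chi-square.
Covariates with p < α (default 0.01) enter the propensity model, ordered by
ascending p. Zero-variance or non-converging covariates are skipped with a
warning. A log-rank variant (`method="logrank"`, median split for
continuous covariates) is available; the choice of screening test is a free
design point, and the Cox Wald test is the default because it handles
continuous covariates without discretization.

**Propensity score.** PS = Pr(Z=1 | X) by maximum-likelihood logistic
regression (IRLS, converged when every score component < 1e-8, at most 100
iterations). Missing covariates are imputed by training mode (categorical)
or median (continuous), computed once and reused at prediction. Collinear
design columns and (quasi-)separation (any |coefficient| exceeding 15
during iteration) raise explicit errors — separation is surfaced, never
penalized away.

**Matching.** Each treated patient receives the k controls (default k=10)
minimizing |PS_i − PS_j|, *with replacement* across treated patients (a
control can serve many treated patients; this is forced by control pools
smaller than the treated arm) and without repeats within one match list.
Distance ties break by ascending control id, making the matching
deterministic and order-independent. No caliper by default (an option
exists). Weights are w_ij = 1/k, so Σ_j w_ij = 1 exactly.

**Survival gain and label.** SG_i = OS_i − (1/k) Σ_{j∈C(i)} OS_j, using
observed times regardless of censoring — the intended settings have rare
censoring (1–7%), and under this convention a censored treated patient can
only be mislabeled *non*-responder; those ambiguous patients (censored with
SG ≤ λ) are counted and reported, and an optional strict mode drops them.
Response = 1 iff SG > λ, strictly; SG = λ is non-response. TRR(λ) is
non-increasing and right-continuous in λ by construction.

Under no unobserved confounding and an additive treatment effect, the mean
of SG over treated patients estimates the mean individual treatment effect
among the treated; the test suite verifies |bias| < 0.5 months at n = 5000,
k = 10 on the synthetic registry.

## Classification tree

A from-scratch binary-outcome CART:

* **Impurity.** Gini 1 − p₀² − p₁² by default (`misclassification`
  available). Split gain is the impurity decrease computed on rows where
  the variable is observed, multiplied by the observed fraction, so heavily
  missing variables are penalized.
* **Split search.** Numeric: thresholds at midpoints of consecutive
  distinct observed values. Categorical: levels ordered by response
  fraction and scanned as ordinal, which is optimal for a binary outcome;
  the test oracle validates this against full 2^(L−1) subset enumeration.
  Both children must contain ≥ `min_bucket` observed rows. Ties break by
  schema column order, then smaller threshold / lexicographically smaller
  subset.
* **Surrogates.** For each internal node, every other variable's best
  split (either orientation for numeric variables) mimicking the primary
  left/right routing is ranked by agreement on rows where both variables
  are observed. A surrogate is kept only if its agreement count strictly
  exceeds the majority-direction baseline *and* the excess is larger than
  2.33 binomial standard deviations. The significance guard is needed
  because the agreement-maximizing threshold of even an independent
  variable drifts above the baseline by optimization alone; routing by such
  a chance surrogate is worse than the majority rule it replaces. Rows with
  a missing primary value route by the first usable surrogate, else the
  majority direction.
* **Growth defaults.** min_split = 20, min_bucket = 7, max_depth = 30,
  cp_grow = 0.01 — the classic CART conventions; all configurable. A split
  is accepted when n_node·ΔGini / (n_root·Gini_root) ≥ cp_grow.
* **Pruning.** Weakest-link cost-complexity pruning on misclassification
  risk produces the nested subtree sequence; cp values are alphas
  normalized by the root risk. 10-fold cross-validation (seeded random
  folds; a fold whose training complement is single-class is merged into
  its neighbor with a warning) regrows a tree per fold and scores each
  subtree at the geometric-mean penalties; the cp minimizing CV
  misclassification error is selected, ties resolving to the larger cp
  (simpler tree). A 1-SE rule is available by flag.
* **Prediction.** A record routes through primary splits, surrogates, then
  majority directions; the leaf's training response fraction is its score.
  Unknown categorical levels route by majority direction with a warning.

## Logistic baseline

A plain multivariable logistic regression of the response label on the full
covariate schema (configurable), sharing the IRLS core, encoding and
imputation rules with the propensity model. No regularization and no
interaction terms — it is the conventional comparison model, and its
main-effects form is exactly why an interaction-shaped response surface
favors the tree.

## Evaluation

80/20 seeded simple random split of the labeled treated patients
(unstratified by default; 3090 patients split into 2472/618). Confusion
matrices use predicted response iff score > threshold (strict). The ROC
sweeps distinct scores descending, one vertex per tied-score group; AUC is
the trapezoidal area, which then equals the Mann–Whitney U statistic with
half tie-credit exactly. The single reported (sensitivity, specificity)
pair sits at the Youden-J-optimal vertex (ties to the smaller FPR); a fixed
0.5 threshold is available instead.

## Iterative exploratory learning loop

`run_iteration` executes screening → PS fit → matching → SG → labeling →
split → tree (grow + CV prune) → logistic → ROC for one configuration,
deterministically given its seeds; `iterate` runs a configuration sequence
and stops once the tree AUC improvement falls below `tol` (default 0.005)
for `patience` consecutive iterations. The loop is deliberately
config-driven, not autonomous: its two levers — the covariate set and the
response definition — model an analyst consulting domain experts, so no
automated search over λ or covariates is performed. When ground-truth ITEs
are supplied, each report also carries the label agreement with true
responder status (true ITE > λ), which quantifies label spuriousness under
deliberate confounder omission.

## Synthetic registry generator

The generator is the package's test bed and defines its reference study
conditions (`default_config`):

* n = 4500 patients, ~2/3 treated; assignment log-odds fall with age
  (slope −0.062/year) and WHO score and rise with surgery, radiotherapy and
  chemotherapy, reproducing the key confounding signature of treated
  patients being about a decade younger than controls.
* Survival is Weibull with shape 6 and a covariate-dependent scale
  (accelerated-failure-time form), median near 12 months. The covariate
  effects on log-scale are proportional to the assignment log-odds: a
  single prognostic index drives both treatment and survival. This is a
  deliberate idealization — it makes the propensity score a monotone
  function of prognosis, so PS matching removes not just the mean
  confounding but the covariate-profile confounding of SG; without it, a
  tree can learn residual-confounding structure even when the true effect
  is zero.
* The planted effect is additive in months, applied to treated patients
  only (floored so OS ≥ 0): by default 6 months for age ≥ 50 ∧
  chemotherapy = 1, else 0. `true_ite` evaluates the rule on the complete
  (pre-missingness) covariates, which the generator retains.
* Censoring is independent uniform truncation at rate 0.04; missingness is
  MCAR (WHO 5%, RPA 5%, sex 2%); RPA class is a deterministic function of
  age and WHO score (III if age < 50 and WHO 0; V if WHO ≥ 2; else IV), a
  realistic collinear covariate.
* The age distribution (mean 52, sd 14) and chemotherapy prevalence (0.62)
  are chosen so the planted rule is *identifiable*: the age-50 boundary
  sits near the distribution's center and chemotherapy is prevalent enough
  that the age split carries the largest root gain. Likewise the Weibull
  shape keeps within-stratum survival noise (SG sd ≈ 4.5 months) low
  enough that a 6-month benefit separates from noise at n = 3000. A real
  glioblastoma registry is older, uses less chemotherapy, and has heavier-
  tailed survival; passing recovery tests here demonstrates the pipeline's
  correctness under recoverable conditions, not that a real registry's
  effect sizes are detectable.

What the generator does **not** emulate: informative censoring, MNAR
missingness, treatment-path time ordering (e.g. deaths before treatment
start), multiplicative or negative-only effects, and the joint covariate
dependence of a real registry beyond the deterministic RPA rule.

## Numerical choices

Months throughout (1 month ≡ 30.44 days). Gain comparisons use a 1e-12
tie tolerance; a split must have gain > 1e-12 to be accepted. The Youden
maximizer uses a 1e-12 tolerance so float dust cannot decide ties. Seeds:
every stochastic step (generation, splitting, CV folds) takes an explicit
integer seed; identical configuration ⇒ byte-identical output.

Problem sizes in the test suite (n = 3000–5000 cohorts, 20–50 seeds for
Monte-Carlo checks, 200 nodes for enumeration oracles) were chosen as the
smallest sizes at which the targeted properties are statistically stable.

## Known limitations

* SG ignores censoring by design; with censoring far above ~10% the
  labeling degrades and the strict mode (dropping ambiguous labels) or a
  semi-supervised treatment of the label would be needed.
* Matching controls only for *observed* covariates; the
  confounder-omission test quantifies, but nothing corrects, unobserved
  confounding.
* The categorical split optimization assumes a binary outcome; the tree is
  not a regression tree.
* CV pruning regrows fold trees with the same growth cp (0.01), so the cp
  grid explored is bounded below by the growth threshold, as in the classic
  implementation.
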