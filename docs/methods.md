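# Methods

This note documents the statistical models, the numerical choices, the
synthetic-data generator, and the limits of what the test-suite can show.

## Ordinal assessment model

The causality category Y ∈ {1,…,5} (WHO-UMC-style, increasing certainty) is
modelled by a cumulative logit regression on p = 11 Boolean report
variables. The partial proportional-odds (PPO) form is

logit P(Y ≤ j | x) = θ_j + βᵀ x_par + τ_jᵀ x_non,  j = 1,…,J−1,

with the predictors partitioned into a *parallel* block (one shared slope
per variable) and a *non-parallel* block (one slope per variable per
logit). With an empty non-parallel block the model reduces exactly to the
proportional-odds model, and the fitted log-likelihood of the PPO model can
never fall below it (nesting; asserted in tests to 1e−8).

Only J − 1 = 4 cut points are identifiable for a 5-level outcome
(P(Y ≤ 5) ≡ 1), so θ has four entries. The linear predictor enters with a
**plus** sign: positive coefficients push probability toward low
categories. This is documented prominently because the opposite convention
(θ_j − βᵀx) is at least as common; negate coefficients to compare with
packages using it.

Category probabilities are differences of logistic CDFs,
P(Y = j) = F(η_j) − F(η_{j−1}) with F(η_0) ≡ 0, F(η_J) ≡ 1. A denominator
of the form 1 − exp(η) appears in some printed statements of this model
family; it is not a probability (it can leave [0, 1]) and the standard
logistic inverse exp(η)/(1 + exp(η)) is what is implemented.

### Fitting

Exact maximum likelihood. The negative log-likelihood and its analytic
gradient are evaluated vectorised over records; L-BFGS-B iterates from the
closed-form intercept-only start (θ_j = logit of the empirical cumulative
frequency of {Y ≤ j}, zero slopes). Consequences of this design:

* an intercept-only model converges at its start, so fitted cumulative
  probabilities equal the empirical cumulative frequencies to well below
  1e−8 (asserted);
* the optimiser is deterministic — identical data and options give
  bit-identical estimates (asserted); the `seed` field in `FitOptions`
  exists for forward compatibility and is unused by the current optimiser;
* default `gradient_tolerance` is 1e−7 (projected-gradient norm), default
  `max_iterations` 500; non-convergence sets `converged=False` with a
  warning, never an exception;
* an optional ridge penalty (default 0) on β and τ is available for
  separated data; it is excluded from the reported log-likelihood;
* standard errors come from the inverse of a finite-difference Hessian of
  the negative log-likelihood at the optimum.

During line search a category probability can be non-positive; the
likelihood clips probabilities at 1e−12 inside the log, which leaves the
interior optimum untouched while keeping the objective finite.

### Cut-point monotonicity and crossing curves

θ is fitted unconstrained. A PPO model can produce crossing cumulative
curves (non-monotone η_j at some x), which yields negative category
probabilities. Policy: after fitting, monotonicity is checked at every
training point and recorded in `monotone_ok` (with a warning when
violated); at prediction time negative entries are floored at 1e−12 and the
vector renormalised, and each such row increments `n_crossing_events`.
Invalid probability vectors are never returned silently.

### Empty outcome categories

In real expert-labelled data some categories go unused (provincial experts
may never assign category 1), leaving the corresponding cut point
unidentified (it diverges). Default policy: refuse to fit, naming the
category. Optional policy `merge`: fit on the J′ observed levels with J′−1
cut points, mapping each absent level to its nearest present neighbour
(lower preferred) and reporting a zero probability for it in the 5-vector.
The merge necessarily shortens θ; the model records which categories were
observed.

### Parallel-assumption screening

The paper-level choice of *which* variables violate the parallel assumption
is made by per-variable likelihood-ratio tests: for each predictor, the
all-parallel fit is compared with the fit freeing that one predictor across
the four logits (3 extra parameters, so df = 3). `select_partition` flags
every variable with p < α (default 0.05) against the same all-parallel null
— a single screening pass, not a sequential procedure; with α = 0 the
screen is skipped entirely. Calibration is verified by simulation: under a
truly parallel 3-predictor model at n = 1000, the empirical type-I error
over 500 replicates is required to lie in (0.03, 0.07) at α = 0.05.

### Prediction

`predict_category` is the argmax of the category probabilities, with exact
ties (within 1e−12) broken toward the lower category — the conservative
direction for a certainty scale.

## Baselines

* **Multinomial logit** — softmax-linear model over the same predictors,
  backed by `statsmodels.MNLogit` after relabelling so the configurable
  reference category (default 4) is the omitted level. Changing the
  reference reparameterises coefficients but leaves fitted probabilities
  invariant (asserted to 1e−6 on well-conditioned data; with Boolean
  predictors and rare cells the likelihood can be nearly flat at large
  coefficients, where the invariance holds only to optimiser tolerance).
* **Decision tree** — CART (Gini, no depth limit, minimum leaf size 1,
  fixed random state) from scikit-learn; leaf class frequencies serve as
  probabilities.

Both expose `category_probabilities` over the fixed 1..5 space and run
through the identical evaluation path as the ordinal model.

## Evaluation

Accuracy is exact-match proportion. F1 is the per-class harmonic mean of
precision and recall, with 0 for classes never predicted and never true.
ROC is one-vs-rest per class with the class's predicted probability as
score; AUC is the Mann–Whitney concordance with ties counted 1/2
(trapezoidal; verified against an O(n²) concordant-pair oracle). Classes
absent from the truth have undefined ROC: they are reported as missing and
excluded from the macro average (the analogue of an unused expert
category). Micro AUC pools the n×5 one-hot expansion.

## Warning signal

Components d, r, t as in the README. Two variants of s ship because the
published formula and the published worked examples disagree for d < 0: the
literal formula s = r·(d+1) gives −8 and −12 for the patterns printed as
−12 and −16, while applying the +1 offset only for d ≥ 0 reproduces every
printed value and the stated serious-side extreme ±16. The table-consistent
reading is the default; the literal variant remains selectable
(`variant="eq8_literal"`) for users who want the formula as printed.

Exhaustive enumeration over all 25 (Y, Y⁰) pairs gives the attainable sets

| variant | normal ADE | serious ADE |
|---|---|---|
| literal | {−3,…,3} | {−12,−8,−4,0,4,8,12} |
| table-consistent | {−4,−3,−2,−1,1,2,3} | {−16,−12,−8,−4,4,8,12} |

Serious reports satisfy |s| ≥ 4 under the table-consistent variant and
normal reports |s| ≤ 4; the severity separation is therefore sharp except
at a single shared boundary value per variant (−4 table-consistent,
0 literal). Signals are undefined (and excluded from filters) when either
assessment is the missing code −1.

Y⁰ defaults to the reporter-institute assessment and is configurable among
the four recorded assessments.

## Triage and export

Queries are pure conjunctions of per-column predicates (eq/ne/lt/le/gt/ge/
in_set/between), matching brushing semantics — one range per axis;
disjunction is deliberately unsupported. Filtering preserves row order, is
idempotent, and is order-invariant in the predicates (property-tested, and
checked against a full-scan oracle on 10,000-row tables). The interactive
browser front end is out of scope; `export_viz` writes the data contract
instead — a JSON document with the default axis ordering, per-row values
and the category→colour map (1 red … 5 blue, a 5-class red-yellow-blue
scheme), plus a static self-contained HTML/SVG snapshot any front end can
replace.

## Synthetic-data generator

`simulate_reports` draws, per report: eleven independent Bernoulli
predictors; the true category from the PPO law of a configurable
`true_model` (generation refuses non-monotone parameter sets, naming the
offending pattern); reporter, institute and municipal assessments as the
true category plus independent clamped offsets (default distribution 0
w.p. 0.6, ±1 w.p. 0.15, ±2 w.p. 0.05); the provincial assessment equal to
the true category but masked to −1 with probability `missing_prov_rate`;
and a serious flag equal to the OR of the six severity items.

Defaults are chosen to resemble a provincial SRS corpus: n = 20,022
(matching the labelled-set size the pipeline is meant for),
`missing_prov_rate` 0.85 (most reports never receive provincial review),
suspect-drug rate 0.8, causality-item prevalences 0.75/0.65/0.45/0.08/0.20
(time relationship and known type are commonly affirmed, rechallenge is
rare), severity-item prevalences 0.015–0.10 (individually rare, ~20%
serious overall). The default true model uses cut points logit(j/5)
(uniform categories at x = 0), parallel slopes drawn once from a fixed-seed
standard normal scaled by 0.8, and one non-parallel variable
(`casualty_assessment_5`, *can be explained by other factors*) with slope
vector (1.2, 0.8, 0.4, 0.2) — monotone for Boolean inputs yet a clear
parallel-assumption violation.

The generator's marginal category distribution is available in closed form
(exhaustive sum over the 2¹¹ covariate patterns) and the Monte-Carlo
output is required to match it within 3 binomial standard errors at
n = 50,000.

**What the generator does not emulate:** covariate correlation (real
causality items are strongly dependent), systematic reporter bias
(under-grading by busy reporters is directional, not symmetric), unused
expert categories, drift over time, and free-text content. Passing tests
therefore demonstrate correctness of the machinery and recoverability under
the assumed law — not expected performance on real SRS data, where accuracy
is driven by how informative the 11 items actually are.

## Verification problem sizes

The validation suite runs at: likelihood-oracle agreement on 20 datasets of
n ≤ 50 (tolerance 1e−4, iterated Nelder-Mead restarts as the independent
optimizer); parameter recovery at n = 5,000 (every coefficient within 3
standard errors of truth); estimator-consistency check over n ∈ {500,
2,000, 8,000} with 40 replicates per size (mean absolute error strictly
decreasing); LR-test calibration over 500 replicates at n = 1,000; AUC
oracle on 100 instances of n ≤ 200 plus a 500-permutation null; triage
oracle on 10,000 rows. These sizes give each stochastic check a comfortable
signal-to-noise margin while the whole suite completes in a couple of
minutes on one CPU.

## Known limitations

* Standard errors are asymptotic (observed-information); no profile or
  bootstrap intervals.
* The LR screen tests variables one at a time against the all-parallel
  null; with many truly non-parallel variables a joint or sequential
  procedure would be more powerful.
* The merge policy for empty categories changes the outcome space rather
  than constraining the cut point; refitting on fresh data with the
  category present requires a new fit.
* `category_probabilities` accepts real-valued inputs (the mathematics does
  not require Boolean x) but the schema, CLI and generator are Boolean-only.
* Logit link only; no Bayesian fitting; no learned or re-weighted variant
  of the warning signal.
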