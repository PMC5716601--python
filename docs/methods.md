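# Methods

`valuetasks` implements a complete analysis chain for comparing the economic
value functions elicited by three behavioral tasks — binary choice, desirability
rating, and grip-force production — over composite monetary offers (a gain G
for the subject and a donation D for a charity, both 0–100 €). This note
documents the models, the numerical choices, and what the synthetic cohort
does and does not emulate.

## Value-function model space

Twelve candidate value functions map an offer to a scalar utility: Leontief-style
`mini` = min(αG, βD) and its `maxi` counterpart; additive forms with optional
curvature (shared or separate exponents) and optional multiplicative
interaction; a linear-equity form with an |G−D| regressor; the Fehr–Schmidt
inequity-aversion function G − α·max(D−G,0) − β·max(G−D,0); the Cobb–Douglas
production function G^δ·D^(1−δ); and the constant-elasticity-of-substitution
(CES) family

    V(G, D) = (α G^δ + (1−α) D^δ)^(1/δ),   α ∈ [0,1], δ > 0,

whose weight α ("selfishness") and exponent δ ("concavity") are the quantities
of interest. Linear (δ=1), Cobb–Douglas (δ→0) and Leontief (δ→−∞) are
special or limit cases of CES; the negative-δ branch is excluded here because
Leontief and Cobb–Douglas enter the comparison as separate models, and because
restricting δ to (0, ∞) via a log transform avoids 0^δ singularities on the
offer grid (0 € amounts are legal offers; 0^δ is evaluated as 0 for δ > 0,
and CES falls back to the weighted geometric mean below δ = 1e−8).

Every free parameter carries a bijective transform to an unconstrained
coordinate: logistic for unit-interval parameters (CES α; the Cobb–Douglas
exponent, which must stay in (0,1) for the function to remain monotone in
both dimensions and finite at D = 0), log for non-negative weights and
exponents, identity for interaction weights and the Fehr–Schmidt envy/guilt
parameters (the conventional 0 ≤ β < α restriction is *not* imposed). All
fitting happens in the unconstrained space.

## Observation models

The three tasks share the value function but differ in how value becomes
behavior. Each response rule is the maximizer of a task-specific net utility:

* **choice** — the win probability of the chosen offer is fixed (70%), so the
  net utility is 0.7·(V_chosen − V_unchosen); choices follow a softmax on the
  value difference, p(left) = 1/(1+exp(−(V_L−V_R)/β)) with temperature β. The
  fixed uncertainty cancels: rescaling the win probability is equivalent to
  rescaling β, so it is not a separate parameter.
* **rating** — the subject minimizes the squared error between the overt
  rating and the covert judgment, so the optimal rating is the value itself.
* **force** — the win probability equals the produced force fraction F and a
  quadratic effort cost is subtracted, U = V·F − γF², maximized at
  F* = V/(2γ): again linear in value.

Since the optimal rating and force are linear in value, both are modelled as
R = a·V + b clipped to the response bounds (rating 0–10; force 10–100 % of
maximal force, the 10 % floor being the required minimal squeeze), with
Gaussian noise of fitted SD. Censoring at the bounds is ignored in the
likelihood — clipping compresses the response distribution but does not bend
the linear scaling. Reaction times and time costs are not modelled.

## Fitting: MAP + Laplace evidence

Each (value function × task × subject) cell is fitted by maximum a posteriori
estimation under independent Gaussian priors, N(0, 3) on every unconstrained
parameter (broad enough to cover, e.g., δ from ≈0.1 to ≈10 within one prior
SD on the log scale) — with one scale-aware exception: the rating/force
intercept lives on the response scale, so it receives a weakly-informative
N(0, range²) prior derived from the task's response bounds. (A unit-scale
prior on an intercept of tens of response units would dominate the
likelihood and, in testing, systematically distorted force fits in favour
of over-flexible value surfaces.) Priors are configurable per parameter.
Rating/force fits add slope, intercept and log-noise-SD as free parameters;
choice fits add the log-temperature. Optimization is multistart L-BFGS-B (default 8
restarts, seeded; prior mean plus random draws; ties broken by higher log
joint then smaller parameter norm). The log model evidence uses the Laplace
(free-energy) approximation

    log p(y|m) ≈ log p(y, θ*|m) + (k/2)·log 2π + ½·log det Σ,

with Σ the inverse Hessian of the negative log joint at θ* (finite
differences, symmetrized, diagonal-jitter-repaired to SPD when needed). The
original analysis toolchain iterates a full variational-Bayes scheme; under
the Laplace approximation both target the same free energy, and the
implementation here is validated against two oracles: the conjugate
closed-form marginal likelihood of a linear-Gaussian model (agreement to
1e−6) and brute-force grid quadrature of a nonlinear two-parameter CES joint
(agreement within 0.5 nats). Explained variance is 1 − SS_res/SS_tot on
responses; for choices the 0/1 outcome is compared with the predicted
probability (one reasonable convention among several; reported choice-task
R² values are not comparable across conventions).

Pooled three-task fits tie one named CES parameter (selfishness or concavity)
across tasks according to one of the 5 set partitions of {force, rating,
choice}, keeping every other parameter task-specific; the joint likelihood is
the sum of task likelihoods. These 13-or-so-parameter fits are warm-started
by assembling the independent per-task MAP estimates (tied slots take the
class mean), which in practice is what makes the all-distinct partition reach
its optimum reliably.

## Group-level model selection

Subject-wise log evidences feed the random-effects Bayesian model selection
scheme: a variational Dirichlet-multinomial fixed point in which subject n's
posterior model attribution is ∝ exp(lme_nk + ψ(α_k) − ψ(Σα)) and the
Dirichlet pseudo-counts are the prior counts plus summed attributions.
Expected frequencies are Ef = α/Σα; exceedance probabilities (the posterior
probability that a model is the most frequent in the population) use the
regularized-incomplete-Beta closed form for two models and seeded, chunked
Monte-Carlo sampling (default 1e6 draws) otherwise.

For the same-vs-different value-function question the three per-task
12-model evidence matrices are combined into the 12³ = 1728-column space of
task-wise assignments (per-subject evidence of a triple = sum of the three
task evidences, as the fits are independent); the 12 diagonal triples form
the 'same' family, the remaining 1716 the 'different' family. Family
inference assigns each family equal prior Dirichlet mass spread uniformly
over its members (prior count 1/12 vs 1/1716 per model) — without this the
12-vs-1716 comparison would be decided by the prior — and aggregates
posterior mass within families (Dirichlet aggregation). Two quirks of this
standard scheme are worth knowing: a subject with flat evidence is attributed
toward the currently more frequent models (not uniformly), and very small
per-model prior counts in large families create a digamma barrier that
models must overcome with evidence. Both are properties of the variational
fixed point, not bugs.

## Adaptive choice design

The choice task selects offer pairs online to sharpen an a-priori value
function that is linear in G, D and G·D. Informative pairs are crossed (one
option higher on gain, the other on donation), differ on both dimensions,
and are never repeated; on the 10 € grid these number C(11,2)² = 3025 of the
121² = 14641 ordered pairs. After each choice the Gaussian posterior over
(β_G, β_D, β_GD) is refreshed with one Newton/Laplace step for the logistic
observation; the next pair minimizes the expected post-update covariance
trace (A-optimality), averaging the two outcomes under the current
predictive probability. The search is restricted to pairs varying a single
dimension from the previous pair, alternating gain and donation across
trials (the strictness of this alternation is a design choice; candidate
amounts are subsampled to 5 € by default for tractability, configurable to
the full 1 € grid). The design prior is N((0.5, 0.5, 0), diag(0.25, 0.25,
2.5e−5)) with fixed temperature 10 — weights on the euro scale, the
interaction entry scaled for the G·D regressor.

## Convergence / trial-efficiency analysis

Estimation convergence is tracked by the relative per-trial drop in mean
posterior variance, γ_t = (σ_{t−1} − σ_t)/σ_{t−1}; the minimum informative
trial count is the last trial with γ_t above 5 %. Three σ series are
implemented:

* `information_sigma_trace` (used by the pipeline): posterior precision =
  prior precision + accumulated per-trial Fisher information evaluated at the
  subject's full-data MAP estimate. This is the natural post-hoc measure when
  trials are *reordered by informativeness after fitting*: σ decays smoothly
  and deterministically, and the decay rate directly reflects the ordering.
* `incremental_sigma_trace`: full MAP refits with trials 1..t (warm-started).
  Faithful to an online re-estimation protocol, but the refit Laplace
  covariance fluctuates non-monotonically by a few percent late in the
  sequence, which makes the "last γ > 5 %" statistic extreme-value-like; it
  is provided for completeness, not used for the headline comparison.
* `sequential_sigma_trace`: a Laplace assumed-density filter (one damped
  Newton step per trial, PSD-projected curvature).

The optimized order draws its first eleven trials (seeded) from offers whose
amounts lie in {0, 30, 50, 70, 100} € on both dimensions — a coverage
lead-in — and appends the rest greedily by minimum posterior trace. With
per-trial information at the fitted CES parameters, the optimized order
reaches the 5 % threshold in roughly a quarter to a third of the trials the
native randomized order needs on simulated rating and force data.

## Synthetic cohort

No behavioral data accompany the analysis, so a generator produces cohorts
with the assumed statistical structure: by default 19 subjects, each with a
CES value function, rating/force designs covering all 121 grid offers once
(three sessions of 40/41/40), and 200 informative choice pairs on the 1 €
grid (sampled, or produced online by the adaptive engine). Population
defaults, chosen to match the study conditions the analysis assumes and then
fixed:

| quantity | default | rationale |
|---|---|---|
| selfishness α | logistic-normal, centre 0.58, logit-SD 0.7 | group mean ≈ 0.58, native SD ≈ 0.15 |
| concavity δ | log-normal, centre 1.5, log-SD 0.5 | between-subject SD comparable to the reported group dispersions |
| temperature β | log-normal, centre 7 € | calibrated so balanced choice accuracy lands near 0.8 |
| rating scale | a ≈ 0.1, b ≈ 0, noise SD 1.0 | maps V∈[0,100] onto the 0–10 scale; mean R² ≈ 0.84 |
| force scale | a ≈ 0.8, b ≈ 30, noise SD 12 | mean force ≈ 65–70 % of max; mean R² ≈ 0.70 |

`study_matched_config()` produces the cohort used for the parameter-sharing
analysis: α a single subject-level trait, δ task-specific — centred per task
at 1.98 (force), 1.60 (rating), 1.10 (choice) with per-task log-SDs
(0.65, 0.50, 0.50) matching the reported group dispersions — and drawn
independently per task, since concavity shows no cross-task correlation.
Selfishness draws are shared across tasks, which reproduces the strong
cross-task α correlations.

A caveat discovered in closed-loop testing: with concavity drawn
independently per task at these dispersions, a sizeable fraction of
subjects end up with two task concavities that coincide by chance, and the
pooled-evidence partition selection then prefers the corresponding
partial-sharing partition over the fully distinct one. Across cohort draws
the *shared*-concavity partition is consistently and decisively rejected,
but which of the non-shared partitions wins varies from cohort to cohort —
a reminder that group-level moments under-determine the per-subject
structure this comparison is sensitive to.

What the generator does **not** emulate: fatigue or session drift (the
model-free fatigue regressions are null by construction, so their passing
only shows the absence of a spurious effect), reaction times, risk-attitude
differences between tasks beyond what the response rules imply, and any
deviation of real subjects from the CES family. Closed-loop results
therefore validate the *inference machinery* — that the pipeline recovers
what was put in — not the paper's empirical claims about human subjects.

## Problem sizes and reproducibility

Default analysis scales: 12 models × 3 tasks × 19 subjects for the family
comparison; 5 partitions × 2 roles × 19 subjects (pooled fits, 2–4 restarts
with assembled warm starts) for parameter sharing; 19 subjects × 2 orders
for convergence. Reduced restart counts (2–4 instead of 8) are used in the
batch stages; with warm starts they reach the same optima in spot checks.
All randomness flows from one master seed through `numpy` SeedSequence
spawning; pipeline artifacts are byte-identical across runs with the same
seed.

## Known limitations

* MAP + Laplace can misestimate evidence for strongly non-Gaussian
  posteriors (e.g., near-boundary α); the quadrature oracle bounds this for
  the 2-parameter CES case only.
* Force responses crowd the 100 % ceiling for high-value offers (the
  scaling targets a ~70 % mean force, as in real grip data) and the
  Gaussian likelihood ignores that censoring; with the scale-aware
  intercept prior the resulting bias is small, but strongly saturating
  subjects are fitted slightly conservatively.
* The Bernoulli-residual R² for choices is one convention among several.
* Family inference inherits the variational scheme's small-count barrier
  (see above); exceedance probabilities for >2 groups are Monte-Carlo
  estimates with ~1e−3 error at the default sample size.
* The greedy A-optimal design is one-step lookahead only; no attempt is made
  at non-myopic design.
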