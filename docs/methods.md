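# Methods

This note documents the models, generators and numerical choices behind
`delaychoice`: what is computed, what the synthetic cohorts do and do not
emulate, and where the design was genuinely open.

## Task design

An episodic session is a 72-trial factorial: 36 obs/sim trials (ecological
condition: immediate option pictured, delayed option text-only), 18 obs/obs
and 18 sim/sim (control condition), with domain (food, culture, sport) ×
condition × delay (1 month, 1 year, 10 years) fully crossed — 4 repetitions
per domain–delay cell in the ecological subtype and 2 in each control
subtype, which is the only split the arithmetic admits. Presentation order
(immediate vs delayed first) and the immediate option's screen side are
counterbalanced as exact 50/50 splits, randomly assigned per seed. Delay
labels convert to days as 1 day = 1, 1 month = 30, 1 year = 365, 5 years =
1825, 10 years = 3650; the model consumes delays in days.

Option items come from a 30-item catalog (10 per domain, price tiers 1–10
by list order). Items are drawn from a per-domain shuffled deck without
replacement; since a session needs 48 item slots per domain, the deck is
reshuffled whenever fewer than two items remain, which preserves the
without-replacement property at deck scale and guarantees the two options
of a trial are distinct.

The monetary session keeps the condition × delay crossing. The 72 immediate
payoffs are a permutation of the 0.5:0.5:36 € grid (used exactly once
each); each delayed payoff adds an extra drawn without replacement from
1:36 €, the 36-element vector being consumed once per half-session block of
36 trials. Hence every extra appears exactly twice per session and delayed
− immediate ∈ [1, 36] always.

Variant `expA` reuses the full episodic factorial (choice screens only, a
presentation detail with no computational consequence here); `expB`
restricts to food items with delays 1 day / 1 month / 5 years and 36 trials
(18/9/9), keeping the 2:1:1 subtype ratio and the equal obs/sim option
counts per condition.

## Computational model

Monetary amounts are mapped affinely onto the rating interval, min → −10
and max → +10, by default over the empirical range of the session's pooled
immediate and delayed amounts (a fixed theoretical range, e.g. 0.5–72 €,
can be passed instead; the choice is a free parameter of the analysis, not
of the data). Values are then discounted hyperbolically, V = R/(1 + kD),
and choices modelled by the softmax P_imp = exp(Vi/β)/{exp(Vi/β) +
exp(Vd/β)}, computed in the overflow-safe logistic form
P_imp = σ((Vi − Vd)/β). Immediate options have D = 0 and are not
discounted.

Fitting maximizes the choice log-likelihood over (log₁₀k, ln β) — log space
enforces positivity — on a deterministic 25 × 25 grid (log₁₀k ∈ [−5, 0],
ln β ∈ [−2, 3]) followed by Nelder–Mead refinement from the grid optimum.
No random restarts: the fit is a pure function of the trial table, which
makes it order-invariant and exactly reproducible. Results carry a
`boundary` flag (optimum at a grid edge, or degenerate data such as
all-identical choices; the likelihood is then flat in k and the point
estimate should not be interpreted) and the prediction score: the
percentage of non-tied trials where the chosen option has the strictly
higher discounted value. Trials with Vi = Vd exactly are excluded from the
score's denominator since "higher-valued option" is undefined there. Group
fits pool trials into a single likelihood; each task is fitted separately
by default because the two tasks' values are in different units.

## Synthetic cohorts

The generator produces the statistical structure the analyses assume, not
a mechanistic model of any brain:

- **Richness and ratings.** Per item, imagination richness r is a
  truncated normal on [0, 20], rounded; the latent value is baseline +
  b·(r − r̄) + noise, rounded and clipped to [−10, 10]. Sim-mode values are
  additionally reduced by the agent's δ_sim ≥ 0 before clipping. Between
  subjects, mean richness feeds back into baseline liking (slope 0.3), so
  the richness–rating coupling exists across trials *and* across subjects.
  Defaults: baseline liking 4 (the catalog items are desirable
  consumables; a lower baseline puts many items at negative value, where
  steeper discounting paradoxically *raises* the delayed option's
  attractiveness and washes phenotypes out), item noise SD 2, richness
  10 ± 4 within subject, richness slope 0.5 rating units per detail.
- **Choices** are Bernoulli draws from the model's own P_imp at the
  agent's true (k, β) — the forward model and the fitted model coincide,
  so parameter recovery is a pure estimation question.
- **Discount rates** are log-normal: log₁₀k ~ N(−3, 0.5) for healthy,
  elderly-control and AD-like groups, N(−2, 0.5) for bvFTD-like agents
  (the 10× ratio that operationalizes condition-general impulsivity).
  With this task's delay set, k = 10⁻³/day leaves a 1-year option at 73%
  of its value and a 10-year option at 21%; k = 10⁻²/day would discount
  every delayed option to near zero (3% at 1 year × 10) and flatten all
  delay and group effects, contradicting the mid-range choice rates the
  paradigm is designed to produce. β is log-normal around 2.
- **Phenotypes.** AD-like agents are defined purely by δ_sim > 0 (mean 5):
  a Sim-specific valuation loss producing impulsivity only where delayed
  options must be imagined. bvFTD-like agents are defined purely by the
  elevated k. Elderly controls have δ_sim = 0 and baseline k. These are
  operationalizations of the two dissociable impulsivity patterns, not
  claims about mechanism.
- **Neural chain.** Per subject GM ~ N(0, 1); BOLD = β₁·GM + ε with
  ε ~ N(0, 1) by default (giving a GM–BOLD correlation ≈ 0.7; with much
  smaller noise the two regressors of the mediation outcome model are
  near-collinear and the direct/indirect split is unidentifiable at small
  n). In healthy cohorts δ_sim = max(0, 3 − 1.5·BOLD): activity lowers the
  Sim-valuation penalty, so behaviour sits strictly downstream of
  GM → BOLD, and the mediation chain is built in causally. The direction
  richness→value (and BOLD→value) is a modelling commitment of the
  generator; the underlying behavioural phenomenon does not identify the
  direction of causality, which is exactly why the simulator must pick
  one. A `bold_control` scalar with the same marginal spread but no
  coupling provides the control-condition outcome for the interaction GLM.
- **Seeding.** All randomness descends from one master seed through named
  substreams (`schedule`, `agent`, `ratings`, `choices`, `neural`, …) via
  CRC-32 stage hashing, so any layer reproduces independently and cohorts
  are byte-identical across reruns.

What passing tests on these cohorts shows: that the estimators and tests
recover structure that is genuinely present, at the stated sample sizes,
and stay calibrated when it is absent. What they cannot show: anything
about real participants — the agents have no response times, no session
effects, no rating drift, no model misspecification (choices truly come
from the hyperbolic+softmax model), and their mean condition effects
(e.g. the healthy ecological-vs-control rate gap induced by mean δ_sim)
are generator artifacts, not empirical claims.

## Statistics

Robust regression is IRLS with the Tukey bisquare ψ (tuning 4.685) and
MAD/0.6745 residual scale (statsmodels RLM), iterated to coefficient
convergence (tol 10⁻⁸, max 50 iterations); tests use the studentized
coefficient (estimate/SE). When the MAD scale degenerates to zero — e.g. a
binary response where most residuals vanish — the fit falls back to OLS,
the all-weights-one limit of the scheme. Per-subject slope tests run the
robust fit within subject and a one-sample t test on the slopes across
subjects; subjects with constant response (no estimable slope, e.g. a
participant who never chose the delayed option) are excluded. Sidedness is
always an explicit argument: directional confirmations default to
one-sided, everything else two-sided, and no multiplicity correction is
applied across behavioural tests.

Binned summaries use per-subject equal-count (quantile) bins with stable
tie-breaking, then average bin means across subjects with intersubject SEM
— the construction behind rate-vs-value-difference curves (9 bins) and
rating-vs-richness curves (8 bins).

The intersubject interaction GLM stacks one row per subject × condition:
Y = b₀ + b₁X + b₂Z + b₃(X·Z) + covariates, Z the ecological dummy, and
tests b₃ — whether the X–Y correlation is stronger in the ecological
condition. The Group × Condition analysis is a mixed-design ANOVA
(condition within, group between; between df = groups − 1, error df = N −
groups, via pingouin); with two groups its interaction F is the square of
the two-sample t on the per-subject ecological-minus-control difference,
which is also what the age-adjusted GLM (difference ~ group + age) refines.
A constant age column is dropped with a warning rather than crashing the
group test.

## Mediation

Two OLS equations with intercepts — BOLD = β₁·GM (+ covariates) and
CHOICE = β₀·GM + β₂·BOLD (+ covariates) — define the direct effect β₀ and
indirect effect β₁β₂. The marginal coefficient of CHOICE ~ GM equals
β₀ + β₁β₂ *identically* (OLS algebra on the same sample); the
implementation asserts this on every call as an internal consistency
check. Significance uses a nonparametric case-resampling bootstrap of
subjects (default 10,000 resamples; the no-covariate path is computed in
closed form from per-resample cross-moments, algebraically identical to
per-resample OLS), percentile 95% CIs (BCa optional; the CI flavour is a
free choice — percentile is the default for its simplicity and exact
seed-reproducibility), and two-sided p-values equal to twice the smaller
tail proportion around zero, floored at 1/n_boot. "Full mediation" means
the indirect CI excludes zero while the direct CI contains it.
Standardization of the three variables before estimation is available but
off by default.

## Parameter-recovery design

Recovery simulations use the task's smaller-sooner/larger-later value
structure: the delayed option's undiscounted value is drawn near the top of
the rating scale (uniform 8–10) and the immediate value uniformly between
0 and it, with delays from the union of the variants' delay sets (1 day …
10 years). This is not cosmetic: with independently drawn option values,
most trials are value-dominated (|Vi − Vd| ≫ β) and carry no information
about k — the Cramér–Rao bound on SE(log₁₀k) under such a design is
0.16–0.21 at β = 2 and 720 trials, so ±0.2 recovery would fail for *any*
estimator. Under the paired design the bound is 0.06–0.11 across
k ∈ {10⁻³, 10⁻², 10⁻¹}/day, and the MLE attains it.

## Problem sizes and calibration checks

The acceptance layer runs, at fixed sizes chosen to estimate each quantity
stably: recovery at 100 replicates × 720 trials per k level (the
acceptance script reports 30 per level); type-I calibration of the slope
test, interaction GLM and mixed ANOVA at 1,000 null replicates each
(script: 500), compared against the 95% binomial band around 5%; mediation
recovery at n = 1,000 subjects with 10,000 bootsamples, and null-path CI
coverage at 500 replicates × 1,000 resamples (script: 200) against the
binomial band around 95%; phenotype contrasts at the patient-study group
sizes (14–20 per group). At those group sizes the bvFTD contrast is
typically but not invariably significant (median t ≈ 3 across seeds) —
single-cohort test statistics at n ≈ 15 are intrinsically noisy, which is
itself a faithful property of the design.

## Known limitations

- Ratings are generated per item and mode; real likeability ratings are
  collected once post-hoc and carry measurement noise shared across the
  trials reusing the item, a dependence the generator omits.
- Neural measures are per-subject scalars (ROI summaries); nothing
  voxelwise is modelled, and the `bold_control` null contrast is
  independent noise rather than a weaker version of the coupling.
- The hyperbolic + softmax model is both generator and estimator;
  model-comparison questions (exponential, quasi-hyperbolic forms) are out
  of scope by design.
- Monetary impulsive rates of simulated agents are low: after the affine
  transform the immediate option is almost always the lower-valued one, so
  a value-maximizing agent rarely takes it. Matching the roughly even
  split real participants produce would require value noise or biases the
  model does not contain — a visible, documented gap between the agents
  and human data.
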