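# Methods

`psyflex` implements, end to end, the quantitative machinery of a
cross-sectional study of psychedelic drug use, schizotypy and cognitive
flexibility: a large survey arm (questionnaire composites, drug-exposure
scoring, an adjusted regression battery) and a small experimental arm
(BADE evidence-integration scoring and a computational model of instructed
fear-reversal learning fitted to trial-level physiological responses).
Because the raw physiology is not redistributable and desk-scale checks
must run anywhere, every analysis is exercised on synthetic data with known
ground truth; the generators are first-class, tested code.

## Survey scoring and composites

Schizotypy is measured by the 43-item short-form O-LIFE (binary items;
facets UE/CD/IA/IN partition the total; the facet key ships as an editable
YAML file, since codebooks order items differently) and by the PDI+ — the
21-item Peters Delusion Inventory plus 5 unusual-experience items from
CAPE-42 (the PDI-21 subtotal excludes those five). The primary outcome is a
**composite z-score**: each total is standardised against the analysis
sample, the two z-scores are averaged, and the average is re-standardised.
We use the R `scale()` convention (ddof = 1) throughout. Whether to
standardise before or after averaging is not determined by the source
material; we standardise first (equal weighting of the two instruments) and
expose `standardize_first=False` as the alternative — the two orders give
identically ranked composites.

Drug **exposure** composites z-merge frequency and recency ordinals over
the subsample of ever-users with complete ratings. Never-users are assigned
the subsample minimum rather than excluded, so the experimental-arm
regressions can include non-users; `never_user_policy="exclude"` switches
this off.

The **young-healthy filter** retains respondents aged 18–35 (inclusive)
with no psychiatric/neurological/head-trauma/serious-medical flag; it is
idempotent, and records with missing age are excluded and counted.

## Regression battery

All adjusted models are ordinary least squares with an intercept,
complete-case per model (dropped counts are carried on the report). Besides
plain R² and AIC we report a Cragg–Uhler (Nagelkerke) pseudo-R² computed
from the Gaussian likelihoods of the fitted and intercept-only models; for
continuous outcomes whose null density exceeds one the normaliser is
dropped (Cox–Snell value reported as-is). Rank deficiency raises an error
naming the collinear columns (pivoted QR); a residual variance of ~0 is
flagged degenerate rather than raised.

Group contrasts use Welch's unequal-variance t with Welch–Satterthwaite
degrees of freedom. Cohen's d uses the pooled SD; its 95% CI inverts the
noncentral-t distribution of the pooled-SD t statistic (df = n1+n2−2), with
a normal-approximation alternative behind a flag. The one-tailed direction
is fixed a priori as users > non-users.

## BADE / Evidence Integration Impairment

Per scorable scenario (12 emotional + 12 neutral; 6 distractors are never
scored), EII = Absurd1 + Absurd2 + Absurd3 + LureA3 + LureB3 − True3 on a
bounded rating scale [0, R]; the per-scenario range is [−R, 5R]. The rating
scale is not fixed by the source material; the default is R = 10 and it is
configurable. Subject-level EII is the **mean** over scorable scenarios
(robust to a missing scenario; a sum aggregate is available), optionally
standardised over the analysed sample. Both raw and standardised values are
emitted because the regression scale of the original coefficients is not
recoverable from the published summary alone.

## Fear-reversal task schedules

80 trials in 4 blocks of 20; per block the CS+ cue appears 12 times (4
reinforced, 8 unreinforced — a 4/12 ≈ 30% reinforcement rate) and the CS−
cue 8 times. The cue↔condition mapping flips at instructed reversals before
trials 21, 41 and 61. Pseudorandomisation constraints: no two reinforced
trials in a row, and no *nominal condition* (CS+/CS−) three times in a row;
both are enforced across block boundaries. "Condition" could also be read
as the three trial types (reinforced CS+, unreinforced CS+, CS−); we use
the stricter two-level reading and keep the rule isolated in the validator
so it can be re-pointed. Generation is per-block rejection sampling
conditioned on the previous block's tail, with a retry cap that reports the
offending seed. Inter-trial timing is configurable (defaults: 4 s CS, 8 s
response window, 3 s gap — an ~16 minute task) and matters only for
raw-trace simulation.

## Physiological response extraction

For both SCR and pupillometry the trial response is the signed **peak
change**: the maximum of the trace in the 8-s window after CS offset minus
a baseline read 500 ms before stimulus onset. The baseline is a single
linearly interpolated sample (a literal reading of a point measurement); a
mean-window baseline is flag-selectable. "Before the stimulus" is taken as
before CS onset. No channel transform is applied by default; log/sqrt
transforms can be layered on upstream. Truncated windows and non-finite
samples mark trials unusable with a reason, never an exception. Subject
screening excludes physiological non-responders (SD of usable responses
below 1e-3 channel units — no published criterion exists, so the floor is a
documented constant) and subjects with under 75% usable trials.

## The instructed Rescorla–Wagner model

Each cue carries an expected shock value V ∈ [0, 1]. Presented cues update
by the delta rule V' = V + α(λ − V) with λ ∈ {0, 1} (CS− trials are λ = 0
updates). At an instructed reversal both values are revised by convex
mixing toward the opposite cue's value with weight ρ:

    V_A' = ρ V_B + (1 − ρ) V_A,   V_B' = ρ V_A + (1 − ρ) V_B

so ρ = 0 ignores the instruction, ρ = 1 swaps the values fully, and
V_A + V_B is exactly conserved at instruction events for every ρ. This
functional form follows the standard instructed-learning model family for
this task; it is isolated in one operation (`apply_instruction`) so a
different revision rule can be substituted. Initial values are free
("initFree"): the instructed CS+ cue starts at the free parameter V0 and
the other cue at 1 − V0 — a one-parameter encoding of how fully the initial
contingency instruction is adopted (V0 = 0.5 ⇒ no initial
differentiation). Responses are a noisy affine readout,
r_t ~ Normal(β0 + β1 V_t, σ).

**Fitting.** Subjects are fitted independently (the original multi-subject
code is ambiguous about pooling; independent fits are the explicit choice
here, with group-level summaries computed from the per-subject estimates).
Bounded parameters are sampled on logit scales and σ on a log scale, with
priors Beta(1.1, 1.1) on α, ρ, V0 (bounded, near-flat), Normal(0, 5) on β0
and β1, Half-Normal(5) on σ. Two estimators:

* **MCMC** (default): affine-invariant ensemble sampling (emcee), 24
  walkers, 2000 steps with 800 discarded by default. Walkers are treated
  as chains for split-R-hat and bulk ESS (the usual, slightly optimistic
  convention for ensemble samplers); subjects with any R-hat ≥ 1.05 are
  flagged, never silently returned. Reduced-draw settings (700/300) are
  used in the simulation studies.
* **MAP**: a profile grid over (α, ρ, V0) — the linear readout (β0, β1, σ)
  has a closed-form conditional ML solution — initialises a full joint
  L-BFGS optimisation of the log posterior; intervals come from a local
  Laplace approximation. Used for replicate-heavy simulation studies.

Model fit is summarised by marginal/conditional R² of a linear mixed model
of responses on fitted expected values with a random intercept per subject
(Nakagawa–Schielzeth decomposition, statsmodels MixedLM).

**Identifiability.** ρ acts at only three instruction events, so its
information content per subject is limited: at response noise σ comparable
to the readout gain β1, per-subject ρ recovery error is of order 0.2–0.3
and a recovery correlation of 0.8 over a U(0,1) spread is not attainable —
intervals widen honestly rather than bias (covered by a test). The
**recovery study** is therefore run at σ = 0.1 against β1 ≈ 1, the
signal-to-noise regime of a clean trial-level readout; the **power study**
for the group contrast uses the noisier σ = 0.3 with the cohort gap
(users ρ ≈ 0.8, n = 22 vs non-users ρ ≈ 0.3, n = 16), where detection is
driven by the gap, not per-subject precision.

## Synthetic data: what it emulates, what it does not

* **Survey generator.** Latent schizotypy = Σ βk·covariate_k + N(0, 1),
  with default planted slopes from the adjusted whole-sample model
  (stimulants +0.065, alcohol −0.02, psychedelics +0.003, diagnosis
  +0.075) and lifetime prevalences from the screened sample (psychedelics
  0.283, stimulants 0.305, ...). Binary items follow a graded-threshold
  model: item endorsed when latent + unit item noise exceeds the item
  threshold; thresholds are spread around values giving ~15/43 expected
  O-LIFE and ~6/26 PDI+ endorsement, so questionnaire totals are monotone
  in the latent score by construction. Age and diagnosis distributions are
  set so the expected young-healthy retention is ≈ 0.68 of the screened
  sample (≈ 701 of 1032). Item-level psychometric realism beyond
  monotonicity (local dependence, reverse-keyed wording effects,
  acquiescence) is deliberately out of scope, and drug classes are drawn
  independently — real polysubstance correlation is not emulated, so
  passing tests say nothing about collinearity-driven confounding in real
  data.
* **BADE generator.** Mean rating trajectories (on the unit scale, ×R):
  True rises 0.5→0.8 but its final value drops by 0.5·w; Lures fall
  0.7→0.3 but their final value rises by 0.4·w; Absurd sits at 0.1+0.4·w
  throughout; w ∈ [0, 1] is the planted impairment. Expected subject EII is
  affine in w (≈ 10·(0.1 + 2.5 w) at R = 10), so rank correlation between
  planted impairment and scored EII exceeds 0.99 at n = 50. Distractors
  are uniform noise and never scored.
* **Physiology generator.** True parameters per cohort: α, ρ, V0 ~ Beta
  (mean/concentration parameterisation), β0, β1 ~ Normal, fixed σ;
  defaults are the experimental arm's 22 users (ρ mean 0.8) vs 16
  non-users (ρ mean 0.3), α mean 0.3, β0 ≈ 0.2, β1 ≈ 1, σ = 0.3.
  Responses come from the forward model; optional raw traces embed each
  response as a gamma-like bump x²·exp(2(1−x)), x = t/2 s, peaking exactly
  2 s after window onset on a flat zero baseline at 10 Hz (peak lands on
  the sampling grid), so peak-change extraction recovers each embedded
  response exactly — for non-negative responses; a positive-going waveform
  cannot encode a negative peak-minus-baseline, which is irrelevant in the
  noiseless contract and documented here. Drift, habituation, blinks and
  motion artefacts are *not* simulated: the round-trip test validates the
  windowing arithmetic, not artefact robustness.

## Simulation studies and problem sizes

`psyflex.studies` packages the seeded studies used by the test suite and
`scripts/acceptance.py`: ρ recovery (50 subjects, ρ ~ U(0,1), σ = 0.1,
reduced-draw MCMC), noiseless MAP bias (15 subjects on an α×ρ grid,
σ → 0), group-gap power (100 replicates of 22 vs 16 at ρ 0.8/0.3,
σ = 0.3, MAP, one-tailed Welch at α = 0.05), type-I control (200 null
replicates of n = 701, 7 drug terms at α = 0.05), planted-slope recovery
(100 replicates of n = 4000), and small-shift Cohen's d recovery (200
replicates of 323 vs 709 at d = 0.16). Sizes were chosen so each study's
Monte-Carlo error is small relative to the property being checked while the
whole battery completes in minutes on one core.

## Numerical choices and edge cases

* Standardisation uses ddof = 1 everywhere a "z-score" is formed.
* Zero-variance inputs to any standardisation raise a degenerate-input
  error; a single flat subject in screening is excluded, not fatal.
* The schedule validator reports *all* violations with 1-based trial
  indices; generation retries up to 20 000 permutations per block before
  raising with the seed.
* MAP uses two starts from the profile grid; the batched
  forward-difference gradient keeps one fit at ~50 ms for 80 trials.
* Posterior summaries report mean, median and central 95% intervals on the
  natural scale; transforms are applied to draws, not summaries.
* All generators derive their randomness from `numpy.random.default_rng`
  on the configured seed; equal seeds give byte-identical CSV output.

## Known limitations

* Independent per-subject fits forgo hierarchical shrinkage; group-level
  SDs are therefore biased upward at high noise.
* Ensemble-sampler R-hat over walkers understates non-convergence relative
  to independent chains; treat `converged` as a screen, not a proof.
* The Laplace intervals attached to MAP fits are local and can be poor
  near the 0/1 bounds of α, ρ, V0.
* The exposure ordinal scales (1–7) are a convention; real follow-up
  surveys may use different scales, which only affects the generator, not
  the scoring (any ordinal scale standardises identically).
* ASRS/RAADS symptom scales, the Ego Pathology Inventory, sampling-site
  random effects and facet-wise multiple-testing correction are out of
  scope by design.
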