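# Methods

This note documents the models, the synthetic data the pipeline is exercised
on, and the numerical and design choices, in enough detail to audit or extend
the package.

## Task and data model

One row per behavioural trial: signed disparity in degrees of visual angle
(positive toward the stimulated site's preferred rotation; conversion from
raw CW/CCW coding happens at load using the site's `pref_direction`), a
stimulation flag, the reward volume available for a correct choice and its
small/large category, the choice, the outcome, the payout, and a Δdx flag for
visual-perturbation control sessions. Two invariants are enforced at load:
ambiguous zero-disparity trials have undefined correctness (encoded NA) and
are paid by a fair coin, and on ordinary signed trials the payout equals the
correctness. Zero-disparity trials are retained in all fits; the models
predict their choice probabilities like any other level.

Disparities are normalized per site by the site's maximum (`C = d / d_max`,
so `C ∈ [−1, 1]`) before pooling across sites, because disparity ranges are
threshold-matched and grow with receptive-field eccentricity. Sites enter
pooled and population analyses only if at least 5 distinct disparity levels
each carry ≥ 10 stimulated and ≥ 10 non-stimulated trials.

## Reward schedules

Reward escalates with the streak of consecutive correct responses and resets
on an error; ambiguous trials do not advance the streak. Two built-in
schedules: `ica` pays 0.08 ml on the 1st/2nd consecutive correct, 0.12 ml on
the 3rd, 0.20 ml from the 4th; `fle` pays max/3, 2·max/3, then the maximum
(default 0.18 ml) from the 3rd. In both, the mean of the distinct sub-maximal
volumes is half the maximum, so "large" (= maximal) is twice the average
"small" reward. The reward *category* of a trial is set from the volume
available **before** the choice, including on ambiguous trials (whose payout
is random but whose available volume is still well defined).

## Model fitting

All models are fitted by per-trial Bernoulli maximum likelihood. Internally
trials are grouped into (C, reward, stimulation) cells first; the Bernoulli
sum depends on a cell only through its trial and PREF-choice counts, so the
grouped evaluation is exactly equal (a property test verifies this against a
brute-force per-trial sum) and makes each likelihood evaluation O(#cells).
Probabilities are clipped to [1e−9, 1 − 1e−9] inside the likelihood.

Optimization is multi-start: a seeded Latin hypercube (default 10 starts)
over data-driven ranges (means within the observed disparity span; the base
σ log-uniform in [0.1×, 10×] the span; sensitivity ranges scaled by the
stimulus span), each start running a Nelder–Mead simplex search followed by a
BFGS polish, best start kept. For the single-σ per-site models the σ is
optimized on a log scale to enforce positivity. For the pooled Gaussian
family the additive form `σ₀ + ασ₁ + βσ₂` is kept as written — re-expressing
it log-additively would change the model family and hence the nested
structure — and positivity of every cell's effective σ is enforced by a large
smooth penalty instead. Fits are flagged non-identifiable (with a warning,
not an error) when all choices are identical or the fitted threshold exceeds
50× the stimulus span (flat data).

Nested pairs are fitted with mutual warm starts: the restriction's optimum
seeds the full model, and the restriction is re-polished from the full
optimum's projection afterwards. This keeps likelihood dominance
(−logL(nested) ≥ −logL(full)) to optimizer tolerance and protects the χ²
statistic from local-minimum artefacts in either direction. A χ statistic
that comes out negative within tolerance is clamped to zero with a warning.
All tests are χ²(1); p values are reported uncorrected, matching the
convention of reporting raw p with an optional Bonferroni flag across
animals.

### The stimulation shift and its closed form

In the accumulation model the PSE of the non-stimulated curve is
`−x_eff/(B_eff·k_ns)` and of the stimulated curve `−(x_eff/B_eff + 1)/(k_ns + k₂)`;
their difference is the stimulation-induced shift. With no bias and no
stimulation-sensitivity term it reduces to `1/k_ns` — independent of B. This
is verified three ways: symbolically, against numeric root-finding of
`P = 1/2` on the fitted curves (to 1e−8), and by Monte-Carlo diffusion
(below). Per-site shifts from the Gaussian fits are reported as the magnitude
of μ₁ toward the preferred direction (with C positive toward PREF, a
PREF-ward bias is μ₁ < 0) and normalized by that condition's fitted σ.

## Drift-diffusion simulator

Euler–Maruyama with dt = 1 ms (2 ms in the heavier sweeps; a
discretization-control test shows halving dt moves estimates by less than 3
Monte-Carlo standard errors), diffusion coefficient fixed at 1 per √s (only
k/noise and B/noise are identifiable — the standard scaling convention),
symmetric absorbing bounds ±B, fixed viewing duration T = 2 s. The choice is
the first bound crossed; undecided paths take the sign of the final decision
variable, and an exactly-zero final state is resolved by a fair coin (a
measure-zero event in the continuum that discrete paths can hit). There are
no reaction-time outputs, no collapsing bounds, and no two-accumulator race
variant: the model family is deliberately the one-dimensional fixed-duration
process the logistic read-out is derived from.

## Synthetic-data generator

`simulate_session` draws disparities i.i.d.-uniformly from a symmetric
normalized grid including zero (default {0, ±0.25, ±0.5, ±1}: seven levels,
satisfying the inclusion rule), stimulation i.i.d. with probability 0.5
("pseudo-randomized" is implemented as unblocked i.i.d. draws), tracks the
streak to set the available reward before each choice, and draws the choice
from the accumulation model (or from cached per-cell Monte-Carlo diffusion
probabilities in `ddm` mode, where the null bias maps to a starting-point
offset). Default truth is of pooled-data magnitude: k₀ = 1.94, k₁ = 1.56,
k₂ = 0.3, B₀ = 1.29, B₁ = −0.50, x₀ = 0.1, x₁ = 0. In Δdx mode the flagged
trials receive a small extra disparity (default raw +0.005°) added to the
*displayed* stimulus only — the payout is computed from the base disparity —
and no electrical evidence term; because a disparity added to C shifts the
PSE by exactly that amount regardless of k, the Δdx design carries no
reward × perturbation interaction, mirroring its role as a strategy control.

`simulate_site_set` emulates a multi-site experiment (default 48 sites split
over the two schedules, 500 trials per site, the scale of a typical
microstimulation campaign):
receptive-field eccentricities uniform over 2–14°, the site's maximum
(threshold-matched) disparity linear in eccentricity (0.005° + 0.004°/°),
small lognormal jitter (s.d. 0.15) on per-site sensitivity and gain. Raw
thresholds therefore worsen with eccentricity while normalized difficulty is
constant — which is what makes raw reward effects correlate with eccentricity
and threshold while normalized effects do not. A vectorized model-based
generator (`simulate_from_gaussian`, i.i.d. reward/stimulation coins) serves
calibration and power studies of the Gaussian family.

What the generator does **not** emulate: block structure in the
pseudo-randomization, fixation breaks and time-outs, session-level fatigue or
learning, inter-animal differences beyond the reward schedule, and any neural
covariates. Passing tests therefore demonstrate correctness of the estimators
and tests under the assumed generative structure, not robustness to every
real-data pathology.

## Engagement and waning controls

Smoothed accuracy is a trailing (causal) 30-trial window over trials with a
defined correct answer, aligned to the window's last trial; ambiguous trials
are excluded from the accuracy computation but inherit the epoch label of
their position. Fluctuation is the trapezoidal area between the smoothed
curve and the session-mean accuracy, normalized by the session's total trial
count. Good/bad epochs are maximal runs strictly above/below the mean of at
least window length; points exactly at the mean break runs and stay
unlabeled. Within each epoch label, pooled trials are re-tested for the
reward × stimulation interaction. The waning control computes, per site, the
ordinary-least-squares slope of the *expanding* running proportion of
large-reward trials (no window is prescribed for this running average; an
expanding mean from session start is the simplest choice) and correlates the
normalized reward effect with that slope across sites (Spearman and Pearson).

## Population statistics

Wilcoxon sign-rank (zero differences dropped; exact enumeration for n ≤ 25
without tied magnitudes, normal approximation with continuity and tie
corrections otherwise; two-sided), a Monte-Carlo composite-normality test (KS
distance of the standardized sample, null distribution re-estimated by
simulation with mean/s.d. refitted per resample), and Pearson/Spearman
correlations. The reward effect is signed as large − small (a reduction under
large reward is negative). "Significant PREF" sites are those whose two-mean
vs single-mean comparison rejects at 5% with the shift toward the preferred
direction; population analyses run on that scope, on all sites, and per
animal. The six-correlation battery relates threshold, eccentricity, overall
shift and the (raw and normalized) reward effect.

## Quantile–quantile model comparison

For every (C, α, β) cell the observed PREF proportion is pushed back through
each fitted psychometric function to the disparity that would produce it;
cells at exactly 0 or 1 cannot be inverted and are omitted with their count
reported. Pearson r over the paired disparities quantifies data–model and
model–model agreement; on synthetic sessions the Gaussian and accumulation
fits agree at r > 0.99.

## Problem sizes and statistical protocols

Chosen once as the package's study conditions: pooled fits and power checks
use 10–20k trials; null calibration of both nested tests uses 400 sessions of
2,000 trials and expects the 5% rejection rate within ±2% (400 replicates
keep the Monte-Carlo error of the rate estimate at ~1.1%, small against the
band); parameter recovery is assessed as the *mean* estimate over 10
independent 50,000-trial sessions against a 10% band (at that n single-draw
estimates of the smaller parameters still carry ~1 band-width of sampling
noise, so the meaningful claim is unbiased recovery; the zero-truth bias term
uses a 0.05 absolute band); the site-population result uses 30 sites × 400
trials × 10 replicates; engagement nulls use 30 sites × 20 replicates with
per-site jitter disabled (constant generative parameters). Seeds are fixed
and fanned out per component via `numpy` seed sequences, so every stage is
bit-reproducible.

## Known limitations

- The logistic read-out is an approximation to the bounded-diffusion choice
  rule, not its exact likelihood; the two are compared by simulation and
  quantile–quantile agreement, not derived from one another.
- B and k enter multiplicatively on non-stimulated trials; their separation
  rests entirely on the stimulated-trial evidence term, so fits without a
  stimulation (or perturbation) condition cannot dissociate them and are
  rejected.
- The Wilcoxon exact path requires untied magnitudes; ties fall back to the
  corrected normal approximation even at small n.
- No lapse/guess parameters are modelled; grossly inattentive data will
  inflate fitted thresholds rather than lapse rates.
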