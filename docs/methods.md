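# Methods

This note documents the models and procedures implemented in `neurocmc`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## The experimental design being emulated

The implicit association test (IAT) probes an audiovisual cross-modal
correspondence (CMC) — pitch–size or pitch–elevation — without ever
presenting the two modalities together. Each block fixes a key–stimulus
mapping over the four stimuli (high/low pitch; small/large or high/low
circle); the mapping is congruent or incongruent with the CMC, and
participants classify one unisensory stimulus per trial. Congruency is a
property of the block's mapping, not of the stimulus. Four mappings
(congruency × key-side counterbalance) cycle deterministically over
blocks; with the full-scale defaults (16 blocks × 4 stimuli × 20
repetitions) this yields 1,280 trials per participant — 640 congruent,
320 congruent per stimulus modality, 80 per block. Within-block trial
order is the only randomized element of the design.

## Synthetic data generator

The generator produces behavior and EEG from one shared ground truth so
the full analysis chain is testable by parameter recovery.

**Behavior.** Each trial's reaction time and correctness are drawn from a
two-boundary Wiener diffusion with accuracy coding (upper boundary =
correct), unbiased start (z = 0.5) and diffusion coefficient 1. The
per-trial drift rate δ, boundary separation θ and non-decision time τ are
linear in planted single-trial component amplitudes y_early, y_late and
the modality predictor S (0 = auditory, 1 = visual):

    δ = α₀ + α₁·y_early + α₂·y_late + α₃·S
    θ = β₀ + β₁·y_early + β₂·y_late
    τ = γ₀ + γ₁·y_early + γ₂·y_late

with one coefficient set per congruency condition and participant-level
coefficients drawn around group means. The default coefficients plant the
qualitative effect structure the pipeline should recover: congruent
trials — Early amplitude raises drift (α₁ = +0.35) and Late amplitude
shortens non-decision time (γ₂ = −0.03 s); incongruent trials — Late
amplitude lowers drift (α₂ = −0.30); visual modality raises drift in
both conditions (α₃ = +0.5); all boundary slopes are zero. Intercepts
(δ ≈ 1.4–1.6, θ ≈ 1.4–1.5, τ ≈ 0.28–0.32 s) put the simulated behavior
in the realistic IAT regime: accuracy ≈ 0.85–0.95, median RT ≈ 0.45–0.7 s,
congruent faster and more accurate. Amplitudes are positive truncated
normals (mean 1.5, SD 0.5).

**EEG.** Stimulus-locked epochs (−0.3 to 0.7 s at 200 Hz, 64 channels by
default) are a sum of two planted components — unit-norm random
orthogonal channel patterns, Hann envelopes over 125–300 ms (Early) and
400–600 ms (Late), and signed per-trial amplitudes (positive for
congruent, negative for incongruent trials, magnitudes shared with the
behavioral links) — plus noise that is AR(1) in time (φ = 0.95) and
spatially correlated through a random orthogonal mixing matrix with a
decaying spectrum. The default noise SD is 2.5 per channel, i.e. a
planted component is clearly sub-noise in any single channel
(single-trial, single-channel SNR ≈ 0.1–0.2 at the envelope peak) and
recoverable only multivariately and after pseudo-trial averaging — the
regime the decoding method exists for, and one at which group-level
forward models and AUC thresholds resolve the planted structure at desk
scale.

**What the generator does not emulate.** Volume conduction from dipolar
sources with a real electrode montage, non-stationary artifacts
(blinks, muscle), 1/f broadband structure beyond AR(1), stimulus-evoked
activity common to both conditions, learning/fatigue trends, and any
raw-recording preprocessing (the generator emits clean epochs). Passing
recovery tests therefore establishes the correctness and calibration of
the statistics, not robustness to real-world artifact structure.

## Behavioral statistics

RT outliers: the fixed lower bound (250 ms) removes anticipations; the
upper cutoff is median + 3·1.4826·MAD with the raw MAD, both computed
per participant (pooling would let slow participants dominate the
cutoff). The rule is upper-tail only — the asymmetry is deliberate, the
lower tail being handled by the absolute bound. The rejection report
gives fractions both per participant and pooled. Note the filter is not
idempotent in principle: re-filtering its own output can shrink the MAD
and reject further trials. It is applied once.

Condition contrasts use paired sign-flip permutation tests on the mean
participant-level difference, exhaustively enumerated when 2ⁿ ≤ 20,000
(then p = #{|stat*| ≥ |stat|}/2ⁿ, identity included) and otherwise
Monte-Carlo with the add-one estimator (#extreme + 1)/(N + 1), which is
valid (never anti-conservative) by construction. Effect sizes: Cliff's
delta for RTs (non-parametric dominance measure), Cohen's d on paired
differences (d_z, n − 1 denominator) for accuracy.

## Single-trial decoding

Epochs are low-pass filtered (4th-order Butterworth at 30 Hz, zero phase
via forward–backward application) and baseline corrected (−0.3 to 0 s).
Pseudo-trials average four randomly grouped trials sharing congruency ×
modality × correctness; remainders are discarded; grouping ignores block
boundaries (blocks only set the mapping, not the signal). A regularized
linear discriminant is fit per sliding window (60 ms, 5 ms steps, data
averaged over the window; timestamps refer to the window onset):
w = Σ̂⁻¹(μ₁ − μ₀) with Ledoit–Wolf analytic shrinkage of the pooled
covariance toward a scaled identity. The shrinkage intensity is the
standard optimal-ratio estimate, computed here in batched form across
all windows at once (a vectorized re-implementation; the single-window
case agrees with the textbook formula). Projections are centered at the
midpoint between class means and oriented so the congruent-class mean is
non-negative — positive amplitudes mean evidence for congruent, negative
for incongruent.

Performance is the test-set ROC AUC under Monte-Carlo stratified
cross-validation (20 random 80/20 splits; the split fraction is our
choice — only the number of folds is standard). Group significance uses
the max-statistic randomization threshold: labels are permuted within
every participant, the group-averaged AUC time course recomputed, its
maximum over windows recorded, and the 99th percentile of that maximum
distribution taken as the threshold; the maximum operation makes the
test family-wise-error controlling at 0.01 over windows. Note that the
AUC of a *single* fixed permutation is not centred on 0.5 — spurious
dataset-level separation is shared between training and test folds —
which is precisely why the threshold is estimated from the permutation
distribution instead of assuming 0.5 chance.

Forward-model topographies a = Xᵀy/(yᵀy) express each discriminant
component in channel space; they are unit-normalized (polarity retained,
since the Early and Late components have opposite polarities) and
clustered over the significant windows with k-means (Euclidean metric,
50 seeded restarts), k chosen to maximize the mean silhouette; k = 1 is
returned when all topographies coincide. Per participant, the peak
discriminant amplitudes y_early_max / y_late_max are taken at the window
of maximal AUC inside the Early/Late search ranges. Two window presets
exist because two variants are in internal use (Early 125–300 vs.
125–350 ms depending on CMC type, Late onset 400 vs. 450 ms); the
`default` preset is the component definition (size: 125–300, elevation:
125–350, late 400–600 ms). Amplitudes are congruency-normalized —
incongruent projections are sign-flipped — so larger always means more
neural evidence for the trial's own condition.

Response-locked analysis re-cuts the stimulus-locked epochs so the
sample at stimulus time rt maps to response time 0; trials whose window
exceeds the source epoch are dropped with a warning.

## Wiener first-passage likelihood

The density is evaluated by the classic dual series: a small-time
image-charge expansion and a large-time sine series in normalized time
t/θ², each with the truncation length given by its analytic error bound
(absolute tolerance 10⁻⁷, well below the MCMC noise floor) and the
cheaper expansion chosen per evaluation. Upper-boundary densities use
the reflection (δ, z) → (−δ, 1 − z). Total probability integrates to 1
within 10⁻⁴ and the choice probability matches the closed form
P(correct) = 1/(1 + e^{−θδ}) for z = 0.5.

The forward simulator is Euler–Maruyama at dt = 1 ms with a
Brownian-bridge boundary-crossing check between steps (the probability
that the within-step bridge crossed a boundary although both endpoints
are interior). Plain Euler–Maruyama has an O(√dt) first-passage bias —
about a 1% RT shift at 1 ms — which a 10⁶-trial histogram comparison
against the analytic density resolves easily; the bridge correction
removes the leading-order bias, and simulated RT distributions agree
with the density CDF to Kolmogorov–Smirnov distance < 0.01 at n = 10⁵.

Trials with rt ≤ τ contribute a finite penalty (−20 − 100·(τ − rt) in
log units) rather than −∞, keeping samplers alive on proposals that
momentarily violate the ordering; θ and τ pass through a smooth softplus
floor (minimum 10⁻³, smoothing scale 0.05) so the linear links remain
linear while positivity is guaranteed.

## Hierarchical inference

Participant-level coefficient vectors (10 per congruency condition) are
exchangeable normal draws around group means; group means and SDs are
inferred jointly. Priors: group means N(0, 5²) for slopes and the drift
intercept, positive-truncated N(1.5, 1²) for the boundary intercept and
N(0.3, 0.2²) for the non-decision intercept (typical DDM values), group
SDs half-normal(0, 1). Hierarchy is placed on all coefficients,
including the EEG-amplitude slopes.

The sampler is adaptive Metropolis-within-Gibbs with a move set chosen
for the posterior's known pathologies:

* random-walk Metropolis on each cell's drift/boundary/non-decision
  blocks (local moves, scale-adapted to 30% acceptance);
* full-vector adaptive-Metropolis moves per participant-condition cell,
  with proposal covariance 2.38²/d times the empirical posterior
  covariance accumulated during burn-in — this handles the strong
  within-cell δ/θ/τ trade-offs;
* conjugate Gibbs for group means (rejection-sampled where truncated)
  and Metropolis on log group SDs;
* joint group-mean translation moves: all of a condition's group means
  are shifted together with every participant's coefficients, using an
  empirical-covariance proposal over the group-mean vector. One
  full-likelihood pass moves the entire group level, which otherwise
  dominates the autocorrelation of group-mean chains;
* group scale moves: a group SD is rescaled together with every
  participant's deviation from the mean (acceptance includes the +log κ
  volume term), breaking the funnel coupling that throttles group-SD
  mixing.

All adaptation (scales and empirical covariances) runs during burn-in
only and is frozen afterwards, so the post-burn-in chain is a fixed
Markov kernel. Starting values are data-informed and chain-jittered
(non-decision intercept at half the cell's minimum RT). Convergence is
monitored with the classic Gelman-Rubin statistic per group-level
parameter (between-/within-chain variance ratio, no rank normalization);
model comparison uses DIC = mean deviance + p_D with p_D = mean deviance
minus deviance at the posterior mean of the participant-level
coefficients; posterior predictive checks re-simulate the full regressor
table from stored draws and compare signed-RT distributions (negative =
incorrect).

Directional hypotheses about group-level coefficients are tested with
posterior log-odds: P = (#{draws in direction} + 0.5)/(N + 1) (the
continuity bound keeps the logit finite at any draw count), log-odds =
logit(P), decision log-odds > logit(threshold_p). For threshold_p = 0.95
the decision threshold is ln 19 ≈ 2.944 — the exact closed form. The
default hypothesis set encodes the congruency predictions (congruent:
amplitude slopes raise drift; incongruent: lower it; boundary and
non-decision time the converse; visual modality positive in both) and is
configurable rather than hard-coded.

## Problem sizes and numerical choices

Desk-scale defaults, chosen so a full pipeline run and the complete
validation suite execute on a single CPU core: 8 participants × 4 blocks
× 20 repetitions (320 trials each, ≈ 75 pseudo-trials), 64 channels;
bootstrap thresholds from 100–400 randomizations in the validation suite
(1,000 remains the analysis default at full scale); MCMC at 4 chains ×
4,000 samples, 1,200 burn-in, thin 7 for the recovery studies, versus
the full-scale 4 × 11,000 / 5,000 / thin 20 available by configuration.
Parameter-recovery studies fit 8 participants × 400 pseudo-trials
simulated directly at the regressor-table level (bypassing the EEG
stage, which is validated separately). Null-calibration studies for the
decoder use 6 participants × 12 channels × 0.3 s epochs and 200
simulated null datasets. At these scales the fitted sampler reaches
max R-hat ≤ 1.02 and recovers every planted coefficient sign with
log-odds above logit(0.95), with false positives on planted-zero
coefficients at the expected ~5% rate.

Other numerical details: covariance solves in float32 with shrinkage
(the regularization dwarfs the precision loss; orientation and AUC
ranking are unaffected); window averaging by cumulative sums; AUC by the
rank-sum identity with midranks for ties; k-means restarts and all
randomized procedures take explicit seeds; every dataset-level seed
derives from a single master seed via `numpy` seed sequences.

## Known limitations

* The generator's spatial patterns are random orthogonal vectors, not
  physiological topographies; cosine-recovery tests validate the
  estimator, not anatomical interpretability.
* The sampler's R-hat ≤ 1.02 is demonstrated at the desk-scale study
  conditions; heavier models (more conditions, weaker effects) may need
  longer chains.
* DIC is reported at the conditional (participant-coefficient) level;
  fully marginalized information criteria are out of scope.
* The intercept-only comparison model shares the likelihood code path;
  no alternative accumulator models (race, LBA) or inter-trial
  variability parameters are implemented, matching the model family
  stated for the analysis.
* Behavioral and EEG effect sizes printed by the pipeline on synthetic
  data characterize the generator, not any empirical population.
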