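# Methods

## Observer model

The generative observer is a standard Gaussian prior–likelihood
combiner. On each trial the true azimuth `A` (degrees right of straight
ahead; all targets are right of centre) produces an internal sensed
azimuth

```
x_sensed = A + β·A + ε,    ε ~ N(0, σ_c²)
```

where `σ_c` is the condition's sensory noise and `β`
(`likelihood_bias_slope`, default 0) is an optional eccentricity-
proportional likelihood shift used to construct counterexample data in
which bias grows with azimuth. The percept is the posterior mean under
a Gaussian prior `N(p, σ_p²)`,

```
x̂ = (1 − w)·x_sensed + w·p,    w = σ_c² / (σ_c² + σ_p²),
```

and the overt response adds motor noise `N(0, σ_m²)`, is replaced by a
uniform draw over the dial range with probability `lapse_rate`, and is
clipped to ±30° (the dial's physical range; clipping leaves a point
mass at the bound, which is why estimation uses a truncated fit rather
than raw means). A flat prior is represented by infinite `σ_p` and gives
`w = 0` exactly.

Because the posterior mean is linear in the sensed azimuth, the
expected bias is exactly `b(A) = w(p − A)` with slope `−w`. This slope
is non-positive for every valid weight — the structural constraint the
critique module exploits. We implement the derivative as `−w`
(constant in `A`), which is what linearity requires.

**Robust integration variant.** For the "combine less under larger
conflict" idea we adopt a Gaussian attenuation of the prior weight,

```
w_eff = w · exp(−½ ((x_sensed − p) / s)²),
```

with conflict scale `s` (degrees). Any attenuation that equals 1 at
zero conflict and decreases monotonically in |conflict|/s would satisfy
the same contract; the Gaussian is chosen for smoothness. Note that
this variant *can* produce positive bias-vs-azimuth slopes when the
prior sits beyond the tested range (attenuation is weakest at the most
eccentric targets), but only by letting the effective weight vary
steeply across a ~13° span — the screen quantifies exactly how steeply
(see below).

## Synthetic study

Defaults reproduce the study design: 24 participants; a before phase
with an auditory task (4 blocks × 50 trials; two blocks each of A1/A2,
block order shuffled; 10 trials per location per block) and a visual
task (same structure with V1/V2); a training phase (4 blocks of A2 with
visual feedback, 12 participants with reliable VF1 feedback and 12 with
VF2); an after phase repeating the auditory task. Feedback azimuth is
the mean of the sampled feedback-LED positions centred on the true
azimuth.

Visual stimuli light 45 (V1/VF1) or 5 (V2/VF2) LEDs drawn without
replacement from 51 integer positions spanning ±25 LED units, with
probabilities proportional to a normal density of sd 12 units truncated
at the edges, at 0.5°/LED. This reproduces mean stimulus widths of
about 24° and 13° for the two reliability levels.

Observer population defaults: σ_A1 = 3°, σ_A2 = 5.5°, σ_V1 = 1.2°,
σ_V2 = 2.2°, prior N(20°, 6°), motor sd 1°, lapse 0. These were chosen
to place the simulated biases and variabilities in the few-degree range
typical of this paradigm (A1 mean bias ≈ 2.8°, A2 ≈ 6.4°) while keeping
σ_A2 > σ_A1 and σ_V2 > σ_V1 (the reliability manipulations) and an
eccentric prior beyond the tested range. Between-participant
heterogeneity is multiplicative log-normal jitter on the sensory sds
(sd 0.15 in log units) and additive normal jitter on the prior azimuth
(sd 2°).

**Training.** The study reports training effects without committing to
a learning rule, so learning is modelled phenomenologically: per-phase
multiplicative retention factors scale the prior weight (defaults 0.6
during training, 0.7 after) and the sensory sd (0.85 in both), applied
to every condition in that phase. This reproduces the qualitative
pattern — bias and variability reduced during and after training —
without claiming a mechanism.

**Eye traces.** Only the summaries the exclusion rule consumes are
generated: per-trial mean and sd of fixation deviation. With
probability `eye_exceed_probability` (default 0.01) one of the two
summaries is drawn above the 2° threshold, otherwise both lie below it;
exclusions are therefore rare, as in the study (<2% per participant).
No saccade dynamics are modelled.

**Randomness.** One master seed; participants get independent
substreams spawned from it, so trial tables are byte-identical across
runs with the same seed and participant-level results do not depend on
participant order.

## Estimation

Trials whose eye-deviation mean *or* sd exceeds 2° are excluded. For
each participant × phase × condition × location cell, a normal
distribution truncated above at 31° is fitted by maximum likelihood
(parameterised as (μ, log σ); L-BFGS-B with the analytic gradient,
objective tolerance 1e−12, with a Nelder-Mead polish on the rare
line-search failure; moment starting values). Bias is μ minus the true
location; variability is σ. The truncation is one-sided because only
the eccentric side of the dial saturates in practice; a lower bound is
accepted for two-sided fits. When all data lie well below 31° the fit
coincides with the ordinary normal MLE (verified to 1e−4). Cells with
fewer than 3 trials or degenerate (zero-spread) data are flagged, not
dropped. Per-location biases and sigmas are averaged across the five
locations for each participant's mean bias and mean variability; the 0°
location (coinciding with fixation) is included by default with a
`drop_zero_azimuth` flag for sensitivity analyses.

## Inferential statistics

The split-plot ANOVA uses the classical balanced sums-of-squares
decomposition (up to two within factors, optional between factor);
each within effect is tested against its own effect-by-subject
interaction and the between effect against subjects-within-groups.
Greenhouse–Geisser epsilon per within effect comes from the covariance
of orthonormal contrast scores pooled within between-subject groups —
ε = (Σλ)²/((k−1)Σλ²), bounded in [1/(k−1), 1], identically 1 for
two-level effects — and Mauchly's χ² uses the same pooled covariance
with error df n − g. Uncorrected and corrected values are always
reported; the corrected ones are flagged for use when Mauchly rejects
at 0.05. One-way and mixed designs agree with pingouin to numerical
precision on F, p, and (one-way) ε; for mixed designs our ε pools the
covariance within groups where pingouin does not, which is the
split-plot convention we adopt. Paired t-tests on identical vectors
return t = 0, p = 1 rather than NaN. Bonferroni adjustment is
min(1, m·p) with the family being the pairwise comparisons within the
decomposed effect (m = 3 for three phases).

The analysis battery mirrors the study's planned comparisons:
reliability t-tests and reliability × azimuth ANOVAs before training;
phase × feedback mixed ANOVAs for the trained stimulus with pairwise
phase post-hocs; before/after × feedback for the untrained stimulus;
phase × stimulus × feedback; and post-training one-sample t-tests of
bias against zero. Degrees of freedom are always taken from the data
supplied, never hard-coded.

## Model critique

The linear bias model is fitted by ordinary least squares on
per-azimuth mean biases; the slope maps to `w_hat = −slope` and
`p_hat = intercept / w_hat`. A zero slope leaves `p` unidentifiable
(flagged); a slope outside [−1, 0] is flagged out of the model's
parameter range rather than clamped. The slope's confidence interval is
a participant-level nonparametric bootstrap (1000 resamples by default,
seed-controlled); the study itself argued from ANOVA post-hocs, so the
bootstrap-slope test is this package's operationalisation of its
qualitative gradient argument. The verdict is conservative: only a CI
excluding zero from above declares the static-prior model refuted.

The explanation screen combines (i) the uncertainty–bias link (paired
tests that both bias and fitted variability are larger for the less
reliable condition), (ii) the gradient sign test per reliability level,
and (iii) a robust-integration sweep: for the fitted (w, p) it computes
the expected bias slope under Gaussian conflict attenuation across a
grid of conflict scales (Gauss–Hermite quadrature over sensory noise,
61 nodes) and reports the per-azimuth prior weights the observed biases
would imply, summarised by their max/min ratio — i.e. how drastic the
reweighting would need to be for a prior account to survive a positive
gradient. No pass/fail threshold is attached to that ratio, since none
is principled; it is reported as a quantity.

The recovery harness simulates the before-phase auditory task at a
given design scale per replicate, runs the full estimation path, and
records recovered (w, p) against truth. At the study's scale (24
participants, 10 trials per cell per block) the group-level `w_hat` is
unbiased for the population-mean weight with a replicate sd well under
0.1.

## Problem sizes and numerical choices

Test-suite simulations use the full design where bookkeeping is being
checked and reduced designs (4–8 participants, 20-trial blocks)
elsewhere; Monte-Carlo checks use 10,000–20,000 draws; statistical
calibration uses 2,000 null replicates of 24-participant datasets
(paired t and one-way RM-ANOVA reject at 0.05 within Monte-Carlo
error). Quadrature oracles use 400k-point grids (posterior mean agrees
to 1e−6°). Ties and degenerate inputs: empty speaker sets, cells with
fewer than 3 trials, zero-variance samples, singular contrast
covariances, and unbalanced ANOVA inputs all raise or flag explicitly —
nothing is imputed silently.

## What passing tests do and do not show

The generator is an idealised Bayesian observer: Gaussian noise,
a static prior, phenomenological training, no front–back confusions, no
serial dependence, no response-strategy shifts, simplified eye
behaviour, and visual biases modelled only through the optional
likelihood slope. Passing the directional tests shows the pipeline
correctly recovers and detects the effects this observer produces at
the study's scale — not that human data obey the model; indeed the
critique module exists to show which observed patterns (bias growing
with eccentricity at stable variability) a static Gaussian prior cannot
produce.

## Known limitations

- The ANOVA requires balanced, complete data (as the study design
  yields); unbalanced real data would need cell-mean aggregation or a
  mixed-model approach out of scope here.
- The robust-integration variant is one of many admissible attenuation
  forms; conclusions drawn from its sweep are illustrative.
- `recovery_experiment` resamples a full population per replicate, so
  its "truth" is the population mean, not a fixed participant set.
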