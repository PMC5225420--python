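# audloc

Simulation and analysis of human sound-localisation bias under varying
sensory uncertainty.

People mislocalise brief sounds in systematic ways, typically
overestimating how far a source sits from straight ahead. One candidate
explanation is Bayesian: if listeners combine a noisy sensory estimate
with a spatial prior, the percept is the reliability-weighted average

```
x̂ = (1 − w)·x_sensed + w·p,      w = σ_like² / (σ_like² + σ_prior²)
```

where `p` is the prior's azimuth and `w` the weight it receives. The
expected localisation bias is then linear in true azimuth `A`:

```
b(A) = w·(p − A),      db/dA = −w ≤ 0
```

A static Gaussian prior therefore predicts bias that *shrinks* toward
the prior with eccentricity — it can never produce bias that grows with
eccentricity, whatever `(w, p)`. `audloc` packages this observer model,
a synthetic study generator matching a classic two-day audio-visual
localisation design (24 participants, targets at 0/2/6/9/13° azimuth,
two auditory and two visual reliability levels, visual-feedback
training), truncated-normal estimation of per-condition bias and
variability, the repeated-measures statistics the design calls for
(paired t, split-plot ANOVA with Mauchly/Greenhouse–Geisser handling,
Bonferroni post-hocs), and a model critique that tests the gradient-sign
constraint against data.

Intended users: computational psychophysicists who want a tested
reference pipeline for prior–likelihood localisation analyses, power or
parameter-recovery studies on this class of design, or a harness to
probe which bias patterns a static prior can and cannot explain.

## Worked example

```python
from audloc import load_config, run_pipeline

bundle = run_pipeline(load_config({"seed": 42}))

tt = bundle["stats_report"]["before_training_t_tests"]["auditory_bias"]
print(f"bias A2 vs A1: t({tt['df']}) = {tt['t']:.2f}, "
      f"mean diff = {tt['mean_difference']:.2f} deg")

fit = bundle["critique_report"]["gradient_tests"]["A2"]["fit"]
print(f"A2 bias line: slope = {fit['slope']:.3f}  ->  "
      f"w = {fit['w_hat']:.3f}, p = {fit['p_hat']:.1f} deg")

a2 = bundle["mean_summaries"].query("stimulus == 'A2'")
print(a2.groupby("phase")["mean_bias"].mean().round(2).to_dict())
```

prints

```
bias A2 vs A1: t(23) = 9.91, mean diff = 3.67 deg
A2 bias line: slope = -0.464  ->  w = 0.464, p = 20.1 deg
{'after': 3.64, 'before': 6.53, 'training': 3.15}
```

Reading: the less reliable auditory stimulus (A2) is localised with
~3.7° more eccentric bias than the reliable one (A1) — the
uncertainty–bias signature of prior reliance. Fitting the linear bias
model to the A2 bias-by-azimuth curve recovers the generating prior
(weight ≈ 0.46, azimuth ≈ 20°; the generator used σ_A2 = 5.5°, prior
sd 6° → w = 0.457, p = 20°). After simulated feedback training, mean A2
bias roughly halves (6.5° → 3.2° during training, 3.6° after).

The same pipeline is scriptable from the shell:

```bash
audloc simulate --seed 42 --out trials.csv
audloc estimate --trials trials.csv --out summaries.csv
audloc stats    --summaries summaries.csv --out report.json
audloc critique --summaries summaries.csv --out critique.json
# or everything at once:
audloc run --seed 42 --out results/
```

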