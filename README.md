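# avcausal

Bayesian causal-inference analysis of audiovisual distance perception.

When an observer sees and hears an event at some distance, the two cues
may stem from one physical source or two. `avcausal` implements a
**non-generative** causal-inference analysis of trial-level
psychophysical distance reports: no free parameters are fitted to the
bimodal data. Instead, every model ingredient is measured directly —
the sensation distribution of each modality from its unimodal trials,
and the causal posterior of each stimulus pair from the rate of
matching bimodal answers — and six closed-form models are then scored
against the binned response counts.

It is aimed at researchers in computational psychophysics and
multisensory perception who want a reusable, tested pipeline for this
style of analysis, together with a synthetic observer for power and
recovery studies.

## The models

Unimodal reports at distance *d* define a Gaussian sensation
*x<sub>i</sub>* ~ N(μ<sub>i</sub>, σ²<sub>i</sub>) per modality
*i* ∈ {A, V}. For a bimodal pair:

* **Common cause (C = 1)** — maximum-likelihood fusion:
  ŝ<sub>C=1</sub> = (x<sub>A</sub>/σ²<sub>A</sub> + x<sub>V</sub>/σ²<sub>V</sub>) / (1/σ²<sub>A</sub> + 1/σ²<sub>V</sub>),
  with variance σ²<sub>A</sub>σ²<sub>V</sub>/(σ²<sub>A</sub>+σ²<sub>V</sub>) —
  the minimum-variance unbiased combination.
* **Separate causes (C = 2)** — segregation: each report keeps its own
  unimodal mean and variance.
* **Causal posterior** — p(C=1) is estimated as the proportion of
  bimodal trials whose visual and auditory answers match (same 1-m bin
  by default; exact equality optionally).
* **Resolution strategies** for intermediate p(C=1):
  * *model selection* — follow the likelier structure
    (p(C=1) > 0.5 → fused, otherwise segregated);
  * *model averaging* — mean and variance are the p(C=1)-weighted
    linear blends of the two structures;
  * *probability matching* — each trial follows C=1 with probability
    p(C=1), so the response distribution is the two-component Gaussian
    mixture with weights (p(C=1), p(C=2)).
* **Rival models without causal inference**: sensory dominance (the
  lower-variance cue captures both reports), mandatory integration
  (always fuse), and no interaction (always segregate).

Each model's predicted response distribution is discretized onto the
ten 1-m response bins, scaled to the trials per pair, and regressed
(simple OLS) against the observed counts over
10 bins × 50 pairs × subjects; the r² is the goodness of fit.

Sensory weights under causal inference follow
w<sub>A</sub> = p(C=2) + p(C=1)·σ²<sub>V</sub>/(σ²<sub>A</sub>+σ²<sub>V</sub>)
and w<sub>V</sub> = p(C=1)·σ²<sub>A</sub>/(σ²<sub>A</sub>+σ²<sub>V</sub>)
for the auditory estimate (symmetrically for the visual one). The
**interaction window** at each auditory distance is the span of visual
distances where w<sub>V</sub> > 0.5, with its bounds read off the
visual grid by linear interpolation.

## Worked example

Simulate the full study layout (visual stimuli at 1–9 m in 2-m steps,
auditory at 1–10 m, all 50 pairs, 6 repetitions, 6 subjects) with a
probability-matching observer, then score all six models:

```python
from avcausal import ObserverConfig, simulate, compare_models, summarize_errors

data = simulate(ObserverConfig(seed=5))
print(compare_models(data).round(3))
```

```
                        All  All (A)  All (V)     s1     s2     s3     s4     s5     s6
model
SensoryDominance      0.455    0.122    0.868  0.434  0.400  0.416  0.478  0.440  0.395
MandatoryIntegration  0.398    0.141    0.696  0.260  0.310  0.257  0.394  0.350  0.342
NoInteraction         0.680    0.352    0.868  0.605  0.582  0.619  0.688  0.604  0.600
CausalInferencePM     0.750    0.540    0.870  0.666  0.671  0.676  0.789  0.708  0.714
CausalInferenceMA     0.681    0.360    0.870  0.594  0.612  0.611  0.705  0.648  0.668
CausalInferenceMS     0.704    0.453    0.870  0.638  0.644  0.675  0.742  0.693  0.687
```

The generating strategy (causal inference resolved by probability
matching) attains the best overall r²; segregation-heavy data also make
no-interaction a close competitor, while mandatory integration fares
worst — the ranking pattern expected when separate causes are often
perceived. `summarize_errors(data)` reports mean absolute localization
errors of 0.38 m (visual) and 1.27 m (auditory) for this run — vision
is the far more reliable distance cue.

Weight surfaces and interaction windows:

```python
from avcausal import (compute_unimodal_profiles, estimate_posteriors,
                      weight_surface, interaction_window)

profiles   = compute_unimodal_profiles(data)
posteriors = estimate_posteriors(data)
surface    = weight_surface(profiles, posteriors, target="auditory")
for a in (1.0, 5.0, 9.0):
    w = interaction_window(surface, a)
    print(f"A={a:.0f} m: window [{w.window_lo:.2f}, {w.window_hi:.2f}] m, "
          f"width {w.width:.2f} m")
```

```
A=1 m: window [1.00, 2.59] m, width 1.59 m
A=5 m: window [3.55, 7.73] m, width 4.18 m
A=9 m: window [6.48, 9.00] m, width 2.52 m
```

The window within which the visual cue dominates the auditory distance
estimate is mobile — centered near the auditory stimulus — and a few
meters wide.

The same pipeline is available from the shell:

```sh
avcausal simulate --out run/
avcausal fit     --data run/responses.csv --out run/fit
avcausal weights --data run/responses.csv --target auditory --out run/weights
avcausal report  --data run/responses.csv --out run/report
```

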