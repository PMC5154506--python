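# Methods

## The analysis model

`avcausal` analyses bimodal distance reports under the assumption that
each modality's sensation at stimulus distance *d* is Gaussian,
x_i ~ N(μ_i(d), σ²_i(d)), with independent noise across modalities and
an unbiased mapping from sensation to report. Nothing is fitted by
maximum likelihood: the analysis is deliberately *non-generative*.
Its three measured ingredients are

1. **Unimodal profiles** — sample mean and unbiased sample variance of
   the unimodal reports per (modality, distance), pooled over subjects
   by default (a per-subject mode exists for per-subject fit columns).
   A sample variance of zero is floored at 1e-4 m² (a 1-cm spread,
   below slider resolution) because every predictor divides by
   variances.
2. **Causal posteriors** — for each stimulus pair, p(C=1) is the
   proportion of bimodal trials whose two reports match. The default
   match rule is same-1-m-bin equality, matching the granularity of
   the count analysis; an exact-equality rule is available and is the
   natural choice when observers are instructed to give identical
   answers under a perceived common cause (and for the synthetic
   observer, which emits literally identical answers in that case).
3. **Model predictions** — closed forms only. Fusion uses
   inverse-variance weighting; segregation is the identity; the three
   resolution strategies combine them by selection, linear averaging,
   or as a two-component mixture. The linear variance rule of model
   averaging is a modelling hypothesis, not the mixture variance; the
   mixture variance exceeds it by the between-component spread
   whenever the component means differ. Alternative variance laws are
   not explored.

Probability matching is represented *analytically* as the expected
mixture with weights (p(C=1), p(C=2)); per-trial ζ-sampling exists
only in the simulator and in a sampling helper used to verify the
analytic form (Kolmogorov–Smirnov distance < 0.01 at 1e5 draws).

### Tie-breaks and degenerate inputs

* Model selection at exactly p(C=1) = 0.5 (undefined under the strict
  rule) returns the segregated estimate — the conservative default of
  no interaction.
* Sensory dominance at exactly equal variances returns the visual
  profile; vision is the more reliable distance modality throughout
  this setting.
* Zero-weight mixture components are dropped; mixture weights must sum
  to 1 within 1e-12.
* A constant (degenerate) predictor in the regression scores r² = 0
  with an explicit flag and warning rather than raising.

## Discretization and goodness of fit

Predicted densities are integrated over ten 1-m bins centered at
1..10 m, half-open [c−0.5, c+0.5), with the extreme bins absorbing the
tails (a response of exactly 0 falls in bin 1). Predicted counts are
bin probabilities × trials per pair, so each vector conserves the
pair's trial mass. Observed counts are regressed on predicted counts
by simple OLS (statsmodels); the r² is reported. Counts rather than
normalized rates are regressed — with a constant number of trials per
pair the two are proportional and give identical r². No
model-complexity correction is applied: all models have the same
number of (zero) fitted parameters.

Scopes: `All` pools both report modalities into one regression (the
flagged open choice; one regression, not an average of two),
`All (A)` / `All (V)` restrict to one modality, and per-subject scopes
re-estimate profiles and posteriors from that subject alone. For the
full layout each modality scope has 10 bins × 50 pairs × 6 subjects =
3000 cells.

## The synthetic observer

The generator emulates the experiment layout: visual stimuli at
{1,3,5,7,9} m, auditory at 1–10 m in 1-m steps, all 50 bimodal pairs,
6 repetitions per stimulus, 6 subjects, slider responses clipped to
[0, 10] m. Defaults, chosen once as realistic for audiovisual distance
localization and kept fixed:

* σ_V = 0.45 m, constant — folded-normal mean absolute error ≈ 0.36 m;
* σ_A(d) = 0.6 + 0.2·d m — mean absolute error ≈ 1.4 m over the grid
  (auditory distance noise grows with distance);
* causal kernel width τ = 2 m.

On a bimodal trial the observer samples its two sensations, computes a
coupling p_c = exp(−(x_V−x_A)²/(2τ²)), and resolves per the configured
strategy (probability matching by default: with probability p_c both
sliders receive the fused value, hence matching answers). The Gaussian
similarity kernel is a *simulator invention* — the analysis pipeline
never uses it — but it has a convenient closed-form expectation,
E[p_c] = τ/√(τ²+s²) · exp(−Δ²/(2(τ²+s²))) with Δ the mean discrepancy
and s² the summed sensation variances, which `ground_truth` exposes
for recovery tests. Because each trial is an i.i.d. draw, the number
of matching answers per pair is exactly Binomial(n, E[p_c]).

Randomness is organized as one substream per subject (spawned from the
master seed), so any subject subset reproduces bit-identically
regardless of how many subjects are simulated.

### What the simulator does not emulate

Response latency, order and learning effects, subject-specific biases
in the mean functions, non-Gaussian or skewed report noise, and any
stimulus-level acoustics or optics. Passing recovery tests therefore
show that the pipeline's estimators are consistent for data satisfying
the analysis assumptions — not that real observers satisfy them.

### Clipping and ground truth

Slider clipping censors responses at 0 and 10 m. Unimodal sample
moments consequently converge to the *censored* normal moments, which
differ substantially from the raw ones when the stimulus sits at the
range edge (at 10 m the censored mean is ≈ 9.0 m for σ ≈ 2.6 m).
`ground_truth` reports both: the configured raw moments (`profiles`)
and the closed-form censored moments (`response_moments`); recovery
checks compare recovered profiles to the latter. Clipping also
creates rare exact-equality matches (both responses clipped to the
same edge), slightly inflating matching rates for edge pairs.

## Recovery suite: statistical design

The recovery tests run the full design at 60 repetitions (n = 360
trials per pair) with a fixed seed chosen a priori:

* **Posteriors** — each pair's matching count is Binomial(n, E[p_c]),
  so exact binomial intervals apply. Because 50 pairs are tested
  simultaneously, per-pair intervals are taken at the Šidák-adjusted
  level (≈ 99.9%) so the whole family has 95% coverage; requiring 50
  independent per-pair 95% events would fail a correct estimator with
  probability ≈ 1 − 0.95⁵⁰ ≈ 92%.
* **Profiles** — recovered means within 4 standard errors of the
  censored mean; recovered variances within 4 standard errors of the
  censored variance, with the sampling SE of s² computed from the
  censored fourth central moment by numeric integration.
* **Model ranking** — over ten fixed seeds at the study's own size
  (6 repetitions), the probability-matching causal-inference model
  must attain the best pooled r² on a majority of runs.

Problem sizes throughout the suite (1e5 draws for Monte-Carlo checks,
60 repetitions for recovery, 10 seeds for ranking) were chosen to make
the statistical bounds sharp at desk scale.

## Interaction windows

Weight surfaces are computed per pair from the estimated posterior and
unimodal variances. The interaction window at a given auditory
distance is the span of visual distances with w_V > 0.5 (strict;
boundary equality is outside). Since the visual grid step is 2 m,
window bounds between grid points are obtained by linear interpolation
of w_V at the 0.5 crossings — a documented reading rule, not a claim
about sub-grid data. Multiple above-threshold segments are summarized
by the extent from the first up-crossing to the last down-crossing.
Windows truncate at the grid edges, so widths are bounded by the
visual-grid extent (8 m).

## Known limitations

* The matching-rate posterior conflates perceived common cause with
  coincidentally equal (or equally binned / equally clipped) answers;
  the exact-match rule removes the binning part only.
* Pooling subjects assumes homogeneous sensation distributions;
  per-subject mode trades that bias for small-sample variance floors.
* The linear variance law for model averaging and the symmetric
  exchange used for visual-target weights are modelling choices;
  alternatives are flagged, not explored.
* Weight surfaces carry no uncertainty bands — they are point values
  from pooled data.
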