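# Methods

## The task being modelled

In a cued enumeration experiment, a spatial cue precedes a brief dot array
(5–30 dots) shown at a cued or uncued location on one of two rectangle
objects, and the participant reports the perceived numerosity by clicking a
number line spanning 1–35. Three cue-validity conditions arise: valid same
location (VSL, 75% of trials), invalid same object (IS, 12.5%) and invalid
different object (ID, 12.5%). Sessions have 150 trials; a study comprises
four sessions per subject, with the first 20 trials of each session treated
as training.

The package simulates this design, applies the study's exclusion rules,
fits the responses with maximum-likelihood and power-function models under
scalar variability, and fits/predicts number-line compression with a
Bayesian central-tendency observer.

## The central-tendency observer

The observer encodes numerosity N as a Gaussian likelihood centred on N
with SD

    sigma_R(N) = k · N^a,

and combines it with a Gaussian prior over the line (mean P̄, SD sigma_P).
The predicted response is the posterior mean

    R̂(N) = (P̄·sigma_R² + N·sigma_P²) / (sigma_R² + sigma_P²),

implemented in the equivalent shrinkage form
`R̂ = P̄ + (N − P̄)·sigma_P²/(sigma_R² + sigma_P²)` so that `R̂(P̄) = P̄` and
`R̂ = N` at `sigma_R = 0` hold exactly in floating point. Because sensory
noise grows with N, shrinkage toward the prior is stronger at the top of
the range, producing a compressive mapping well approximated by a power
function with exponent < 1. With Weber scaling `sigma_R = x·WF`, the same
mapping can be written `W_L·x + (1 − W_L)·P̄` with likelihood weight
`W_L = sigma_P²/(x²·WF² + sigma_P²)`; the two forms agree to machine
precision and a property test asserts this identity.

## Response models fitted to trials

Both response fits assume scalar variability: the response SD is
proportional to the predicted mean (constant coefficient of variation
sigma_n).

* **Linear MLE**: mean `mu_k = intercept + slope·N_k`,
  SD `sigma_n·mu_k`. The printed form of this likelihood circulating in
  the literature contains sign/placement typos (a residual `R − α + β·N`
  and the variability coefficient inside the mean term) that would permit
  negative SDs; we implement the standard scalar-variability reading, which
  is the model the accompanying text describes.
* **Power MLE**: mean `mu_k = scale·N_k^exponent`, same SD rule. The
  exponent is the nonlinearity index: 1 is veridical, < 1 compressive.

Both are maximised with bounded L-BFGS-B from a least-squares-informed
start plus random restarts (default 10; the heavier replicate analyses use
1–3 since the informed start is reliable). Bounds: intercept ∈ [−10, 20],
slope/scale ∈ (0, 5], exponent ∈ (0, 2], sigma_n ∈ [10⁻⁴, 2]. Parameter
vectors implying non-positive means return a large finite penalty rather
than NaN, keeping the optimizer inside the valid region. Tests verify the
optimum against a dense brute-force lattice on 30-trial instances.

The SD-vs-numerosity scaling fit (`fit_sd_power`) is ordinary least squares
in log-log space, because it operates on per-numerosity summary SDs, not
trial data; numerosities with zero SD are excluded with a warning.

Noise summaries: `internal_noise` is the sample SD of response/numerosity
ratios; `cv` averages SD(R|N)/N over numerosities (the per-N-then-average
convention; pooling is ambiguous in common usage and this choice is the
documented default).

## Prior-width fitting

`fit_prior` fits the posterior-mean mapping to mean responses per
numerosity with the prior width as the free parameter, maximising
R² = 1 − RSS/TSS via a bounded 1-D search (verified against a
0.01-resolution grid). The prior mean is fixed at 15 by default — near but
not exactly the 5–30 midpoint of 17.5, matching the convention of fixing
it at the round mid-range value — with `fixed_midpoint` and `free` modes
also exposed. The sensory-noise spec can be given as `(k, a)` or as
per-numerosity SDs. When driven from trial data, the pipeline sets
`a = 0.5` (square-root scaling, see below) and `k = CV·√30`, i.e. the
condition's coefficient of variation converted so that `sigma_R` at the
top of the range equals the Weber-implied value; this choice is one of
several defensible calibrations and is configurable.

## The nonlinearity-vs-noise model curve

`nonlinearity_vs_noise_curve` simulates, for each Weber fraction on a
grid, responses `posterior_mean(N) + Normal(0, N·WF)` clamped to the line,
with a 17-dot prior width (the value implied by the spread of the stimulus
range itself), then records the internal noise and the fitted power
exponent. The construction of such curves is under-specified in general;
this simulation definition (Weber-scaled noise, clamped line, power-MLE
exponent) is the package's choice and is stated here so results are
reproducible. The exponent decreases and internal noise increases with WF,
giving the predicted positive association between noise and compression.

## The synthetic-data generator

Defaults are the study conditions: 4 × 150 trials, (0.75, 0.125, 0.125)
condition split drawn i.i.d. per trial (75% of 150 is not an integer, so
exact within-session counts cannot be what the percentages describe),
numerosity uniform on 5..30 (the per-numerosity trial distribution is not
specified by the design; uniform is assumed), 20 training trials, line
1–35.

Responses: each condition has its own observer; the simulated response is
the observer's posterior mean for the true N plus Gaussian readout jitter
with SD `response_jitter_sd · N^a`, clamped to the line. Condition effects
are carried by the sensory-noise constant k (VSL 0.5 < IS 0.6 < ID 1.0,
with a = 0.5 and prior (15, 5)); the defaults set
`response_jitter_sd = k`, so output variability mirrors the sensory noise
that drives compression. Setting the jitter to zero gives deterministic
responses, which the exact-value tests exploit. Multi-subject experiments
scale each subject's noise constants by a log-normal factor
(`exp(N(0, 0.25))`), creating the between-subject heterogeneity the
nonlinearity-vs-noise correlation needs while preserving the
within-subject condition ordering.

What this generator does *not* emulate: sequential (trial-history) effects,
response rounding to tick marks, lapses, learning across sessions, or any
perceptual interaction with the dot-array geometry. Passing tests
demonstrate that the pipeline recovers the structure this generator puts
in; they are evidence about the code, not about human data.

Reaction times are a shifted log-normal parameterised by its mean
(defaults 1.07, 1.13, 1.27 s for VSL/IS/ID; log-scale SD 0.35, floor
0.30 s), reproducing the qualitative valid-faster ordering; only
condition means are constrained by the study design, the distributional
form is plumbing.

Dot arrays: rejection sampling places dots in a 4°-diameter circular field
with edge-to-edge gaps ≥ 0.15° and an attempt cap (default 10,000,
explicit `PackingError` on failure). In size-equated mode diameters are
uniform within ±31% of the 0.25° default; in area-equated mode the same
relative variability is applied around the diameter implied by splitting
the cumulative-area target (default: a 15-dot array at default diameter)
equally among dots, followed by a joint rescale so the total area matches
the target within 1%. Anchoring the ±31% band to the mode's own base
diameter keeps "maximum variability in size between dots" meaningful in
both modes; anchoring it to the global 0.25° default would make
area-equating infeasible for small arrays. Degrees of visual angle are
abstract units; no pixel conversion is performed.

## Preprocessing conventions

* Training exclusion first, then the outlier rule; the RT floor (drop
  < 150 ms, keep exactly 150 ms) applies only on the RT-summary branch.
* Outlier rule: per condition within subject (configurable to pooled),
  sample (n−1) SD, mean/SD computed once before removal (single pass),
  strict inequality (exactly 2 SD kept). Groups with fewer than two trials
  pass through with a warning.
* Cleaning reports carry per-condition drop counts and fractions; on
  default synthetic data the per-condition drop fraction stays below 5%.

## Problem sizes

Default analyses use 15 subjects × 4 sessions × 150 trials. Replicate
checks use 100 fits at 520 trials/subject for parameter recovery and 50
simulated 15-subject experiments for the condition-ordering and
noise-association properties; the SD-scaling check uses 2,000 trials per
numerosity. These sizes give Monte-Carlo error comfortably below the
assertion tolerances while keeping a full run on one core in minutes.

## Known limitations

* The likelihood treats responses as unbounded Gaussians; clamping at the
  line ends slightly truncates extreme numerosities, which biases fitted
  exponents upward by a small amount at high noise.
* Per-subject fits with only ~65 trials (the invalid conditions) have
  substantial sampling error in the exponent; condition means over
  subjects are the stable quantity.
* No hierarchical pooling across subjects, no bootstrap intervals, no
  serial-dependence or logarithmic-mapping alternative models.
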