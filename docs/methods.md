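# Methods

## The task and the data it is modeled on

A head-fixed mouse reports, by licking, whether a three-odor mixture
contains one of two rewarded ("go") target odors. Every mixture holds
one target (4 possible, 2 go / 2 no-go, delivered at 0.025% of
saturated vapor), one contextual background (4 possible, 0.1%), and a
third background that is either a fixed, well-learned odor (training
trials) or one of 11 novel odors (catch trials, 0.1%). The full design
therefore has 16 training mixtures and 176 test mixtures (192
combinations); a reduced design keeps 8 of the 16 target–context
combinations for training — each context paired with one go and one
no-go target so that no context predicts reward — and tests on the
complementary 8 combinations crossed with the 11 novel backgrounds
(88 mixtures).

The neural data the simulations emulate are intrinsic-signal images of
the dorsal olfactory bulb in awake mice: odor-evoked activation appears
as a negative z-scored reflectance deflection per glomerulus (ROI),
quantified against a 5-s pre-odor baseline and averaged 2–9 s after
odor onset.

## Synthetic atlas generator

`glomix.synthetic.generate_atlas` draws per-animal matrices of mean
z-score responses (20 odors × `n_rois`, default 155). Its defaults are
calibrated to measured population statistics:

| statistic | target | generator default |
|---|---|---|
| ROIs per animal | ~155 | 155 |
| target activation fraction / mean z over all ROIs | 29.5% / −0.32 | exact by construction |
| contextual background | 43.5% / −0.70 | exact |
| fixed background | 37% / −0.41 | exact |
| novel background | 46.1% / −0.63 | exact |
| responsive-pair amplitude dispersion (sd/mean) | 0.85 | 0.80 |
| go–go / no-go–no-go / go–no-go target similarity (cosine, CV = 0.25 instantiations) | 0.51 / 0.60 / 0.37 | 0.56 / 0.62 / 0.35 |

Note the printed mean z per odor is the average over **all** ROIs of an
animal; the mean over active ROIs alone is that value divided by the
activation fraction (e.g. −0.32 / 0.295 ≈ −1.08 for targets), which is
what makes the pooled responsive-pair mean land near −1.37.

Mechanism: each ROI carries a latent Gaussian affinity vector over the
odor panel. Affinities of the four (chemically related) target odors
are mutually correlated — ρ = 0.75 within a valence pair, 0.45 across —
while background odors are uncorrelated with everything (the measured
conditional overlap between target- and background-responsive glomeruli
is close to the base rate, so independent masks are the right default).
All odors share a low-dimensional tuning space across ROIs
(`n_tuning_factors = 20`, the size of the odor panel): glomerular odor
codes are strongly correlated across glomeruli, and the dictionary
construction below relies on exactly this rank limitation. An ROI is
active for an odor when its |affinity| ranks in the top role fraction;
the amplitude is the latent magnitude raised to `amplitude_power = 2`
(spreading the distribution to the observed heavy-tailed dispersion)
and rescaled so the all-ROI mean is exact. The ρ values and the power
were calibrated once against the similarity triplet and the dispersion
ratio above and are not meant to be retuned per experiment.

What the generator does **not** emulate: session-to-session drift and
independent re-measurement noise of recorded mixtures, glomerular
spatial layout (ROIs are abstract indices), temporal response dynamics,
and any odor-identity chemistry. Consequences for interpretation are
noted under "Decoder orderings" below.

## Trial instantiation and the noise model

Single presentations follow a multiplicative mean–variance model:

```
s_ij(t) = mean_ij · (1 + CV_corr·g_t + CV_uncorr·e_ijt) + sigma_noise·h_ijt
```

with `g_t` a gain shared by all ROIs of a presentation,
`CV_corr = sqrt(CV² − CV_uncorr²)`, and `e`, `h` independent standard
normals. Total trial variance is `sigma_noise² + CV²·mean²`, so the
variance–mean fit and the correlated/uncorrelated decomposition are
exact on this generator. Nominal regimes:

| regime | CV | CV_uncorr | sigma_noise | sigma_uncorr_noise | detection threshold |
|---|---|---|---|---|---|
| wild type | 0.34 | 0.25 | 1.59 | 1.47 | −0.42 |
| knockout-like | 0.64 | 0.44 | 1.83 | 1.65 | −0.46 |

Detection thresholds are `sigma_noise / sqrt(n)` at the n = 16 repeat
floor of the imaging protocol. Decoder evaluation adds only the
uncorrelated multiplicative term (`CV = CV_uncorr`) to mean mixture
patterns — population decoders could in principle subtract the shared
gain, a single glomerulus cannot, so the single-glomerulus decoder is
evaluated at the total CV.

## Noise-parameter estimation

`fit_variance_mean` fits `σ²(μ) = σ²_noise + CV²·μ²`. The model is
linear in `(σ²_noise, CV²)`, so the least-squares optimum is computed in
closed form (non-negativity by clipping). When the per-pair repeat
count is supplied, a classical errors-in-variables moment correction
subtracts the sampling variance of the empirical mean from the
regressor second moment; without it, trial-averaged means attenuate the
recovered CV by 5–10% at ~24 repeats. Bootstrap confidence intervals
resample ROI–odor pairs (1000 draws, seeded).

`decompose_uncorrelated` regresses, per presentation, all simultaneous
ROI responses onto their trial-averaged responses (ordinary least
squares with intercept): population-wide gain fluctuations fall on that
line; the residuals are the uncorrelated part. Residual variances are
leverage-studentized (`r²/(1−h)`) because strongly responding ROIs are
leverage points whose raw residuals are deflated, then fit with the
same corrected variance law. On means drawn uniformly on [−6, 0] the
round trip is unbiased (knockout regime: 0.438 ± 0.010 over 12
replicates against a generating 0.44); on heavy-tailed atlas
amplitudes a residual downward bias of roughly 0.03 remains — a known
limitation of line-fit gain removal under heteroscedastic leverage.
The variance-law fit defaults to the σ² form; a σ-form fit is available
(`fit_sd=True`).

## Imaging quantification

df/f₀ against the mean of the 5-s pre-odor baseline; subtraction of a
wide Gaussian low-pass (σ = 40 µm) to remove the broad hemodynamic
component; narrow Gaussian smoothing (σ = 12 µm); per-pixel z-scores
from the baseline mean and s.d. of the filtered signal; ROI responses
as the spatial mean z over 2–9 s after onset. "Radius σ" is read as the
Gaussian standard deviation in µm, converted to pixels via the pixel
size (3.3 µm default); boundary handling is edge-inclusive mirroring.
Zero-variance baseline pixels receive a machine-epsilon-scaled s.d.
floor instead of producing non-finite z. Thresholding sets entries
weaker than the (negative) cutoff to exactly zero and is idempotent.
ROI masks are inputs (label images); segmentation is out of scope.

## Virtual mixtures

Component mean patterns are thresholded (sub-threshold activations
zeroed), summed per ROI, and passed through the saturating nonlinearity
`σ(R) = 2A/(1 + e^{R·s}) − A` with A = −8.0934, s = 0.2091 (fit to
two-odor mixture measurements; odd, monotone, asymptote A). Trial noise
is added after saturation, to the mixture mean. The
threshold-before-sum order follows the measurement pipeline; both the
threshold and the saturation step can be disabled.

## Decoders and evaluation protocol

All decoders train on the mean training-set mixture patterns after
per-ROI centering by the training mean (centering is stored and applied
to test patterns). Evaluation draws 100 noisy instantiations of each
test mixture (reducible for quick runs) and reports the fraction
correctly classified, with per-novel-background aggregation.

* Single glomerulus: ROI with maximal training discriminability
  `|auROC − 0.5| + 0.5`; threshold at the Youden point of its ROC
  (the 45° tangent); orientation learned from training; ties to the
  lowest ROI index.
* Linear SVM / logistic regression: L1-penalized (scikit-learn
  liblinear); the sparsity constant λ maps to `C = 1/(λ·n_samples)`
  with λ = 0 an effectively unpenalized fit. The λ↔strength mapping is
  a package convention — only the qualitative sweep behavior (fewer
  ROIs at larger λ, plateaued performance) is meaningful. Exact-zero
  decision values resolve to no-go.
* Nearest neighbor: largest dot product against training templates,
  optionally restricted to ROIs above a training-discriminability
  threshold (0.5 keeps all ROIs); dot-product ties to the lowest
  template index.
* Lasso deconvolution: dictionary of the 9 training odors plus
  synthetic elements drawn from a Gaussian with the mean and (rank-
  deficient, eigenvalue-clipped) ROI×ROI covariance of the 20-odor
  panel; every element scaled to unit variance across ROIs. λ = 1e-4 on
  the mean-squared-error cost `(1/2n)‖s − Dc‖² + λ‖c‖₁` (the
  convention of the standard implementations; an unnormalized
  summed-squares convention is available). Coefficients are
  unconstrained in sign (a non-negative switch exists, off by
  default). Because the dictionary is strongly rank-deficient, the
  coordinate-descent duality gap cannot certify optimality at this
  penalty even at the fixed point; the solver caps sweeps and validates
  the achieved objective (it must beat c = 0), raising on genuine
  failure. Readout: max coefficient over the two go targets vs the two
  no-go targets, exact ties to no-go.

## Experiment drivers

`run_comparison` generates one atlas per session, simulates the atlas
*measurement* (average of 16 noisy repeats — the residual imaging noise
that motivates the detection threshold; disable with
`n_measurement_repeats=None`), composes training and test mixtures,
trains every decoder family, and evaluates; Lasso runs on the same
design with 30 dictionaries per size by default. `sweep_glomeruli` runs
the 21-point λ grid on [0, 1] and the 10-point NNC selectivity grid on
[0.5, 1]. `correlate_with_behavior` Monte-Carlos (500 repeats) the
Pearson correlation between per-novel-odor decoder performance and a
behavioral table. `cv_sensitivity` re-evaluates decoders along a
CV_uncorr grid; its `degraded` flag requires both a paired t-test at
α = 0.05 across sessions and a drop larger than 2 percentage points —
matched-session pairing otherwise resolves sub-percent dips that no
behavioral comparison could. Reporting-level significance conventions
are just that: reporting, not scientific claims.

## Decoder orderings on synthetic data

With all calibrated statistics in place, the pipeline reproduces: all
population decoders clearly above chance on the full design; a sharp
NNC drop when training diversity is reduced (≈0.99 → ≈0.7); Lasso
performance high (≈0.99) and insensitive to the knockout noise regime;
single-glomerulus generalization far below population decoders; decoder
performance flat from CV_uncorr 0.25 to 0.44 and degraded beyond ~0.85.
It does **not** reproduce chance-level reduced-set performance for the
L1 linear classifiers: on virtual mixtures their margin-to-noise ratio
stays ≈3 under every statistic the generator matches, and chance-level
linear decoding in the motivating experiments arose with separately
recorded real mixtures (independent per-session measurement noise and
drift), which this synthetic pipeline deliberately does not model. The
corresponding acceptance property is left failing rather than weakened.

## Problem sizes

Default study-condition sizes (155 ROIs, 20 odors, 16–24 repeats,
100 instantiations, 30 dictionaries × sizes 100–1000) run in minutes.
The test suite uses reduced sizes — 40–155 ROIs, 10–30 instantiations,
dictionary sizes ≤ 200, 2–4 sessions — chosen so that every qualitative
property remains resolvable at comfortable statistical margins.
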