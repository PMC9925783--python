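# glomix

Simulation and decoding of olfactory-bulb glomerular activation
patterns, built around a go/no-go odor-identification task in which a
mouse must recognize a known target odor inside a three-odor mixture
whose background component may be entirely novel.

The package is aimed at computational neuroscientists who want to ask,
on fully synthetic but statistically calibrated data, which decoding
strategies survive novel backgrounds and restricted training diversity:

* **single best glomerulus** — auROC-selected ROI with a Youden-optimal
  threshold;
* **L1-regularized linear classifiers** (SVM and logistic regression),
  `c = Σᵢ wᵢ sᵢ + w₀`, decision by sign;
* **nearest-neighbor template matching** over training mixtures (largest
  dot product wins);
* **Lasso sparse deconvolution** of the observed pattern `s` into a
  dictionary of odor patterns `d_j`, minimizing
  `Σᵢ (sᵢ − Σⱼ cⱼ d_{ij})² + λ Σⱼ |cⱼ|`, read out by comparing the
  largest go-target concentration against the largest no-go-target
  concentration.

Everything runs on synthetic per-animal atlases (odors × ROIs mean
z-score matrices, activation = negative deflection) whose statistics —
activation fractions, response amplitudes and their dispersion, odor
similarity structure, and the multiplicative trial-to-trial noise model

```
σ²(μ) = σ²_noise + CV²·μ²        (total variability)
σ²_uncorr(μ) = σ²_un,noise + CV²_uncorr·μ²   (after removing the shared per-trial gain)
```

— are calibrated to awake intrinsic-signal imaging of the mouse dorsal
olfactory bulb, in both a wild-type regime (CV = 0.34, CV_uncorr = 0.25,
σ_noise = 1.59) and a high-variability Cntnap2-knockout-like regime
(CV = 0.64, CV_uncorr = 0.44, σ_noise = 1.83). An imaging module
quantifies raw intrinsic-signal movies (df/f₀, hemodynamic removal,
per-pixel z-scores, ROI averaging, detection thresholding), and a
mixtures module synthesizes virtual three-odor stimuli
(threshold → sum → saturating nonlinearity).

## Worked example

```python
import numpy as np
from glomix.synthetic import AtlasSpec, generate_atlas, instantiate_trials
from glomix.noise import WT, fit_variance_mean, decompose_uncorrelated

rng = np.random.default_rng(0)
atlas = generate_atlas(AtlasSpec(n_rois=155, seed=0))
trials = instantiate_trials(atlas, WT, n_repeats=24, seed=1)

fit = fit_variance_mean(trials.trials.mean(axis=2),
                        trials.trials.std(axis=2, ddof=1),
                        n_repeats=24, n_boot=0)
unc = decompose_uncorrelated(trials.trials)
print(f"CV = {fit['cv']:.3f}  sigma_noise = {fit['sigma_noise']:.3f}  "
      f"CV_uncorr = {unc['cv_uncorr']:.3f}")
```

prints

```
CV = 0.339  sigma_noise = 1.594  CV_uncorr = 0.218
```

i.e. the variance–mean fit recovers the generating wild-type noise
parameters (CV 0.34, noise floor 1.59) from 24 noisy repeats of each of
the 20 × 155 responses. The line-fit decomposition isolates the
uncorrelated component (generating value 0.25); on heavy-tailed atlas
amplitudes it retains a modest downward bias even after leverage
studentization — see `docs/methods.md` for the estimator's behavior
across response distributions.

The same pipeline is available from the shell:

```
glomix simulate --seed 0 --n-repeats 24 --out run/
glomix fit-noise --trials run/trials.csv --out run/
glomix run-experiment --design reduced --seed 0 --out run/exp/
```

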