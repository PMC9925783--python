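"""Trial-to-trial variability models for glomerular odor responses.

Intrinsic-signal responses of a glomerulus fluctuate from presentation to
presentation.  Two sources contribute: a multiplicative component whose
standard deviation scales with the mean evoked response (quantified by a
coefficient of variation, CV), and an additive imaging-noise floor that is
present even for unresponsive glomeruli (``sigma_noise``).  The total
trial variance therefore follows

    sigma^2(mu) = sigma_noise^2 + CV^2 * mu^2

where ``mu`` is the mean z-score response of a glomerulus to an odor.
Part of the multiplicative fluctuation is shared across the whole
glomerular population within a trial (a common gain); the remainder is
independent per glomerulus and is quantified by ``CV_uncorr`` with its own
noise floor ``sigma_uncorr_noise``.

This module fits those parameters from (mean, trial s.d.) data, performs
the per-trial line-fit decomposition that isolates the uncorrelated
component, derives detection thresholds, and fits/applies the saturating
nonlinearity used when synthesizing virtual odor mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class NoiseModel:
    """Noise parameters of a genotype's glomerular responses.

    Parameters are dimensionless (CVs) or in z-score units (noise floors).
    ``ci`` maps a parameter name to a (low, high) bootstrap interval when
    the model was estimated from data; it is empty for nominal regimes.
    """

    cv: float
    cv_uncorr: float
    sigma_noise: float
    sigma_uncorr_noise: float
    genotype: str = ""
    ci: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cv", "cv_uncorr", "sigma_noise", "sigma_uncorr_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cv_uncorr > self.cv + 1e-12:
            raise ValueError("cv_uncorr cannot exceed total cv")

    @property
    def cv_corr(self) -> float:
        """S.d. of the shared per-trial gain, sqrt(CV^2 - CV_uncorr^2)."""
        return float(np.sqrt(max(self.cv**2 - self.cv_uncorr**2, 0.0)))


#: Awake wild-type regime (intrinsic imaging, 2684 ROI-odor pairs).
WT = NoiseModel(cv=0.34, cv_uncorr=0.25, sigma_noise=1.59,
                sigma_uncorr_noise=1.47, genotype="WT")

#: Cntnap2-knockout-like regime: same response amplitudes, higher
#: trial-to-trial variability.
CNTNAP2 = NoiseModel(cv=0.64, cv_uncorr=0.44, sigma_noise=1.83,
                     sigma_uncorr_noise=1.65, genotype="Cntnap2")

#: z-score detection thresholds (magnitude of the cutoff) per genotype,
#: derived from sigma_noise / sqrt(16) and rounded as reported.
DETECTION_THRESHOLD = {"WT": -0.42, "Cntnap2": -0.46}


def _variance_law(mu: np.ndarray, sigma_noise: float, cv: float) -> np.ndarray:
    return sigma_noise**2 + cv**2 * mu**2


def _ls_variance_fit(x, y, vx=None, cxy=None):
    """Least squares for y = a + b x, clipped to a, b >= 0.

    The variance-mean law is linear in (sigma_noise^2, CV^2), so the
    least-squares optimum is closed-form.  When the regressor is a noisy
    estimate of mu^2, ``vx`` (its per-pair sampling variance) and ``cxy``
    (its noise covariance with y) apply the classical errors-in-variables
    moment correction, removing the attenuation that finite repeat counts
    would otherwise impose on the recovered CV.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc - (0.0 if vx is None else vx.sum())
    sxy = xc @ yc - (0.0 if cxy is None else cxy.sum())
    b = sxy / sxx if sxx > 0 else 0.0
    b = max(b, 0.0)
    a = max(y.mean() - b * x.mean(), 0.0)
    return a, b  # (sigma_noise^2, CV^2)


def fit_variance_mean(means, sds, *, n_repeats: int | None = None,
                      n_boot: int = 1000, seed: int | None = 0,
                      min_abs_mean: float = 0.0):
    """Fit sigma^2(mu) = sigma_noise^2 + CV^2 mu^2 to (mean, s.d.) pairs.

    Parameters
    ----------
    means, sds
        Per ROI-odor mean response and trial-to-trial standard deviation,
        both in z-score units.
    n_repeats
        Number of trials each (mean, s.d.) pair was estimated from.  When
        given, the fit corrects for the sampling noise of the empirical
        mean (errors-in-variables), which otherwise attenuates CV; leave
        None for exact/noise-free pairs.
    n_boot
        Bootstrap resamples (over ROI-odor pairs) for the 95% confidence
        intervals; 0 disables the bootstrap.
    seed
        Seed for the bootstrap resampling.
    min_abs_mean
        Optional preselection: drop pairs with |mean| below this value.

    Returns
    -------
    dict with keys ``cv``, ``sigma_noise`` and, when bootstrapped,
    ``cv_ci`` and ``sigma_noise_ci`` as (low, high) tuples.
    """
    mu = np.asarray(means, dtype=float).ravel()
    sd = np.asarray(sds, dtype=float).ravel()
    if mu.shape != sd.shape:
        raise ValueError("means and sds must have the same shape")
    keep = np.abs(mu) >= min_abs_mean
    mu, sd = mu[keep], sd[keep]
    if mu.size < 3 or np.unique(np.abs(mu)).size < 3:
        raise ValueError("need at least 3 pairs with distinct |mean|")
    if np.allclose(mu, 0.0):
        raise ValueError("all means are zero: CV is unidentifiable")
    if n_repeats is not None and n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 when given")

    var = sd**2

    def _fit(m, v):
        if n_repeats is None:
            a, b = _ls_variance_fit(m**2, v)
        else:
            n = n_repeats
            x = m**2 - v / n
            vx = 4.0 * np.clip(x, 0.0, None) * v / n + 2.0 * v**2 / (n * (n - 1))
            cxy = -2.0 * v**2 / ((n - 1) * n)
            a, b = _ls_variance_fit(x, v, vx, cxy)
        return np.sqrt(a), np.sqrt(b)  # (sigma_noise, cv)

    sigma_noise, cv = _fit(mu, var)
    out = {"cv": float(cv), "sigma_noise": float(sigma_noise)}
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 2))
        for b in range(n_boot):
            idx = rng.integers(0, mu.size, mu.size)
            boots[b] = _fit(mu[idx], var[idx])
        lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
        out["sigma_noise_ci"] = (float(lo[0]), float(hi[0]))
        out["cv_ci"] = (float(lo[1]), float(hi[1]))
    return out


def decompose_uncorrelated(trials: np.ndarray, *, n_boot: int = 0,
                           seed: int | None = 0, fit_sd: bool = False):
    """Split trial variability into a shared gain and an uncorrelated part.

    ``trials`` has shape (odors, rois, repeats).  For each odor and each
    repeat the single-trial responses of all simultaneously recorded ROIs
    are regressed (ordinary least squares, intercept included) onto the
    trial-averaged responses; the fitted line captures the population-wide
    gain of that presentation, and the residuals are the uncorrelated
    fluctuation of each ROI on that trial.  The per ROI-odor residual
    variance is then fit with

        sigma_uncorr^2(mu) = sigma_uncorr_noise^2 + CV_uncorr^2 mu^2

    Returns a dict with ``cv_uncorr``, ``sigma_uncorr_noise``, the
    per-presentation ``gains`` (slope of each line fit, odors x repeats),
    and per ROI-odor ``residual_sd``.  With ``n_boot`` > 0, bootstrap CIs
    over ROI-odor pairs are added.  ``fit_sd`` switches the final fit from
    variance to standard deviation form.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must be (odors, rois, repeats)")
    n_odors, n_rois, n_rep = trials.shape
    if n_rois < 2:
        raise ValueError("line-fit decomposition needs at least 2 ROIs")
    if n_rep < 3:
        raise ValueError("need at least 3 repeats")

    mean = trials.mean(axis=2)  # odors x rois
    gains = np.empty((n_odors, n_rep))
    resid = np.empty_like(trials)
    leverage = np.empty((n_odors, n_rois))
    for j in range(n_odors):
        x = mean[j]
        X = np.column_stack([np.ones(n_rois), x])
        # one OLS line per presentation: response_i(t) ~ a + b * mean_i
        coef, *_ = np.linalg.lstsq(X, trials[j], rcond=None)
        gains[j] = coef[1]
        resid[j] = trials[j] - X @ coef
        xc = x - x.mean()
        leverage[j] = 1.0 / n_rois + xc**2 / (xc @ xc)

    # studentize: strongly responding ROIs are leverage points of the
    # line fit and their raw residuals are deflated by (1 - h)
    residual_sd = np.sqrt(resid.var(axis=2, ddof=1)
                          / np.clip(1.0 - leverage, 1e-6, None))
    mu = mean.ravel()
    total_var = trials.var(axis=2, ddof=1).ravel()
    rvar = (residual_sd**2).ravel()

    # regressor: unbiased estimate of mu^2 with errors-in-variables
    # correction terms from the finite repeat count (see fit_variance_mean)
    x = mu**2 - total_var / n_rep
    vx = (4.0 * np.clip(x, 0.0, None) * total_var / n_rep
          + 2.0 * total_var**2 / (n_rep * (n_rep - 1)))

    def _fit(xx, vv, rv):
        if fit_sd:
            f = lambda m2, s0, c: np.sqrt(s0**2 + c**2 * m2)
            p, _ = curve_fit(f, xx, np.sqrt(rv), p0=[1.0, 0.2],
                             bounds=([0.0, 0.0], [np.inf, np.inf]),
                             maxfev=10000)
            return float(p[0]), float(p[1])
        a, b = _ls_variance_fit(xx, rv, vv)
        return np.sqrt(a), np.sqrt(b)

    sigma_un, cv_un = _fit(x, vx, rvar)
    out = {"cv_uncorr": float(cv_un), "sigma_uncorr_noise": float(sigma_un),
           "gains": gains, "residual_sd": residual_sd}
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 2))
        for b in range(n_boot):
            idx = rng.integers(0, x.size, x.size)
            boots[b] = _fit(x[idx], vx[idx], rvar[idx])
        lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
        out["sigma_uncorr_noise_ci"] = (float(lo[0]), float(hi[0]))
        out["cv_uncorr_ci"] = (float(lo[1]), float(hi[1]))
    return out


def detection_threshold(sigma_noise: float, n_repeats: int) -> float:
    """Standard error of the repeat-averaged response, sigma_noise/sqrt(n).

    Returned as a magnitude; downstream it is applied as a negative z-score
    cutoff (responses weaker than -threshold are treated as zero).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be non-negative")
    return sigma_noise / np.sqrt(n_repeats)


@dataclass(frozen=True)
class SaturationModel:
    """Saturating nonlinearity sigma(R) = 2A/(1 + exp(R*s)) - A.

    ``A`` (z-score) is the asymptote for strongly negative summed input;
    ``s`` (1/z-score) sets how quickly the sum saturates.  The function is
    odd and monotone, and passes through the origin for every (A, s).
    """

    A: float
    s: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("saturation rate s must be positive")


#: Fit to 68 glomeruli responding to two-odor mixtures.
SATURATION = SaturationModel(A=-8.0934, s=0.2091)


def apply_saturation(r, model: SaturationModel = SATURATION):
    """Evaluate the saturating nonlinearity at summed input ``r``."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * model.A / (1.0 + np.exp(r * model.s)) - model.A
    return float(out) if out.ndim == 0 else out


def fit_saturation(r_sum, observed, *, p0=(-1.0, 1.0)) -> SaturationModel:
    """Least-squares fit of (A, s) to (summed input, mixture response) pairs.

    Raises RuntimeError on non-convergence rather than returning defaults.
    """
    r = np.asarray(r_sum, dtype=float)
    y = np.asarray(observed, dtype=float)
    if r.size < 4:
        raise ValueError("need at least 4 pairs")

    def f(x, A, s):
        return 2.0 * A / (1.0 + np.exp(x * s)) - A

    popt, _ = curve_fit(f, r, y, p0=list(p0),
                        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                        maxfev=20000)
    return SaturationModel(A=float(popt[0]), s=float(popt[1]))
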