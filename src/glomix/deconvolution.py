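"""Lasso sparse deconvolution of glomerular mixture patterns.

An observed pattern ``s`` (one z-score per glomerulus) is decomposed
into a non-sparse dictionary of odor patterns ``d_j`` by minimizing

    Cost = sum_i (s_i - sum_j c_j d_ij)^2 + lambda * sum_j |c_j|

The dictionary holds the nine odors known from training (4 targets, 4
contextual backgrounds, the fixed background) plus synthetic elements
drawn from a Gaussian process whose mean and covariance across
glomeruli are estimated from the full 20-odor panel, so the synthetic
elements share the per-glomerulus activation statistics and the
inter-glomerular correlations of real odors.  Every element is scaled
to unit variance across the ROI axis.

The go/no-go readout compares the largest coefficient assigned to the
two go targets against the largest assigned to the two no-go targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso

from .decoders import GO, NOGO
from .mixtures import mixture_patterns
from .synthetic import GO_TARGETS, NOGO_TARGETS, GlomerularAtlas, ALL_ODORS


@dataclass
class OdorDictionary:
    """Columns = dictionary elements (ROIs x m), unit variance each."""

    elements: np.ndarray
    known_odors: tuple
    go_index: tuple
    nogo_index: tuple
    seed: int | None = None

    @property
    def m(self) -> int:
        return self.elements.shape[1]


@dataclass
class ConcentrationEstimate:
    """Lasso solution: one (signed) concentration per dictionary element."""

    c: np.ndarray
    residual: float
    lam: float


def _unit_variance(mat: np.ndarray) -> np.ndarray:
    sd = mat.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mat / sd


def build_dictionary(known_patterns: np.ndarray, known_odors,
                     all_odor_patterns: np.ndarray, m_total: int,
                     seed: int = 0) -> OdorDictionary:
    """Assemble known + synthetic dictionary elements.

    ``known_patterns`` is (ROIs, n_known); ``all_odor_patterns`` is
    (ROIs, n_odors) — typically the 20-odor panel — from which the mean
    vector and ROI x ROI covariance of the synthetic elements are taken.
    The covariance of ~20 samples in ~150 dimensions is rank-deficient;
    sampling uses its eigendecomposition restricted to non-negative
    eigenvalues, without shrinkage.
    """
    known = np.asarray(known_patterns, dtype=float)
    panel = np.asarray(all_odor_patterns, dtype=float)
    n_rois, n_known = known.shape
    if m_total < n_known:
        raise ValueError("m_total must be at least the number of known odors")
    known_odors = tuple(known_odors)
    if len(known_odors) != n_known:
        raise ValueError("known_odors must label every known pattern")

    cols = [_unit_variance(known)]
    n_extra = m_total - n_known
    if n_extra:
        mean = panel.mean(axis=1)
        cov = np.cov(panel)  # ROI x ROI, rank <= n_odors - 1
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 0.0, None)
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((evals.size, n_extra))
        extra = mean[:, None] + evecs @ (np.sqrt(evals)[:, None] * draws)
        cols.append(_unit_variance(extra))
    elements = np.concatenate(cols, axis=1)
    go_index = tuple(known_odors.index(o) for o in GO_TARGETS)
    nogo_index = tuple(known_odors.index(o) for o in NOGO_TARGETS)
    return OdorDictionary(elements=elements, known_odors=known_odors,
                          go_index=go_index, nogo_index=nogo_index, seed=seed)


def lasso_solve(dictionary: OdorDictionary, observed, lam: float = 1e-4,
                *, convention: str = "mse", positive: bool = False,
                max_iter: int = 5000) -> ConcentrationEstimate:
    """Minimize the L1-penalized reconstruction cost for one pattern.

    ``convention`` fixes the scale of ``lam``: "mse" (default) places it
    on the mean-squared-error cost (1/2n)||s - Dc||^2 + lam ||c||_1 —
    the convention of Matlab's ``lasso`` and scikit-learn, under which
    the reference value is lam = 1e-4; "sse" places it on the raw
    summed-squares cost ||s - Dc||^2 + lam ||c||_1.

    Coefficients are unconstrained in sign by default (set ``positive``
    for a non-negative variant).  Coordinate descent runs for up to
    ``max_iter`` sweeps; because realistic dictionaries are strongly
    rank-deficient, the duality-gap certificate can be unattainable at
    tiny penalties even at the fixed point, so the solution is validated
    against the objective itself — a solution that fails to beat c = 0
    or is non-finite raises RuntimeError.
    """
    s = np.asarray(observed, dtype=float)
    D = dictionary.elements
    if s.shape[0] != D.shape[0]:
        raise ValueError("observation length must match dictionary ROI axis")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n = D.shape[0]
    if convention == "mse":
        alpha = max(lam, 1e-12)
    elif convention == "sse":
        alpha = max(lam, 1e-12) / (2.0 * n)
    else:
        raise ValueError("convention must be 'mse' or 'sse'")
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = Lasso(alpha=alpha, fit_intercept=False, positive=positive,
                      max_iter=max_iter, tol=1e-4).fit(D, s)
    c = model.coef_.copy()
    rss = float(np.sum((s - D @ c) ** 2))
    achieved = rss / (2.0 * n) + alpha * np.abs(c).sum()
    baseline = float(np.sum(s**2)) / (2.0 * n)
    if not np.all(np.isfinite(c)) or achieved > baseline + 1e-9:
        raise RuntimeError("Lasso failed to converge to a useful solution")
    return ConcentrationEstimate(c=c, residual=rss, lam=lam)


def cost(dictionary: OdorDictionary, observed, c, lam: float,
         convention: str = "mse") -> float:
    """Evaluate the L1-penalized reconstruction cost at coefficients ``c``."""
    s = np.asarray(observed, dtype=float)
    c = np.asarray(c, dtype=float)
    rss = float(np.sum((s - dictionary.elements @ c) ** 2))
    if convention == "mse":
        return rss / (2.0 * s.size) + lam * float(np.sum(np.abs(c)))
    return rss + lam * float(np.sum(np.abs(c)))


def go_nogo_readout(estimate: ConcentrationEstimate,
                    dictionary: OdorDictionary) -> str:
    """Compare max go-target vs max no-go-target concentration.

    Exact ties resolve to no-go.
    """
    c = estimate.c
    go_max = max(c[i] for i in dictionary.go_index)
    nogo_max = max(c[i] for i in dictionary.nogo_index)
    return GO if go_max > nogo_max else NOGO


def evaluate_lasso(atlas: GlomerularAtlas, mixtures, *, dictionary_sizes=(500,),
                   n_dictionaries: int = 30, lam: float = 1e-4,
                   noise_cv: float = 0.25, threshold: float | None = None,
                   saturation=None, seed: int = 0,
                   known_odors=None):
    """Lasso go/no-go performance per dictionary size.

    For each size, ``n_dictionaries`` random dictionaries are built and
    each is probed with one noisy instantiation of every mixture in
    ``mixtures`` (composed from the atlas with the given threshold and
    saturation).  Returns {size: mean fraction correct}.
    """
    if not mixtures:
        raise ValueError("empty test design")
    if known_odors is None:
        known_odors = tuple(o for o in ALL_ODORS
                            if atlas.odor_roles.get(o) in
                            ("go_target", "nogo_target", "contextual", "fixed"))
    known = np.stack([atlas.pattern(o) for o in known_odors], axis=1)
    panel = atlas.mean_z.T  # ROIs x all odors
    patterns = mixture_patterns(atlas, mixtures, threshold, saturation)
    rng = np.random.default_rng(seed)

    perf = {}
    for size in dictionary_sizes:
        correct = 0
        total = 0
        for d in range(n_dictionaries):
            dic = build_dictionary(known, known_odors, panel, size,
                                   seed=int(rng.integers(2**31 - 1)))
            noisy = patterns * (1.0 + noise_cv
                                * rng.standard_normal(patterns.shape))
            for i, m in enumerate(mixtures):
                est = lasso_solve(dic, noisy[i], lam)
                correct += go_nogo_readout(est, dic) == m.valence
                total += 1
        perf[size] = correct / total
    return perf
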