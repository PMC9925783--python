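"""Decoders for go/no-go odor-mixture classification.

Four families, all operating on time-averaged glomerular patterns:

* single best glomerulus — the ROI with the highest training
  discriminability, thresholded at the Youden point of its ROC curve;
* L1-regularized linear SVM and logistic regression — decision by the
  sign of ``w . s + w0``;
* nearest-neighbor classifier (NNC) — the test pattern inherits the
  valence of the training template with the largest dot product, with an
  optional auROC-based selectivity filter on the included ROIs.

Discriminability of a single ROI is ``abs(auROC - 0.5) + 0.5``: 1 for
perfect separation of go from no-go responses in either direction, 0.5
for none.  Evaluation instantiates each test mixture many times with
multiplicative trial noise (the population decoders use the uncorrelated
CV; the single-glomerulus decoder the total CV, since one ROI cannot
subtract the population-wide gain) and reports the fraction of
correctly labeled instantiations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import LinearSVC

GO, NOGO = "go", "nogo"


def center_patterns(train: np.ndarray, test: np.ndarray | None = None):
    """Subtract per-ROI training means from training and test patterns.

    Returns (centered_train, centered_test, means); ``test`` may be None.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("training set must be a non-empty (mixtures, rois) matrix")
    means = train.mean(axis=0)
    ctest = None if test is None else np.asarray(test, dtype=float) - means
    return train - means, ctest, means


def _go_mask(labels) -> np.ndarray:
    mask = np.asarray([lab == GO if isinstance(lab, str) else bool(lab)
                       for lab in labels])
    if mask.all() or not mask.any():
        raise ValueError("both classes must be present")
    return mask


def glomerulus_discriminability(responses, labels):
    """auROC (go as positive class) and discriminability of one ROI.

    Returns (auroc, abs(auroc - 0.5) + 0.5).  Rank-based; ties count 1/2.
    """
    y = _go_mask(labels)
    auroc = float(roc_auc_score(y, np.asarray(responses, dtype=float)))
    return auroc, abs(auroc - 0.5) + 0.5


@dataclass
class GlomerulusClassifier:
    """Decision rule of a single ROI: side + threshold in z-score units."""

    roi: int
    threshold: float
    orientation: int  # +1: go side is above threshold; -1: below
    training_auroc: float
    center: np.ndarray | None = None

    def predict_batch(self, patterns: np.ndarray):
        x = np.asarray(patterns, dtype=float)[:, self.roi]
        go = self.orientation * (x - self.threshold) > 0
        return np.where(go, GO, NOGO)


def fit_best_glomerulus(train: np.ndarray, labels) -> GlomerulusClassifier:
    """Pick the most discriminative ROI and its Youden-optimal threshold.

    The orientation (whether more-negative responses indicate go) is
    learned from the training set.  Ties in discriminability resolve to
    the lowest ROI index.
    """
    train = np.asarray(train, dtype=float)
    y = _go_mask(labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 mixtures per class")
    aurocs = np.array([roc_auc_score(y, train[:, i])
                       for i in range(train.shape[1])])
    disc = np.abs(aurocs - 0.5) + 0.5
    roi = int(np.argmax(disc))
    orientation = 1 if aurocs[roi] >= 0.5 else -1
    score = orientation * train[:, roi]
    fpr, tpr, thr = roc_curve(y, score)
    k = int(np.argmax(tpr - fpr))  # Youden point = 45-degree tangent
    # roc_curve thresholds are inclusive scores; place the cut just below
    # so ">" classification keeps the boundary sample on the go side.
    cut = thr[k] - 1e-12 if np.isfinite(thr[k]) else score.max()
    return GlomerulusClassifier(roi=roi, threshold=float(orientation * cut),
                                orientation=orientation,
                                training_auroc=float(aurocs[roi]))


@dataclass
class LinearDecoder:
    """Linear go/no-go filter: sign of ``w . s + w0``.

    ``lam`` is the sparseness constraint (0 = unpenalized); ``center``
    stores the per-ROI training means subtracted before decoding.
    """

    weights: np.ndarray
    bias: float
    family: str
    lam: float
    center: np.ndarray | None = None

    def decision_values(self, patterns: np.ndarray) -> np.ndarray:
        x = np.asarray(patterns, dtype=float)
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError("pattern length does not match weight vector")
        return x @ self.weights + self.bias

    def predict_batch(self, patterns: np.ndarray):
        # exact zero resolves to no-go (conservative, deterministic)
        return np.where(self.decision_values(patterns) > 0, GO, NOGO)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.weights))


def train_linear(train: np.ndarray, labels, family: str = "svm",
                 lam: float = 0.0) -> LinearDecoder:
    """Fit an L1-penalized linear SVM or logistic regression.

    ``lam`` maps onto the inverse of scikit-learn's C (scaled by the
    number of training mixtures); lam = 0 gives an effectively
    unpenalized fit.
    """
    train = np.asarray(train, dtype=float)
    y = np.where(_go_mask(labels), 1, -1)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n = train.shape[0]
    if family == "svm":
        if lam == 0:
            clf = LinearSVC(C=1e6, loss="squared_hinge", max_iter=50000, tol=1e-6)
        else:
            clf = LinearSVC(penalty="l1", dual=False, C=1.0 / (lam * n),
                            loss="squared_hinge", max_iter=50000, tol=1e-6)
    elif family == "logistic":
        if lam == 0:
            clf = LogisticRegression(C=np.inf, max_iter=10000)
        else:
            clf = LogisticRegression(l1_ratio=1, solver="liblinear",
                                     C=1.0 / (lam * n), max_iter=10000)
    else:
        raise ValueError("family must be 'svm' or 'logistic'")
    clf.fit(train, y)
    return LinearDecoder(weights=clf.coef_.ravel().copy(),
                         bias=float(clf.intercept_[0]), family=family, lam=lam)


@dataclass
class NNCDecoder:
    """Nearest-neighbor template matcher over training mixtures.

    ``included`` masks the ROIs that survive the training-set
    discriminability filter; dot products run over those ROIs only.
    """

    templates: np.ndarray
    valences: tuple
    included: np.ndarray
    selectivity_threshold: float = 0.5
    center: np.ndarray | None = None

    def predict_batch(self, patterns: np.ndarray):
        x = np.asarray(patterns, dtype=float)[:, self.included]
        dots = x @ self.templates[:, self.included].T
        best = np.argmax(dots, axis=1)  # ties -> lowest template index
        return np.asarray(self.valences)[best]

    @property
    def n_active(self) -> int:
        return int(self.included.sum())


def train_nnc(train: np.ndarray, labels,
              selectivity_threshold: float = 0.5) -> NNCDecoder:
    """Build an NNC, filtering ROIs by training discriminability.

    At threshold 0.5 every ROI is included (discriminability is never
    below 0.5); at 1 only perfectly discriminating ROIs survive.
    """
    train = np.asarray(train, dtype=float)
    y = _go_mask(labels)
    disc = np.array([abs(roc_auc_score(y, train[:, i]) - 0.5) + 0.5
                     for i in range(train.shape[1])])
    included = disc >= selectivity_threshold
    if not included.any():
        raise ValueError("no ROIs survive the selectivity filter")
    valences = tuple(GO if g else NOGO for g in y)
    return NNCDecoder(templates=train, valences=valences, included=included,
                      selectivity_threshold=selectivity_threshold)


@dataclass
class DecoderResult:
    """Evaluation summary over noisy instantiations of a test set."""

    fraction_correct: float
    per_background: pd.DataFrame
    n_instantiations: int
    seed: int
    decisions: np.ndarray = field(repr=False, default=None)


def evaluate(decoder, mixtures, patterns: np.ndarray, noise_cv: float,
             n_instantiations: int = 100, seed: int = 0) -> DecoderResult:
    """Fraction of correctly classified noisy instantiations.

    Each mean mixture pattern is instantiated ``n_instantiations`` times
    as ``s = mu * (1 + noise_cv * eps)`` (multiplicative trial noise on
    the raw pattern); the decoder's stored centering means, if any, are
    subtracted afterwards.  Per novel-background aggregation is included
    in the result.
    """
    if n_instantiations < 1:
        raise ValueError("n_instantiations must be >= 1")
    patterns = np.asarray(patterns, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    correct_all = np.empty((len(mixtures), n_instantiations), dtype=bool)
    for i, m in enumerate(mixtures):
        mu = patterns[i]
        x = mu * (1.0 + noise_cv * rng.standard_normal((n_instantiations, mu.size)))
        if getattr(decoder, "center", None) is not None:
            x = x - decoder.center
        pred = decoder.predict_batch(x)
        correct_all[i] = pred == m.valence
        rows.append({"background": m.background, "valence": m.valence,
                     "fraction_correct": float(correct_all[i].mean())})
    per_bg = (pd.DataFrame(rows).groupby("background", as_index=False)
              ["fraction_correct"].mean())
    return DecoderResult(fraction_correct=float(correct_all.mean()),
                         per_background=per_bg,
                         n_instantiations=n_instantiations, seed=seed,
                         decisions=correct_all)
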