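"""End-to-end model-comparison experiments on synthetic atlases.

These drivers reproduce the study-level comparisons: all four decoder
families plus Lasso deconvolution, trained on the full or reduced
design, under wild-type or knockout-like noise regimes, with
glomerulus-count sweeps, behavioral-correlation Monte Carlo, and
sensitivity of performance to the uncorrelated trial-to-trial CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import decoders as dec
from .deconvolution import evaluate_lasso
from .mixtures import enumerate_design, mixture_patterns
from .noise import CNTNAP2, DETECTION_THRESHOLD, SATURATION, WT
from .synthetic import AtlasSpec, generate_atlas, measure_atlas


@dataclass
class ExperimentConfig:
    """Knobs of one model-comparison run.

    ``n_instantiations`` follows the evaluation protocol (100 noisy
    instantiations per test mixture); reduce for quick runs.
    ``n_measurement_repeats`` sets the per-odor repeat count of the
    simulated atlas measurement (the source of the residual imaging
    noise the detection threshold guards against); None uses the true
    atlas directly.
    """

    genotype: str = "WT"
    design: str = "full"
    decoder_families: tuple = ("svm", "logistic", "nnc", "glomerulus")
    n_sessions: int = 5
    n_rois: int = 155
    n_measurement_repeats: int | None = 16
    n_instantiations: int = 100
    lam_grid: tuple = tuple(np.round(np.linspace(0.0, 1.0, 21), 3))
    selectivity_grid: tuple = tuple(np.round(np.linspace(0.5, 1.0, 10), 3))
    lasso_sizes: tuple = (100, 500, 1000)
    lasso_n_dictionaries: int = 30
    lasso_lam: float = 1e-4
    use_saturation: bool = True
    seed: int = 0

    def noise_model(self):
        return WT if self.genotype == "WT" else CNTNAP2

    def threshold(self) -> float:
        return DETECTION_THRESHOLD["WT" if self.genotype == "WT" else "Cntnap2"]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonReport:
    """Per-session decoder performance plus optional sweep/Lasso tables."""

    performance: pd.DataFrame
    sweeps: pd.DataFrame | None = None
    lasso: pd.DataFrame | None = None
    config: ExperimentConfig | None = None


def _session_data(cfg: ExperimentConfig, session: int, *, design=None,
                  noise_cv: float | None = None):
    """Atlas, composed train/test patterns and labels for one session."""
    design = design if design is not None else enumerate_design(cfg.design)
    atlas = generate_atlas(AtlasSpec(n_rois=cfg.n_rois, seed=cfg.seed * 1000 + session),
                           animal_id=f"session_{session}")
    if cfg.n_measurement_repeats is not None:
        atlas = measure_atlas(atlas, cfg.noise_model(),
                              cfg.n_measurement_repeats,
                              seed=cfg.seed * 1000 + session + 31)
    sat = SATURATION if cfg.use_saturation else None
    thr = cfg.threshold()
    train = mixture_patterns(atlas, design.training, thr, sat)
    test = mixture_patterns(atlas, design.test, thr, sat)
    nm = cfg.noise_model()
    cv = nm.cv_uncorr if noise_cv is None else noise_cv
    return atlas, design, train, test, nm, cv


def _train_family(family: str, ctrain, labels, lam=0.0, selectivity=0.5):
    if family in ("svm", "logistic"):
        return dec.train_linear(ctrain, labels, family=family, lam=lam)
    if family == "nnc":
        return dec.train_nnc(ctrain, labels, selectivity_threshold=selectivity)
    if family == "glomerulus":
        return dec.fit_best_glomerulus(ctrain, labels)
    raise ValueError(f"unknown decoder family {family!r}")


def run_comparison(cfg: ExperimentConfig, *, include_lasso: bool = True,
                   noise_cv: float | None = None) -> ComparisonReport:
    """Train every configured decoder per session and evaluate on the
    test set; optionally run Lasso deconvolution on the same design.

    Population decoders see multiplicative noise at the genotype's
    uncorrelated CV; the single-glomerulus decoder sees the total CV.
    """
    rows = []
    lasso_rows = []
    for s in range(cfg.n_sessions):
        atlas, design, train, test, nm, cv = _session_data(
            cfg, s, noise_cv=noise_cv)
        labels = [m.valence for m in design.training]
        ctrain, _, means = dec.center_patterns(train)
        for family in cfg.decoder_families:
            decoder = _train_family(family, ctrain, labels)
            decoder.center = means
            ev_cv = nm.cv if family == "glomerulus" else cv
            res = dec.evaluate(decoder, design.test, test, ev_cv,
                               cfg.n_instantiations,
                               seed=cfg.seed * 7919 + s)
            tr_res = dec.evaluate(decoder, design.training, train, ev_cv,
                                  cfg.n_instantiations,
                                  seed=cfg.seed * 7919 + s + 500)
            rows.append({"session": s, "decoder": family,
                         "test_performance": res.fraction_correct,
                         "train_performance": tr_res.fraction_correct})
        if include_lasso:
            perf = evaluate_lasso(
                atlas, list(design.test), dictionary_sizes=cfg.lasso_sizes,
                n_dictionaries=cfg.lasso_n_dictionaries, lam=cfg.lasso_lam,
                noise_cv=cv, threshold=cfg.threshold(),
                saturation=SATURATION if cfg.use_saturation else None,
                seed=cfg.seed * 104729 + s)
            for size, p in perf.items():
                lasso_rows.append({"session": s, "decoder": "lasso",
                                   "dictionary_size": size,
                                   "test_performance": p})
    perf_df = pd.DataFrame(rows)
    lasso_df = pd.DataFrame(lasso_rows) if lasso_rows else None
    return ComparisonReport(performance=perf_df, lasso=lasso_df, config=cfg)


def sweep_glomeruli(cfg: ExperimentConfig) -> pd.DataFrame:
    """Performance and included-ROI count along the sparsity grids.

    Linear families sweep the 21-value lambda grid on [0, 1]; the NNC
    sweeps 10 selectivity thresholds on [0.5, 1].  Returns one row per
    (session, decoder, grid value).
    """
    rows = []
    for s in range(cfg.n_sessions):
        _, design, train, test, nm, cv = _session_data(cfg, s)
        labels = [m.valence for m in design.training]
        ctrain, _, means = dec.center_patterns(train)
        for family in ("svm", "logistic"):
            if family not in cfg.decoder_families:
                continue
            for lam in cfg.lam_grid:
                d = dec.train_linear(ctrain, labels, family=family, lam=lam)
                d.center = means
                res = dec.evaluate(d, design.test, test, cv,
                                   cfg.n_instantiations, seed=cfg.seed + s)
                rows.append({"session": s, "decoder": family, "grid": lam,
                             "n_rois_used": d.n_active,
                             "test_performance": res.fraction_correct})
        if "nnc" in cfg.decoder_families:
            for sel in cfg.selectivity_grid:
                try:
                    d = dec.train_nnc(ctrain, labels, selectivity_threshold=sel)
                except ValueError:  # no ROI survives at this selectivity
                    continue
                d.center = means
                res = dec.evaluate(d, design.test, test, cv,
                                   cfg.n_instantiations, seed=cfg.seed + s)
                rows.append({"session": s, "decoder": "nnc", "grid": sel,
                             "n_rois_used": d.n_active,
                             "test_performance": res.fraction_correct})
    return pd.DataFrame(rows)


def correlate_with_behavior(per_odor_sampler, behavior: pd.DataFrame,
                            n_mc: int = 500, seed: int = 0) -> np.ndarray:
    """Monte-Carlo distribution of Pearson r between decoder and behavior.

    ``per_odor_sampler(seed)`` must return a Series of per-odor decoder
    performance indexed by odor; it is re-drawn ``n_mc`` times with fresh
    instantiation noise and correlated with the behavioral per-odor
    fraction correct on the shared odors.
    """
    beh = behavior.set_index("odor")["fraction_correct"]
    rng = np.random.default_rng(seed)
    rs = np.empty(n_mc)
    for k in range(n_mc):
        perf = per_odor_sampler(int(rng.integers(2**31 - 1)))
        shared = beh.index.intersection(perf.index)
        if len(shared) < 3:
            raise ValueError("need at least 3 shared odors")
        rs[k] = stats.pearsonr(perf.loc[shared], beh.loc[shared])[0]
    return rs


def make_per_odor_sampler(decoder, mixtures, patterns, noise_cv,
                          n_instantiations: int = 100):
    """Sampler of per-novel-background decoder performance for the
    behavioral-correlation Monte Carlo."""
    def sampler(seed: int) -> pd.Series:
        res = dec.evaluate(decoder, mixtures, patterns, noise_cv,
                           n_instantiations, seed=seed)
        return res.per_background.set_index("background")["fraction_correct"]
    return sampler


def cv_sensitivity(cfg: ExperimentConfig, cv_grid, alpha: float = 0.05,
                   min_effect: float = 0.02) -> pd.DataFrame:
    """Decoder performance across a grid of uncorrelated CV values.

    Each grid point re-evaluates the configured population decoders with
    that CV (training is noise-free, as in the evaluation protocol).
    The returned frame carries, per decoder, a ``degraded`` flag: whether
    mean performance at that CV falls significantly below the first grid
    value (paired two-sided t-test across sessions at ``alpha``) by more
    than ``min_effect`` — the effect-size floor keeps sub-percent dips,
    which paired tests on matched sessions can resolve, from counting as
    degradation.
    """
    cv_grid = list(cv_grid)
    rows = []
    per_session = {}  # (decoder, cv) -> array over sessions
    for cv in cv_grid:
        rep = run_comparison(cfg, include_lasso=False, noise_cv=cv)
        for family, grp in rep.performance.groupby("decoder"):
            vals = grp.sort_values("session")["test_performance"].to_numpy()
            per_session[(family, cv)] = vals
    base_cv = cv_grid[0]
    for (family, cv), vals in per_session.items():
        base = per_session[(family, base_cv)]
        if cv == base_cv:
            p = 1.0
        else:
            p = float(stats.ttest_rel(vals, base)[1])
        rows.append({"decoder": family, "cv_uncorr": cv,
                     "test_performance": float(vals.mean()),
                     "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                     if len(vals) > 1 else 0.0,
                     "p_vs_baseline": p,
                     "degraded": bool(p < alpha and
                                      base.mean() - vals.mean() > min_effect)})
    return pd.DataFrame(rows).sort_values(["decoder", "cv_uncorr"],
                                          ignore_index=True)
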