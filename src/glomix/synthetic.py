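"""Synthetic glomerular data with the statistical structure of awake
intrinsic imaging of the mouse olfactory bulb.

The generator produces per-animal *atlases*: matrices of mean z-score
responses (odors x ROIs) in which activation is a negative deflection.
Default role statistics follow the measured ones: target odors activate
~29.5% of glomeruli at a mean z of -0.32, contextual backgrounds ~43.5%
at -0.70, the fixed background ~37% at -0.41, and novel backgrounds
~46.1% at -0.63, on ~155 ROIs per animal.

Single presentations are instantiated from an atlas with the
multiplicative noise model

    s_ij(t) = mean_ij * (1 + CV_corr * g_t + CV_uncorr * e_ijt)
              + sigma_noise * h_ijt

where ``g_t`` is a gain shared by all ROIs within a presentation and
``e``, ``h`` are independent standard normals.  The total variance obeys
sigma^2(mu) = sigma_noise^2 + CV^2 mu^2 with CV^2 = CV_corr^2 +
CV_uncorr^2, so the variance-mean decomposition implemented in
:mod:`glomix.noise` is exact under this generator.

Also provided: planted-glomerulus intrinsic-imaging movies (fixtures for
the quantification pipeline, with ground-truth ROI masks) and synthetic
per-odor behavioral performance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noise import NoiseModel

# Odor roles used throughout the package.  Two go and two no-go targets,
# four contextual backgrounds, one fixed background, eleven novel
# backgrounds: 20 odors total.
GO_TARGETS = ("target_go_1", "target_go_2")
NOGO_TARGETS = ("target_nogo_1", "target_nogo_2")
TARGETS = GO_TARGETS + NOGO_TARGETS
CONTEXTS = tuple(f"context_{i}" for i in range(1, 5))
FIXED_BG = "fixed_bg"
NOVELS = tuple(f"novel_{i}" for i in range(1, 12))
ALL_ODORS = TARGETS + CONTEXTS + (FIXED_BG,) + NOVELS

DEFAULT_ROLES = {
    **{o: "go_target" for o in GO_TARGETS},
    **{o: "nogo_target" for o in NOGO_TARGETS},
    **{o: "contextual" for o in CONTEXTS},
    FIXED_BG: "fixed",
    **{o: "novel" for o in NOVELS},
}

# (fraction of ROIs activated, mean z over ALL ROIs of the animal) per
# role; the mean over active ROIs alone is mean / fraction.
DEFAULT_ROLE_STATS = {
    "go_target": (0.295, -0.32),
    "nogo_target": (0.295, -0.32),
    "contextual": (0.435, -0.70),
    "fixed": (0.37, -0.41),
    "novel": (0.461, -0.63),
}


@dataclass(frozen=True)
class AtlasSpec:
    """Recipe for a synthetic per-animal atlas.

    ``frac_active_by_role`` maps each role to the fraction of ROIs an
    odor of that role activates; ``mean_amplitude_by_role`` to the mean
    z-score over all ROIs of the animal (negative; the active-ROI mean is
    this value divided by the fraction).

    Odor tuning is a latent affinity field per ROI: an ROI's affinities
    to different odors are jointly Gaussian with an odor-odor correlation
    set by the ``*_rho`` fields (the four chemically related targets are
    mutually correlated, more strongly within a valence pair; background
    odors are independent, matching the near-baseline conditional overlap
    between target- and background-responsive glomeruli).
    ``n_tuning_factors`` confines all odor patterns to a shared
    low-dimensional tuning space across ROIs (glomerular odor codes are
    strongly correlated across glomeruli; the default matches the size
    of the odor panel); None gives independent ROIs.  An ROI is active
    for an odor when its |affinity| ranks in the top ``frac`` fraction,
    and the amplitude is that magnitude scaled to the role mean — so
    activation masks and amplitudes of related odors are correlated
    through one mechanism.
    """

    n_rois: int = 155
    odor_roles: dict = field(default_factory=lambda: dict(DEFAULT_ROLES))
    frac_active_by_role: dict = field(
        default_factory=lambda: {r: f for r, (f, _) in DEFAULT_ROLE_STATS.items()})
    mean_amplitude_by_role: dict = field(
        default_factory=lambda: {r: m for r, (_, m) in DEFAULT_ROLE_STATS.items()})
    target_rho_same_valence: float = 0.75
    target_rho_cross_valence: float = 0.45
    background_rho: float = 0.0
    n_tuning_factors: int | None = 20
    amplitude_power: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois <= 0:
            raise ValueError("n_rois must be positive")
        for role, f in self.frac_active_by_role.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for role {role!r} outside [0, 1]")
        for role, m in self.mean_amplitude_by_role.items():
            if m > 0:
                raise ValueError(f"mean amplitude for role {role!r} must be <= 0")
        for name in ("target_rho_same_valence", "target_rho_cross_valence",
                     "background_rho"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.amplitude_power <= 0:
            raise ValueError("amplitude_power must be positive")

    def odor_correlation(self) -> np.ndarray:
        """Odor-odor correlation matrix of the latent affinity field."""
        odors = tuple(self.odor_roles)
        k = len(odors)
        rho = np.eye(k)
        is_target = {o: self.odor_roles[o] in ("go_target", "nogo_target")
                     for o in odors}
        for a in range(k):
            for b in range(a + 1, k):
                oa, ob = odors[a], odors[b]
                if is_target[oa] and is_target[ob]:
                    same = self.odor_roles[oa] == self.odor_roles[ob]
                    r = (self.target_rho_same_valence if same
                         else self.target_rho_cross_valence)
                elif not is_target[oa] and not is_target[ob]:
                    r = self.background_rho
                else:
                    r = 0.0
                rho[a, b] = rho[b, a] = r
        return rho


@dataclass
class GlomerularAtlas:
    """Mean z-score responses of one animal: odors x ROIs, negative = active.

    Entries of non-activated ROI-odor pairs are exactly zero.
    """

    mean_z: np.ndarray
    odors: tuple
    odor_roles: dict
    animal_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.mean_z = np.asarray(self.mean_z, dtype=float)
        if not np.all(np.isfinite(self.mean_z)):
            raise ValueError("atlas entries must be finite")
        if self.mean_z.shape[0] != len(self.odors):
            raise ValueError("row count must match odor count")

    @property
    def n_rois(self) -> int:
        return self.mean_z.shape[1]

    def pattern(self, odor: str) -> np.ndarray:
        return self.mean_z[self.odors.index(odor)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: animal, odor, roi, value."""
        n_odor, n_roi = self.mean_z.shape
        return pd.DataFrame({
            "animal": self.animal_id,
            "odor": np.repeat(self.odors, n_roi),
            "roi": np.tile(np.arange(n_roi), n_odor),
            "value": self.mean_z.ravel(),
        })


@dataclass
class TrialSet:
    """Single-presentation responses: odors x ROIs x repeats."""

    trials: np.ndarray
    odors: tuple
    noise: NoiseModel
    seed: int

    @property
    def n_repeats(self) -> int:
        return self.trials.shape[2]

    def to_frame(self, animal_id: str = "synthetic") -> pd.DataFrame:
        n_odor, n_roi, n_rep = self.trials.shape
        return pd.DataFrame({
            "animal": animal_id,
            "odor": np.repeat(self.odors, n_roi * n_rep),
            "roi": np.tile(np.repeat(np.arange(n_roi), n_rep), n_odor),
            "repeat": np.tile(np.arange(n_rep), n_odor * n_roi),
            "value": self.trials.ravel(),
        })


def generate_atlas(spec: AtlasSpec, animal_id: str = "synthetic") -> GlomerularAtlas:
    """Draw a per-animal atlas from an :class:`AtlasSpec`.

    Per ROI, a latent affinity vector over odors (correlated per
    ``spec.odor_correlation``, optionally confined to a low-dimensional
    tuning space across ROIs) is drawn; for each odor the ROIs whose
    |affinity| ranks in the top role fraction are active, with
    amplitudes equal to that magnitude scaled so the mean response over
    all ROIs matches the role's mean.  Inactive entries are exactly
    zero.
    """
    rng = np.random.default_rng(spec.seed)
    odors = tuple(spec.odor_roles)
    k = len(odors)
    rho = spec.odor_correlation()
    # Cholesky with a tiny jitter guard for borderline-PSD matrices
    try:
        chol = np.linalg.cholesky(rho)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(rho + 1e-10 * np.eye(k))
    if spec.n_tuning_factors is None:
        latent = chol @ rng.standard_normal((k, spec.n_rois))
    else:
        d = spec.n_tuning_factors
        factors = chol @ rng.standard_normal((k, d))  # odor loadings
        roi_weights = rng.standard_normal((d, spec.n_rois))
        latent = factors @ roi_weights / np.sqrt(d)

    mean_z = np.zeros((k, spec.n_rois))
    for j, odor in enumerate(odors):
        role = spec.odor_roles[odor]
        frac = spec.frac_active_by_role[role]
        mean_all = spec.mean_amplitude_by_role[role]
        n_act = int(round(frac * spec.n_rois))
        if n_act == 0 or mean_all == 0.0:
            continue
        a = np.abs(latent[j])
        active = np.argsort(a)[-n_act:]
        # power transform spreads the amplitude distribution to the
        # heavy-tailed dispersion seen across responsive ROI-odor pairs
        amp = a[active] ** spec.amplitude_power
        mean_z[j, active] = -amp * (abs(mean_all) * spec.n_rois / amp.sum())
    return GlomerularAtlas(mean_z=mean_z, odors=odors,
                           odor_roles=dict(spec.odor_roles), animal_id=animal_id)


def instantiate_trials(atlas, noise: NoiseModel, n_repeats: int, seed: int,
                       *, include_correlated: bool = True,
                       include_imaging_noise: bool = True) -> TrialSet:
    """Instantiate noisy single presentations of every odor in an atlas.

    The uncorrelated multiplicative term uses ``noise.cv_uncorr``; when
    ``include_correlated`` a shared per-presentation gain of s.d.
    ``noise.cv_corr`` is applied to all ROIs; when ``include_imaging_noise``
    independent additive noise of s.d. ``noise.sigma_noise`` is added.
    Deterministic under a fixed seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if isinstance(atlas, GlomerularAtlas):
        mean, odors = atlas.mean_z, atlas.odors
    else:
        mean = np.atleast_2d(np.asarray(atlas, dtype=float))
        odors = tuple(f"odor_{j}" for j in range(mean.shape[0]))
    rng = np.random.default_rng(seed)
    n_odors, n_rois = mean.shape

    trials = np.repeat(mean[:, :, None], n_repeats, axis=2)
    trials = trials * (1.0 + noise.cv_uncorr
                       * rng.standard_normal((n_odors, n_rois, n_repeats)))
    if include_correlated and noise.cv_corr > 0:
        gain = noise.cv_corr * rng.standard_normal((n_odors, 1, n_repeats))
        trials += mean[:, :, None] * gain
    if include_imaging_noise and noise.sigma_noise > 0:
        trials += noise.sigma_noise * rng.standard_normal(trials.shape)
    return TrialSet(trials=trials, odors=odors, noise=noise, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic intrinsic-imaging movies


@dataclass(frozen=True)
class MovieSpec:
    """Geometry and noise of a planted-glomerulus movie.

    Times in seconds, sizes in micrometres.  The response window used for
    quantification downstream is 2-9 s after odor onset, so the default
    duration leaves room for a 5 s air baseline plus a 9 s odor pulse.
    """

    shape: tuple = (96, 96)
    pixel_size_um: float = 3.3
    frame_rate: float = 5.0
    baseline_s: float = 5.0
    odor_onset_s: float = 5.0
    odor_duration_s: float = 9.0
    duration_s: float = 15.0
    glom_sigma_um: float = 20.0
    dff_per_z: float = 1e-3
    hemodynamic_amplitude: float = 0.0
    hemodynamic_sigma_um: float = 150.0
    pixel_noise: float = 0.0
    f0: float = 1000.0

    def __post_init__(self) -> None:
        if self.odor_onset_s < self.baseline_s:
            raise ValueError("odor onset must come after the baseline window")
        if self.duration_s <= self.odor_onset_s:
            raise ValueError("odor onset must fall inside the movie")


def measure_atlas(atlas: GlomerularAtlas, noise: NoiseModel, n_repeats: int,
                  seed: int) -> GlomerularAtlas:
    """Simulate the measured (repeat-averaged) version of a true atlas.

    Real atlases are averages of ``n_repeats`` noisy presentations, so
    every entry carries residual imaging noise of s.d.
    ``sigma_noise / sqrt(n)`` plus averaged multiplicative variability —
    the reason a detection threshold exists downstream.
    """
    ts = instantiate_trials(atlas, noise, n_repeats, seed)
    return GlomerularAtlas(mean_z=ts.trials.mean(axis=2), odors=atlas.odors,
                           odor_roles=dict(atlas.odor_roles),
                           animal_id=atlas.animal_id)


def generate_movie(atlas: GlomerularAtlas, spec: MovieSpec, seed: int = 0,
                   n_glomeruli: int | None = None):
    """Render an atlas as raw intrinsic-imaging stacks with known ROIs.

    Glomeruli are planted as 2-D Gaussian spots at random non-overlapping
    centers; during the odor pulse each spot's intensity drops by
    ``dff_per_z`` per unit of (negative) atlas z-score, emulating the
    reduced-reflectance activation signature.  A spatially broad, slowly
    rising hemodynamic component and white pixel noise can be superimposed.

    Returns ``(movies, labels)``: a float array (odors, frames, H, W) of
    raw intensities and an integer label image where pixel value ``i+1``
    marks glomerulus ``i`` (ROI index ``i`` in the atlas).
    """
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    n_glom = atlas.n_rois if n_glomeruli is None else n_glomeruli
    n_frames = int(round(spec.duration_s * spec.frame_rate))
    t = np.arange(n_frames) / spec.frame_rate

    sigma_px = spec.glom_sigma_um / spec.pixel_size_um
    margin = int(np.ceil(3 * sigma_px)) + 1
    centers = []
    # rejection-sample centers at least 4 sigma apart so masks stay disjoint
    for _ in range(10000):
        if len(centers) == n_glom:
            break
        c = rng.uniform(margin, [h - margin, w - margin])
        if all(np.hypot(*(c - o)) > 4 * sigma_px for o in centers):
            centers.append(c)
    if len(centers) < n_glom:
        raise ValueError("field of view too small for the requested glomeruli")
    centers = np.array(centers)

    yy, xx = np.mgrid[0:h, 0:w]
    spots = np.empty((n_glom, h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    for i, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        spots[i] = np.exp(-d2 / (2 * sigma_px**2))
        labels[d2 <= (2 * sigma_px) ** 2] = i + 1

    odor_on = (t >= spec.odor_onset_s) & (t < spec.odor_onset_s + spec.odor_duration_s)
    movies = np.empty((len(atlas.odors), n_frames, h, w), dtype=float)
    for j in range(len(atlas.odors)):
        z = atlas.mean_z[j, :n_glom]
        dff = np.zeros((n_frames, h, w))
        # activation: intensity drop proportional to |z| during the pulse
        amp_img = np.tensordot(z * spec.dff_per_z, spots, axes=(0, 0))
        dff[odor_on] += amp_img
        if spec.hemodynamic_amplitude:
            ramp = np.clip((t - spec.odor_onset_s) / 3.0, 0.0, 1.0)
            broad = np.exp(-((yy - h / 2) ** 2 + (xx - w / 2) ** 2)
                           / (2 * (spec.hemodynamic_sigma_um / spec.pixel_size_um) ** 2))
            dff += spec.hemodynamic_amplitude * ramp[:, None, None] * broad
        if spec.pixel_noise:
            dff += spec.pixel_noise * rng.standard_normal(dff.shape)
        movies[j] = spec.f0 * (1.0 + dff)
    return movies, labels


def generate_behavior(decoder_performance_by_odor, behavioral_noise_sd: float,
                      n_trials_per_odor: int, seed: int = 0,
                      odors=None) -> pd.DataFrame:
    """Synthetic per-odor go/no-go performance table.

    Each odor's underlying success probability is the supplied decoder
    performance plus Gaussian jitter (clipped to [0, 1]); observed
    performance is a binomial draw over ``n_trials_per_odor`` trials.
    """
    perf = np.asarray(decoder_performance_by_odor, dtype=float)
    if np.any((perf < 0) | (perf > 1)):
        raise ValueError("performances must lie in [0, 1]")
    if n_trials_per_odor < 0:
        raise ValueError("trial count must be non-negative")
    rng = np.random.default_rng(seed)
    p = np.clip(perf + behavioral_noise_sd * rng.standard_normal(perf.size), 0, 1)
    correct = rng.binomial(n_trials_per_odor, p)
    if odors is None:
        odors = [f"odor_{i}" for i in range(perf.size)]
    frac = np.divide(correct, n_trials_per_odor, out=np.zeros(perf.size),
                     where=n_trials_per_odor > 0)
    return pd.DataFrame({"odor": list(odors), "n_trials": n_trials_per_odor,
                         "n_correct": correct, "fraction_correct": frac})
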