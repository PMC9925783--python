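"""Intrinsic-signal imaging quantification.

Pipeline: df/f0 against the mean of a pre-odor baseline window; removal
of the broad hemodynamic component by subtracting a wide Gaussian
low-pass (sigma 40 um); suppression of high-spatial-frequency noise with
a narrow Gaussian (sigma 12 um); per-pixel z-scores using the baseline
mean and s.d. of the filtered signal; ROI quantification as the spatial
mean z over a response window (2-9 s after odor onset); and detection
thresholding that zeroes responses weaker than the noise-derived cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


@dataclass
class ZScoreMovie:
    """Per-pixel z-score stack with its timing metadata."""

    z: np.ndarray  # (frames, H, W)
    frame_rate: float
    odor_onset_s: float
    baseline_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.baseline_s > self.odor_onset_s:
            raise ValueError("baseline window must precede odor onset")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z stack contains non-finite values")


def zscore_movie(raw, frame_rate: float, odor_onset_s: float,
                 *, baseline_s: float = 5.0, pixel_size_um: float = 3.3,
                 wide_sigma_um: float = 40.0, narrow_sigma_um: float = 12.0,
                 var_floor: float | None = None) -> ZScoreMovie:
    """Convert a raw intensity stack to per-pixel z-scores.

    The baseline is the ``baseline_s`` seconds immediately preceding
    ``odor_onset_s``.  Gaussian sigmas are in micrometres and converted to
    pixels via ``pixel_size_um``; filtering uses reflective boundaries.
    Zero-variance baseline pixels get a small variance floor (scaled from
    machine epsilon) instead of producing non-finite z-scores.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3:
        raise ValueError("raw stack must be (frames, H, W)")
    n_frames = raw.shape[0]
    onset_f = int(round(odor_onset_s * frame_rate))
    base_f0 = onset_f - int(round(baseline_s * frame_rate))
    if base_f0 < 0 or onset_f > n_frames:
        raise ValueError("stack too short for the baseline window")
    if onset_f - base_f0 < 2:
        raise ValueError("baseline window must span at least 2 frames")

    f0 = raw[base_f0:onset_f].mean(axis=0)
    f0 = np.where(f0 == 0, 1.0, f0)
    dff = raw / f0 - 1.0

    wide = wide_sigma_um / pixel_size_um
    narrow = narrow_sigma_um / pixel_size_um
    filt = np.empty_like(dff)
    for i in range(n_frames):
        frame = dff[i] - gaussian_filter(dff[i], wide, mode="reflect")
        filt[i] = gaussian_filter(frame, narrow, mode="reflect")

    base = filt[base_f0:onset_f]
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=0)
    floor = np.sqrt(np.finfo(float).eps) if var_floor is None else var_floor
    sd = np.maximum(sd, floor)
    z = (filt - mu) / sd
    return ZScoreMovie(z=z, frame_rate=frame_rate, odor_onset_s=odor_onset_s,
                       baseline_s=baseline_s, pixel_size_um=pixel_size_um)


def quantify_rois(zmovie: ZScoreMovie, roi_labels,
                  response_window: tuple = (2.0, 9.0),
                  odor: str = "odor", repeat: int = 0) -> pd.DataFrame:
    """Mean z per ROI over the response window.

    ``roi_labels`` is an integer label image (0 = background, i = ROI i).
    ``response_window`` is (start, stop) in seconds after odor onset.
    Returns one row per ROI with columns roi, odor, repeat, value.
    """
    labels = np.asarray(roi_labels)
    if labels.shape != zmovie.z.shape[1:]:
        raise ValueError("label image must match the frame shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no ROIs in the label image")
    t0 = int(round((zmovie.odor_onset_s + response_window[0]) * zmovie.frame_rate))
    t1 = int(round((zmovie.odor_onset_s + response_window[1]) * zmovie.frame_rate))
    t1 = min(t1, zmovie.z.shape[0])
    if t1 <= t0:
        raise ValueError("response window outside the movie")
    window_mean = zmovie.z[t0:t1].mean(axis=0)
    rows = [{"roi": int(i) - 1, "odor": odor, "repeat": repeat,
             "value": float(window_mean[labels == i].mean())} for i in ids]
    return pd.DataFrame(rows)


def repeat_average(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a repeat-resolved response table to one mean row per ROI-odor."""
    return (table.groupby(["odor", "roi"], as_index=False)["value"].mean())


def apply_detection_threshold(values, threshold: float):
    """Zero responses weaker than a (negative) z-score threshold.

    Activation is a negative deflection: entries with value > ``threshold``
    are set to exactly 0; entries <= threshold pass unchanged.  Accepts an
    array or a response table with a ``value`` column.  Idempotent.
    """
    if threshold > 0:
        raise ValueError("threshold must be <= 0 (activation is negative)")
    if isinstance(values, pd.DataFrame):
        out = values.copy()
        out["value"] = np.where(out["value"].to_numpy() > threshold, 0.0,
                                out["value"].to_numpy())
        return out
    arr = np.asarray(values, dtype=float)
    return np.where(arr > threshold, 0.0, arr)
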