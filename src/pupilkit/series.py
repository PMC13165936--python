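"""Temporal cleaning of keypoint tracks and derived scalar series.

Three operations used throughout the pipeline live here: a sliding median
filter on keypoint coordinates (window 3, step 1 by default), IQR-based
outlier removal on scalar series (asymmetric 1.5×/3.0× bounds for the
pupil-area series), and gap-limited linear interpolation (gaps of at most
30 frames ≈ 1 s at 30 fps are bridged; longer gaps stay missing).  All
operations preserve series length and never alter present values except
where documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dlc_io import PUPIL_BOUNDARY, TrackTable
from .errors import ConfigError

__all__ = [
    "CleaningConfig",
    "sliding_median_coords",
    "pooled_points_for_frame",
    "remove_area_outliers",
    "interpolate_gaps",
]


@dataclass
class CleaningConfig:
    """Temporal-cleaning parameters (units: frames unless noted).

    ``iqr_low_factor``/``iqr_high_factor`` are the asymmetric bounds of the
    area-series outlier rule ``[Q1 − low·IQR, Q3 + high·IQR]``; the high
    bound is looser because pupil dilation produces legitimate large
    areas while blinks/fit failures produce spuriously small ones.
    ``pool_frames`` switches the ellipse-fit input from smoothed per-frame
    points to the union of raw points across the window (up to 24 markers
    for a 3-frame window).
    """

    smooth_window: int = 3
    smooth_step: int = 1
    iqr_low_factor: float = 1.5
    iqr_high_factor: float = 3.0
    max_gap: int = 30
    pool_frames: bool = False

    def validate(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd and >= 1")
        if self.smooth_step != 1:
            raise ConfigError("only step 1 sliding windows are supported")
        if self.iqr_low_factor <= 0 or self.iqr_high_factor <= 0:
            raise ConfigError("IQR factors must be > 0")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")


def sliding_median_coords(track: TrackTable, window: int = 3) -> TrackTable:
    """Centred sliding-median filter on x and y of every keypoint.

    Missing values are skipped inside the window; a window that is all
    missing stays missing.  At the series edges the window shrinks to the
    available frames.  Likelihood columns are untouched.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError("window must be odd and >= 1")
    out = track.data.copy()
    coord_cols = [c for c in out.columns if c[1] in ("x", "y")]
    sub = out[coord_cols]
    out[coord_cols] = sub.rolling(window, center=True, min_periods=1).median()
    return TrackTable(out, frame_rate=track.frame_rate, scorer=track.scorer)


def pooled_points_for_frame(
    track: TrackTable,
    frame: int,
    window: int = 3,
    bodyparts: tuple[str, ...] = PUPIL_BOUNDARY,
) -> np.ndarray:
    """Union of valid boundary points over the centred window at one frame.

    Returns an (m, 2) array, m ≤ len(bodyparts)·window (24 for the default
    8 keypoints and 3-frame window); missing points are dropped.
    """
    if not 0 <= frame < track.n_frames:
        raise ConfigError(f"frame {frame} outside session (0..{track.n_frames - 1})")
    half = window // 2
    lo = max(0, frame - half)
    hi = min(track.n_frames, frame + half + 1)
    chunks = [track.coords(bp)[lo:hi] for bp in bodyparts]
    pts = np.concatenate(chunks, axis=0)
    return pts[np.isfinite(pts).all(axis=1)]


def remove_area_outliers(
    values,
    low_factor: float = 1.5,
    high_factor: float = 3.0,
) -> np.ndarray:
    """Replace values outside ``[Q1 − low·IQR, Q3 + high·IQR]`` with NaN.

    Quartiles use linear-interpolation quantiles over the non-missing
    values; the bounds are inclusive (only strictly outside values are
    removed).  With fewer than 4 non-missing values the series is returned
    unchanged with a warning.
    """
    v = np.asarray(values, float).copy()
    ok = np.isfinite(v)
    if ok.sum() < 4:
        warnings.warn("fewer than 4 non-missing values; outlier removal skipped")
        return v
    q1, q3 = np.percentile(v[ok], [25, 75])
    iqr = q3 - q1
    lo = q1 - low_factor * iqr
    hi = q3 + high_factor * iqr
    v[ok & ((v < lo) | (v > hi))] = np.nan
    return v


def interpolate_gaps(values, max_gap: int = 30) -> np.ndarray:
    """Linearly fill missing runs of length ≤ ``max_gap``.

    Only runs flanked by present values on both sides are filled; longer
    runs and runs touching the series ends remain missing (no
    extrapolation).  Present values are never altered, and the operation
    is idempotent.
    """
    v = np.asarray(values, float).copy()
    if max_gap < 0:
        raise ConfigError("max_gap must be >= 0")
    isnan = ~np.isfinite(v)
    if not isnan.any() or isnan.all():
        return v
    n = len(v)
    # maximal NaN runs via the boundaries of the mask
    edges = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        run = stop - start
        if run > max_gap or start == 0 or stop == n:
            continue
        left, right = v[start - 1], v[stop]
        t = np.arange(1, run + 1) / (run + 1)
        v[start:stop] = left + t * (right - left)
    return v
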