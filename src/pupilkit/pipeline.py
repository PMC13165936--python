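"""End-to-end processing: keypoint track → calibrated diameter series.

Stage order mirrors the measurement chain: optional likelihood gating →
sliding-median smoothing of keypoint coordinates → per-frame robust
ellipse fit and area (A = πab) → IQR outlier removal on the area series →
gap-limited linear interpolation → reference-length extraction and
cleaning → A/L² normalisation → equivalent-circle diameter in mm.
Per-frame failures never abort a session; they surface as missing values
with a quality flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dlc_io import PUPIL_BOUNDARY, DiameterSeries, TrackTable
from .errors import ConfigError
from .geometry import RobustFitConfig, robust_fit_ellipse
from .scale import ReferenceConfig, clean_reference, diameter_mm, normalize_area, reference_length
from .series import (
    CleaningConfig,
    interpolate_gaps,
    pooled_points_for_frame,
    remove_area_outliers,
    sliding_median_coords,
)
from .stats import ResponseResult, pupillary_response

__all__ = ["PipelineConfig", "process_track", "response_from_series"]


@dataclass
class PipelineConfig:
    """Aggregate configuration for one processing run.

    ``likelihood_filter`` is off by default: long sessions with
    movement artifacts make a fixed confidence threshold impractical, so
    robust fitting and series cleaning carry the outlier burden instead.
    ``baseline_frames``/``stim_frames`` define the default analysis
    windows (30 s and 9 s at 30 frames/s).
    """

    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    fit: RobustFitConfig = field(default_factory=RobustFitConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    baseline_frames: int = 900
    stim_frames: int = 270
    likelihood_filter: float | None = None
    frame_rate: float = 30.0

    def validate(self) -> None:
        self.cleaning.validate()
        self.fit.validate()
        self.reference.validate()
        if self.likelihood_filter is not None and not 0 <= self.likelihood_filter <= 1:
            raise ConfigError("likelihood_filter must lie in [0, 1]")
        if self.baseline_frames < 1 or self.stim_frames < 1:
            raise ConfigError("analysis windows must be at least 1 frame")


def apply_likelihood_filter(track: TrackTable, threshold: float) -> TrackTable:
    """Blank every keypoint observation whose likelihood is below threshold."""
    out = track.copy()
    for bp in out.bodypart_names:
        low = out.likelihood(bp) < threshold
        if low.any():
            out.data.loc[low, (bp, "x")] = np.nan
            out.data.loc[low, (bp, "y")] = np.nan
    return out


def process_track(
    track: TrackTable, config: PipelineConfig | None = None
) -> tuple[DiameterSeries, dict]:
    """Run the full pipeline on one session.

    Returns the per-frame diameter series and a dictionary of per-stage
    counts (frames fitted, outliers removed, gaps filled, frames invalid,
    reference gating bounds) suitable for a run log.
    """
    config = config or PipelineConfig()
    config.validate()
    n = track.n_frames
    counts: dict = {"frames_total": n}

    work = track
    if config.likelihood_filter is not None:
        before = sum(
            int(np.isfinite(work.coords(bp)).all(axis=1).sum()) for bp in work.bodypart_names
        )
        work = apply_likelihood_filter(work, config.likelihood_filter)
        after = sum(
            int(np.isfinite(work.coords(bp)).all(axis=1).sum()) for bp in work.bodypart_names
        )
        counts["likelihood_filtered_points"] = before - after

    area = np.full(n, np.nan)
    n_inliers = np.zeros(n)
    flags = ["ok"] * n
    if config.cleaning.pool_frames:
        for i in range(n):
            pts = pooled_points_for_frame(work, i, config.cleaning.smooth_window)
            res = robust_fit_ellipse(pts, config.fit)
            area[i] = res.area_px2
            n_inliers[i] = res.n_points_used
    else:
        smoothed = sliding_median_coords(work, config.cleaning.smooth_window)
        boundary = np.stack([smoothed.coords(bp) for bp in PUPIL_BOUNDARY], axis=1)
        for i in range(n):
            res = robust_fit_ellipse(boundary[i], config.fit)
            area[i] = res.area_px2
            n_inliers[i] = res.n_points_used
    fitted = np.isfinite(area)
    counts["frames_fitted"] = int(fitted.sum())
    for i in np.flatnonzero(~fitted):
        flags[i] = "no_fit"

    cleaned = remove_area_outliers(
        area, config.cleaning.iqr_low_factor, config.cleaning.iqr_high_factor
    )
    removed = fitted & ~np.isfinite(cleaned)
    counts["area_outliers_removed"] = int(removed.sum())
    for i in np.flatnonzero(removed):
        flags[i] = "area_outlier"

    interp = interpolate_gaps(cleaned, config.cleaning.max_gap)
    filled = np.isfinite(interp) & ~np.isfinite(cleaned)
    counts["gaps_filled_frames"] = int(filled.sum())
    for i in np.flatnonzero(filled):
        flags[i] = "interpolated"

    ref_raw = reference_length(work, config.reference.endpoint_pair)
    ref = clean_reference(ref_raw, config.reference, config.cleaning)
    ref_ok = np.isfinite(ref)
    counts["reference_frames_valid"] = int(ref_ok.sum())

    a_norm = normalize_area(interp, ref, config.reference.min_valid_px)
    diam = diameter_mm(a_norm, config.reference.ref_mm)
    for i in np.flatnonzero(np.isfinite(interp) & ~np.isfinite(a_norm)):
        flags[i] = "no_reference"
    counts["frames_invalid"] = int((~np.isfinite(diam)).sum())

    series = DiameterSeries(
        frame=np.arange(n),
        frame_rate=config.frame_rate,
        area_px2=interp,
        ref_len_px=ref,
        area_norm=a_norm,
        diameter_mm=diam,
        n_inliers=n_inliers,
        quality_flag=flags,
    )
    return series, counts


def response_from_series(
    series: DiameterSeries,
    baseline_window: tuple[int, int] | None = None,
    stim_window: tuple[int, int] | None = None,
    config: PipelineConfig | None = None,
) -> ResponseResult:
    """Pupillary response from a processed series.

    Default windows: the first ``baseline_frames`` frames as baseline and
    the last ``stim_frames`` frames as the maximum-tolerable-intensity
    window.  Averaging happens on the normalised area, then the window
    means are converted to mm.
    """
    config = config or PipelineConfig()
    n = len(series)
    if baseline_window is None:
        baseline_window = (0, min(config.baseline_frames, n))
    if stim_window is None:
        stim_window = (max(0, n - config.stim_frames), n)
    return pupillary_response(
        series.area_norm, baseline_window, stim_window, config.reference.ref_mm
    )
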