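"""Synthetic keypoint sessions with known ground truth.

Emulates what the webcam + pose-estimation front end would deliver: eight
keypoints on an elliptical pupil boundary at 45° spacing, a centre point,
and four reference-marker endpoints whose S2–S4 separation is 8 mm at the
nominal camera scale.  The generator superimposes

* a diameter profile (baseline plus trapezoidal dilation events with a
  linear rise, plateau and linear fall),
* isotropic Gaussian keypoint jitter,
* blinks (all pupil keypoints missing for a short run of frames),
* sporadic gross outlier keypoints displaced in a random direction, and
* a slow sinusoidal drift of the overall camera scale that multiplies
  every coordinate uniformly (head moving toward/away from the camera).

The diameter-to-ellipse mapping preserves area (a·b fixed by the
equivalent-area circle, axis ratio free), so any axis ratio reproduces
the same diameter through the A = πab → D = 2√(A/π) chain.

It does **not** model photorealistic appearance, the pupillary light
reflex, gaze shifts, or non-uniform (out-of-plane) scale changes.

Determinism: one shared generator seeded from the config; draws occur in
a fixed order (pupil noise block, centre noise, reference noise, blink
count/onsets/durations, outlier mask/directions) so identical configs
give bitwise-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dlc_io import PUPIL_BOUNDARY, PUPIL_CENTER, REFERENCE_POINTS, TrackTable, make_track
from .errors import ConfigError, ContractError

__all__ = [
    "DilationEvent",
    "SynthConfig",
    "SessionGroundTruth",
    "diameter_profile",
    "generate_session",
    "ground_truth_response",
    "write_ground_truth_csv",
]


@dataclass(frozen=True)
class DilationEvent:
    """Trapezoidal dilation: linear rise, plateau, linear fall.

    ``amplitude_mm`` is the plateau height above baseline; the rise and
    fall each last ``rise_frames`` and are contained within
    ``duration_frames``.
    """

    onset_frame: int
    duration_frames: int
    amplitude_mm: float
    rise_frames: int = 90


@dataclass
class SynthConfig:
    """Study-condition parameters for one synthetic session.

    Defaults mirror the acquisition geometry the pipeline targets: 30
    frames/s, a ~5.7 mm resting pupil, an 8 mm reference at 20 px/mm
    (160 px), 0.5 px keypoint jitter, ~12 blinks/min of 0.1–0.4 s, 5%
    gross outliers displaced 40 px, and a ±5% slow scale drift over the
    session.
    """

    n_frames: int = 1800
    frame_rate: float = 30.0
    px_per_mm: float = 20.0
    baseline_diameter_mm: float = 5.7
    dilation_events: tuple[DilationEvent, ...] = ()
    ellipse_axis_ratio: float = 0.85
    orientation_rad: float = 0.3
    keypoint_noise_px: float = 0.5
    blink_rate_per_min: float = 12.0
    blink_duration_frames: tuple[int, int] = (3, 12)
    outlier_prob: float = 0.05
    outlier_shift_px: float = 40.0
    scale_drift_amplitude: float = 0.05
    ref_mm: float = 8.0
    pupil_center_px: tuple[float, float] = (320.0, 240.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1 or self.frame_rate <= 0 or self.px_per_mm <= 0:
            raise ConfigError("n_frames, frame_rate and px_per_mm must be positive")
        if not 0 < self.ellipse_axis_ratio <= 1:
            raise ConfigError("ellipse_axis_ratio must lie in (0, 1]")
        if not 0 <= self.outlier_prob < 1:
            raise ConfigError("outlier_prob must lie in [0, 1)")
        if self.keypoint_noise_px < 0 or self.outlier_shift_px < 0:
            raise ConfigError("noise and shift magnitudes must be >= 0")
        if self.blink_duration_frames[0] > self.blink_duration_frames[1]:
            raise ConfigError("blink_duration_frames must be (low, high) with low <= high")


@dataclass
class SessionGroundTruth:
    """True per-frame geometry underlying a generated session."""

    true_diameter_mm: np.ndarray
    true_ref_px: np.ndarray
    center_px: np.ndarray  # (n, 2), drift included
    a_semi_px: np.ndarray
    b_semi_px: np.ndarray
    phi: float
    blink_mask: np.ndarray  # (n,) bool
    outlier_mask: np.ndarray  # (n, 8) bool over P1..P8
    frame_rate: float = 30.0


def diameter_profile(cfg: SynthConfig) -> np.ndarray:
    """True pupil diameter per frame: baseline plus active event profiles."""
    t = np.arange(cfg.n_frames, dtype=float)
    d = np.full(cfg.n_frames, cfg.baseline_diameter_mm)
    for ev in cfg.dilation_events:
        rise = max(ev.rise_frames, 1)
        up = (t - ev.onset_frame) / rise
        down = (ev.onset_frame + ev.duration_frames - t) / rise
        shape = np.clip(np.minimum(np.minimum(up, down), 1.0), 0.0, None)
        d = d + ev.amplitude_mm * shape
    return d


def _event_truth_arrays(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.n_frames
    drift = cfg.scale_drift_amplitude * np.sin(
        2.0 * np.pi * np.arange(n, dtype=float) / max(n, 1)
    )
    return diameter_profile(cfg), 1.0 + drift


def generate_session(cfg: SynthConfig) -> tuple[TrackTable, SessionGroundTruth]:
    """Generate one session; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    diam_mm, scale = _event_truth_arrays(cfg)

    # true ellipse (area-preserving): a·b = (D·ppm·scale/2)², b/a = ratio
    r_eq = diam_mm * cfg.px_per_mm * scale / 2.0  # equivalent-circle radius, px
    a_semi = r_eq / np.sqrt(cfg.ellipse_axis_ratio)
    b_semi = r_eq * np.sqrt(cfg.ellipse_axis_ratio)
    center = np.asarray(cfg.pupil_center_px, float)[None, :] * scale[:, None]

    # ideal keypoint geometry
    angles = np.deg2rad(np.arange(8) * 45.0)
    ca, sa = np.cos(cfg.orientation_rad), np.sin(cfg.orientation_rad)
    ex = a_semi[:, None] * np.cos(angles)[None, :]
    ey = b_semi[:, None] * np.sin(angles)[None, :]
    px = center[:, 0][:, None] + ca * ex - sa * ey
    py = center[:, 1][:, None] + sa * ex + ca * ey

    half_mm = cfg.ref_mm / 2.0 * cfg.px_per_mm
    cx, cy = cfg.pupil_center_px
    ref_ideal = np.array(
        [  # S1/S3 upper line, S2/S4 lower line; |S2 − S4| = ref_mm·px_per_mm
            [cx - half_mm, cy + 150.0],
            [cx - half_mm, cy + 160.0],
            [cx + half_mm, cy + 150.0],
            [cx + half_mm, cy + 160.0],
        ]
    )
    ref = ref_ideal[None, :, :] * scale[:, None, None]  # (n, 4, 2)

    # draw order is fixed: pupil noise, centre noise, reference noise,
    # blinks, outliers
    noise_p = rng.standard_normal((n, 8, 2)) * cfg.keypoint_noise_px
    noise_c = rng.standard_normal((n, 2)) * cfg.keypoint_noise_px
    noise_s = rng.standard_normal((n, 4, 2)) * cfg.keypoint_noise_px

    minutes = n / cfg.frame_rate / 60.0
    n_blinks = rng.poisson(cfg.blink_rate_per_min * minutes)
    blink_mask = np.zeros(n, bool)
    if n_blinks > 0:
        onsets = rng.integers(0, n, n_blinks)
        lo, hi = cfg.blink_duration_frames
        durations = rng.integers(lo, hi + 1, n_blinks)
        for o, dur in zip(onsets, durations):
            blink_mask[o : min(n, o + dur)] = True

    outlier_mask = rng.random((n, 8)) < cfg.outlier_prob
    outlier_mask &= ~blink_mask[:, None]
    directions = rng.uniform(0.0, 2.0 * np.pi, (n, 8))

    px = px + noise_p[:, :, 0]
    py = py + noise_p[:, :, 1]
    px = np.where(outlier_mask, px + cfg.outlier_shift_px * np.cos(directions), px)
    py = np.where(outlier_mask, py + cfg.outlier_shift_px * np.sin(directions), py)

    lk_p = np.ones((n, 8))
    lk_p[outlier_mask] = 0.1
    cxy = center + noise_c
    lk_c = np.ones(n)

    px[blink_mask] = np.nan
    py[blink_mask] = np.nan
    lk_p[blink_mask] = 0.05
    cxy[blink_mask] = np.nan
    lk_c[blink_mask] = 0.05

    coords = {}
    likelihood = {}
    for i, bp in enumerate(PUPIL_BOUNDARY):
        coords[bp] = np.column_stack([px[:, i], py[:, i]])
        likelihood[bp] = lk_p[:, i]
    coords[PUPIL_CENTER] = cxy
    likelihood[PUPIL_CENTER] = lk_c
    for i, bp in enumerate(REFERENCE_POINTS):
        coords[bp] = ref[:, i, :] + noise_s[:, i, :]
        likelihood[bp] = np.ones(n)

    track = make_track(coords, likelihood, frame_rate=cfg.frame_rate, scorer="synthetic")
    truth = SessionGroundTruth(
        true_diameter_mm=diam_mm,
        true_ref_px=cfg.ref_mm * cfg.px_per_mm * scale,
        center_px=center,
        a_semi_px=a_semi,
        b_semi_px=b_semi,
        phi=cfg.orientation_rad,
        blink_mask=blink_mask,
        outlier_mask=outlier_mask,
        frame_rate=cfg.frame_rate,
    )
    return track, truth


def ground_truth_response(
    truth: SessionGroundTruth,
    baseline_window: tuple[int, int],
    stim_window: tuple[int, int],
) -> float:
    """True pupillary response: difference of window means of the true
    diameter (mm)."""
    n = len(truth.true_diameter_mm)
    for name, (start, stop) in (("baseline", baseline_window), ("stim", stim_window)):
        if not (0 <= start < stop <= n):
            raise ContractError(f"{name} window ({start}, {stop}) outside session of {n} frames")
    base = truth.true_diameter_mm[slice(*baseline_window)].mean()
    stim = truth.true_diameter_mm[slice(*stim_window)].mean()
    return float(stim - base)


def write_ground_truth_csv(truth: SessionGroundTruth, path) -> None:
    """Flat per-frame ground-truth table for downstream comparisons."""
    pd.DataFrame(
        {
            "frame": np.arange(len(truth.true_diameter_mm)),
            "true_diameter_mm": truth.true_diameter_mm,
            "true_ref_px": truth.true_ref_px,
            "blink": truth.blink_mask.astype(int),
            "outlier_count": truth.outlier_mask.sum(axis=1),
        }
    ).to_csv(path, index=False)
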