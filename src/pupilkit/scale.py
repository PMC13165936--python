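"""Reference-marker scale normalisation and mm conversion.

A sticker on the skin carries two endpoints a known 8 mm apart (keypoints
S2 and S4 by default).  The per-frame Euclidean distance L between them
tracks the instantaneous camera scale; dividing the pupil area A (px²) by
L² yields a dimensionless normalised area A_norm that cancels uniform
scale changes (head moving toward/away from the camera).  The absolute
pupil diameter follows as the equivalent-area circle,

    D = ref_mm · 2·√(A_norm / π)   [mm].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dlc_io import TrackTable
from .errors import ConfigError, ContractError
from .series import CleaningConfig, interpolate_gaps, remove_area_outliers

__all__ = [
    "ReferenceConfig",
    "reference_length",
    "clean_reference",
    "normalize_area",
    "diameter_mm",
]


@dataclass
class ReferenceConfig:
    """Reference-marker parameters.

    ``min_px``/``max_px`` gate implausible lengths; when None they default
    to ±50% around the session median (logged by the pipeline).
    ``min_valid_px`` guards the A/L² division against near-zero lengths.
    ``ref_iqr_factor`` is the symmetric outlier bound used when cleaning
    the length series (distinct from the asymmetric area rule).
    """

    endpoint_pair: tuple[str, str] = ("S2", "S4")
    min_px: float | None = None
    max_px: float | None = None
    min_valid_px: float = 1e-6
    ref_mm: float = 8.0
    ref_iqr_factor: float = 1.5

    def validate(self) -> None:
        if self.min_px is not None and self.max_px is not None and not self.min_px < self.max_px:
            raise ConfigError("min_px must be < max_px")
        if self.ref_mm <= 0:
            raise ConfigError("ref_mm must be > 0")
        if self.ref_iqr_factor <= 0:
            raise ConfigError("ref_iqr_factor must be > 0")


def reference_length(track: TrackTable, pair: tuple[str, str] = ("S2", "S4")) -> np.ndarray:
    """Frame-by-frame Euclidean distance between the two endpoints (px).

    Missing whenever either endpoint is missing that frame.
    """
    p = track.coords(pair[0])
    q = track.coords(pair[1])
    return np.hypot(p[:, 0] - q[:, 0], p[:, 1] - q[:, 1])


def clean_reference(
    series,
    cfg: ReferenceConfig | None = None,
    cleaning: CleaningConfig | None = None,
) -> np.ndarray:
    """Clean a reference-length series in three stages.

    (1) manual plausibility gating to [min_px, max_px] (defaults: ±50%
    around the median of the raw series); (2) symmetric IQR outlier
    removal; (3) gap-limited linear interpolation.  Stages reuse the
    generic series operations.
    """
    cfg = cfg or ReferenceConfig()
    cleaning = cleaning or CleaningConfig()
    cfg.validate()
    v = np.asarray(series, float).copy()
    ok = np.isfinite(v)
    if ok.any():
        med = float(np.median(v[ok]))
        lo = cfg.min_px if cfg.min_px is not None else 0.5 * med
        hi = cfg.max_px if cfg.max_px is not None else 1.5 * med
        v[ok & ((v < lo) | (v > hi))] = np.nan
    v = remove_area_outliers(v, cfg.ref_iqr_factor, cfg.ref_iqr_factor)
    return interpolate_gaps(v, cleaning.max_gap)


def normalize_area(area, ref_len, min_valid_px: float = 1e-6) -> np.ndarray:
    """Dimensionless normalised area A/L² per frame.

    Defined only where both inputs are present and L exceeds the
    ``min_valid_px`` guard; missing elsewhere.
    """
    a = np.asarray(area, float)
    l = np.asarray(ref_len, float)
    if a.shape != l.shape:
        raise ContractError(f"length mismatch: area {a.shape} vs reference {l.shape}")
    out = np.full(a.shape, np.nan)
    ok = np.isfinite(a) & np.isfinite(l) & (l > min_valid_px)
    out[ok] = a[ok] / (l[ok] * l[ok])
    return out


def diameter_mm(a_norm, ref_mm: float = 8.0):
    """Absolute pupil diameter D = ref_mm·2·√(A_norm/π) in millimetres.

    Accepts scalars or arrays; missing values propagate, but a present
    negative normalised area is a contract violation.
    """
    a = np.asarray(a_norm, float)
    if np.any(a[np.isfinite(a)] < 0):
        raise ContractError("normalised area must be >= 0")
    with np.errstate(invalid="ignore"):
        d = ref_mm * 2.0 * np.sqrt(a / np.pi)
    return float(d) if np.isscalar(a_norm) else d
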