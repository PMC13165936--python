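"""Reading and writing keypoint tracks and tidy diameter tables.

The input dialect is the single-animal pose-estimation CSV: three header
rows labelled ``scorer`` / ``bodyparts`` / ``coords``, one leading column of
frame indices, and per bodypart a triplet of ``x``, ``y``, ``likelihood``
columns.  Coordinates are image pixels with the origin at the top-left
corner and y increasing downward; empty cells encode missing observations
(occlusion, blinks).  Frame indices are re-based to start at 0.

Output is a flat per-frame diameter table (one row per video frame) with
missing values serialised as empty cells.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, FormatError, ParseError

#: Pupil-boundary keypoints, placed at 45° intervals around the perimeter.
PUPIL_BOUNDARY = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")
#: Pupil-centre keypoint (tracked but unused downstream).
PUPIL_CENTER = "P9"
#: Reference-marker endpoint keypoints on the skin sticker.
REFERENCE_POINTS = ("S1", "S2", "S3", "S4")

COORD_LEVELS = ("x", "y", "likelihood")

_HEADER_LABELS = ("scorer", "bodyparts", "coords")


@dataclass
class TrackTable:
    """Per-frame, per-bodypart (x, y, likelihood) records for one session.

    ``data`` is a DataFrame indexed by contiguous 0-based frame numbers with
    a two-level column index ``(bodypart, coord)`` where coord is one of
    ``x``, ``y``, ``likelihood``.  Missing observations are NaN; the
    likelihood of a missing record is treated as 0 wherever it is consumed.
    """

    data: pd.DataFrame
    frame_rate: float = 30.0
    scorer: str = "pupilkit"

    @property
    def bodypart_names(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def coords(self, bodypart: str) -> np.ndarray:
        """(n_frames, 2) array of x, y for one bodypart (NaN = missing)."""
        if bodypart not in self.bodypart_names:
            raise ConfigError(f"unknown bodypart {bodypart!r}")
        return self.data[bodypart][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, bodypart: str) -> np.ndarray:
        if bodypart not in self.bodypart_names:
            raise ConfigError(f"unknown bodypart {bodypart!r}")
        lk = self.data[bodypart]["likelihood"].to_numpy(dtype=float)
        return np.where(np.isfinite(lk), lk, 0.0)

    def copy(self) -> "TrackTable":
        return TrackTable(self.data.copy(), self.frame_rate, self.scorer)


def make_track(
    coords: dict[str, np.ndarray],
    likelihood: dict[str, np.ndarray] | None = None,
    frame_rate: float = 30.0,
    scorer: str = "pupilkit",
) -> TrackTable:
    """Assemble a TrackTable from per-bodypart (n, 2) coordinate arrays."""
    cols = {}
    n = None
    for bp, xy in coords.items():
        xy = np.asarray(xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ConfigError(f"coords for {bp!r} must be (n, 2)")
        if n is None:
            n = len(xy)
        elif len(xy) != n:
            raise ConfigError("all bodyparts must have the same frame count")
        lk = None if likelihood is None else likelihood.get(bp)
        if lk is None:
            lk = np.where(np.isfinite(xy).all(axis=1), 1.0, 0.0)
        cols[(bp, "x")] = xy[:, 0]
        cols[(bp, "y")] = xy[:, 1]
        cols[(bp, "likelihood")] = np.asarray(lk, dtype=float)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    return TrackTable(df, frame_rate=frame_rate, scorer=scorer)


def read_dlc_csv(path, frame_rate: float = 30.0) -> TrackTable:
    """Parse a single-animal keypoint CSV into a :class:`TrackTable`.

    Raises :class:`FormatError` on a malformed header or duplicate frame
    index and :class:`ParseError` (with row and column named) on a
    non-numeric cell.  Empty cells become NaN; bodypart order is preserved.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    if len(lines) < 4:
        raise FormatError(f"{path}: expected 3 header rows plus data rows")
    labels = [ln.split(",", 1)[0].strip() for ln in lines[:3]]
    if tuple(labels) != _HEADER_LABELS:
        raise FormatError(
            f"{path}: expected header rows labelled {_HEADER_LABELS}, got {tuple(labels)}"
        )
    df = pd.read_csv(io.StringIO(text), header=[0, 1, 2], index_col=0, dtype=str)
    scorer_level = df.columns.get_level_values(0)
    scorer = scorer_level[0] if len(scorer_level) else "unknown"
    df.columns = pd.MultiIndex.from_arrays(
        [df.columns.get_level_values(1), df.columns.get_level_values(2)],
        names=["bodyparts", "coords"],
    )
    # each bodypart must declare exactly the x / y / likelihood triplet
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(0)))
    for bp in bodyparts:
        have = tuple(df[bp].columns)
        if have != COORD_LEVELS:
            missing = [c for c in COORD_LEVELS if c not in have]
            raise FormatError(
                f"bodypart {bp!r}: coords row declares {have}, missing {missing}"
            )
    # numeric conversion: exact (round-trip) float parsing with
    # cell-accurate error reporting
    out = {}
    for col in df.columns:
        raw = df[col]
        values = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw.to_numpy()):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                values[i] = np.nan
                continue
            try:
                values[i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell at frame row {raw.index[i]!r}, "
                    f"column {col[0]}/{col[1]}"
                ) from None
        out[col] = values
    idx_raw = pd.to_numeric(pd.Series(df.index), errors="coerce")
    if idx_raw.isna().any():
        raise ParseError("non-integer frame index")
    idx = idx_raw.to_numpy()
    if np.any(idx != np.round(idx)):
        raise ParseError("non-integer frame index")
    idx = idx.astype(int)
    if len(np.unique(idx)) != len(idx):
        dup = idx[pd.Series(idx).duplicated().to_numpy()][0]
        raise FormatError(f"duplicate frame index {dup}")
    if np.any(np.diff(idx) <= 0):
        raise FormatError("frame indices must be strictly increasing")
    if np.any(np.diff(idx) != 1):
        raise FormatError("frame indices must be contiguous")
    clean = pd.DataFrame(out)
    clean.columns = pd.MultiIndex.from_tuples(clean.columns, names=["bodyparts", "coords"])
    clean.index = pd.RangeIndex(len(clean))  # re-base to 0
    return TrackTable(clean, frame_rate=frame_rate, scorer=str(scorer))


def write_dlc_csv(track: TrackTable, path) -> None:
    """Write a TrackTable in the three-header-row CSV dialect.

    Coordinates are serialised at full precision so write→read round-trips
    bit-exactly.
    """
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_arrays(
        [
            [track.scorer] * df.shape[1],
            df.columns.get_level_values(0),
            df.columns.get_level_values(1),
        ],
        names=list(_HEADER_LABELS),
    )
    df.index.name = None
    # shortest round-trip formatting so read-back is bit-exact
    df.to_csv(path, float_format=lambda v: repr(float(v)))


@dataclass
class DiameterSeries:
    """Per-frame pupil metrics produced by the processing pipeline.

    All arrays share the session length; NaN marks frames where the
    quantity could not be computed.  ``quality_flag`` is a short per-frame
    label (``ok``, ``interpolated``, ``no_fit``, ``area_outlier``,
    ``no_reference``).
    """

    frame: np.ndarray
    frame_rate: float
    area_px2: np.ndarray
    ref_len_px: np.ndarray
    area_norm: np.ndarray
    diameter_mm: np.ndarray
    n_inliers: np.ndarray
    quality_flag: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def time_s(self) -> np.ndarray:
        return self.frame / self.frame_rate

    def to_frame(self) -> pd.DataFrame:
        n_inl = pd.array(
            [int(v) if np.isfinite(v) else None for v in np.asarray(self.n_inliers, float)],
            dtype="Int64",
        )
        return pd.DataFrame(
            {
                "frame": self.frame.astype(int),
                "time_s": self.time_s,
                "area_px2": self.area_px2,
                "ref_len_px": self.ref_len_px,
                "area_norm": self.area_norm,
                "diameter_mm": self.diameter_mm,
                "n_inliers": n_inl,
                "quality_flag": self.quality_flag,
            }
        )


def write_diameter_csv(series: DiameterSeries, path) -> None:
    """Write the flat diameter table; missing values become empty cells."""
    if len(series) == 0:
        raise ContractError("diameter series is empty")
    series.to_frame().to_csv(path, index=False)


def read_diameter_csv(path, frame_rate: float | None = None) -> DiameterSeries:
    """Read a diameter table written by :func:`write_diameter_csv`."""
    df = pd.read_csv(path)
    required = {"frame", "time_s", "area_px2", "ref_len_px", "area_norm", "diameter_mm"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if frame_rate is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = df["frame"].to_numpy(float)[1:] / df["time_s"].to_numpy(float)[1:]
        frame_rate = float(np.nanmedian(rates)) if len(rates) else 30.0
    flags = df.get("quality_flag")
    n_inl = df.get("n_inliers")
    return DiameterSeries(
        frame=df["frame"].to_numpy(int),
        frame_rate=float(frame_rate),
        area_px2=df["area_px2"].to_numpy(float),
        ref_len_px=df["ref_len_px"].to_numpy(float),
        area_norm=df["area_norm"].to_numpy(float),
        diameter_mm=df["diameter_mm"].to_numpy(float),
        n_inliers=(
            n_inl.to_numpy(float) if n_inl is not None else np.full(len(df), np.nan)
        ),
        quality_flag=(
            [str(v) if pd.notna(v) else "" for v in flags] if flags is not None else [""] * len(df)
        ),
    )
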