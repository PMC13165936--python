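"""Robust ellipse fitting to pupil-boundary keypoints.

The pupil boundary is reconstructed per frame by a two-stage procedure:

1. an algebraic conic least-squares fit (``ax² + bxy + cy² + dx + ey + f =
   0``) to all valid keypoints, solved by singular value decomposition;
2. outlier rejection on the orthogonal point-to-ellipse distances — a
   point is excluded when its distance exceeds ``median + k·IQR`` of the
   distance set, or exceeds ``α·a₀`` where ``a₀`` is the initial
   semi-major axis — followed by a refit on the inliers.

A minimum of 5 keypoints is required at every stage; frames that cannot
produce a valid ellipse yield an *invalid* result value rather than an
exception, so a bad frame never aborts a session.  Pupil area is
``A = π·a·b`` from the refined semi-axes.

Numerical note: before the SVD the points are canonically normalised
(centroid at the origin, root-mean-square radius √2).  This conditions the
design matrix and makes the fit exactly equivariant under similarity
transforms, which the downstream pixel→mm normalisation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateInputError, NonEllipseError

__all__ = [
    "ConicCoefficients",
    "EllipseGeometry",
    "RobustFitConfig",
    "RobustFitResult",
    "fit_conic_lsq",
    "conic_to_ellipse",
    "ellipse_to_conic",
    "point_ellipse_distance",
    "ellipse_distances",
    "robust_fit_ellipse",
]


@dataclass(frozen=True)
class ConicCoefficients:
    """Unit-norm coefficients of ``ax² + bxy + cy² + dx + ey + f = 0``."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f], float)

    @property
    def is_ellipse(self) -> bool:
        return self.b * self.b - 4.0 * self.a * self.c < 0.0

    def evaluate(self, x, y):
        """Algebraic residual Q(x, y) of the conic at the given points."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            self.a * x * x + self.b * x * y + self.c * y * y
            + self.d * x + self.e * y + self.f
        )


@dataclass(frozen=True)
class EllipseGeometry:
    """Centre, semi-axes (a ≥ b > 0, pixels) and orientation φ ∈ [0, π)."""

    xc: float
    yc: float
    a_semi: float
    b_semi: float
    phi: float

    @property
    def area(self) -> float:
        """Area A = π·a·b in squared pixels."""
        return float(np.pi * self.a_semi * self.b_semi)


@dataclass
class RobustFitConfig:
    """Tuning knobs for the two-stage robust fit.

    ``k_iqr`` is the multiplier in the median + k·IQR distance threshold
    (the conventional 1.5 by default), ``alpha`` the absolute-threshold
    factor relative to the initial semi-major axis, ``min_points`` the
    minimum number of keypoints for a valid ellipse.  ``distance_metric``
    selects the geometric orthogonal distance (default) or the absolute
    algebraic residual of the unit-norm conic.
    """

    k_iqr: float = 1.5
    alpha: float = 0.1
    min_points: int = 5
    distance_metric: str = "geometric"
    initial_fit: str = "lmeds"

    def validate(self) -> None:
        if not self.k_iqr > 0:
            raise ConfigError("k_iqr must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.min_points < 5:
            raise ConfigError("min_points must be >= 5")
        if self.distance_metric not in ("geometric", "algebraic"):
            raise ConfigError("distance_metric must be 'geometric' or 'algebraic'")
        if self.initial_fit not in ("lmeds", "plain"):
            raise ConfigError("initial_fit must be 'lmeds' or 'plain'")


@dataclass
class RobustFitResult:
    """Outcome of :func:`robust_fit_ellipse` for one frame.

    ``ellipse`` is None and ``area_px2`` NaN when no valid ellipse could be
    produced.  ``inlier_flags`` is aligned with the input point list
    (non-finite input points are flagged False).
    """

    ellipse: EllipseGeometry | None
    inlier_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    area_px2: float = np.nan
    n_points_used: int = 0

    @property
    def valid(self) -> bool:
        return self.ellipse is not None


def _normalise_conic(v: np.ndarray) -> np.ndarray:
    v = v / np.linalg.norm(v)
    # fix the sign so the x² coefficient is non-negative (first non-zero
    # coefficient decides if a == 0)
    for coef in v:
        if coef != 0.0:
            if coef < 0.0:
                v = -v
            break
    return v


def _conic_svd(u: np.ndarray) -> np.ndarray:
    """Unit-norm conic through already-normalised points via SVD.

    Minimises ‖M·v‖ over ‖v‖ = 1 where the rows of M are the monomials
    (x², xy, y², x, y, 1).  Raises for a rank-deficient design.
    """
    x, y = u[:, 0], u[:, 1]
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    # full_matrices so the exact null direction is available when n == 5
    _, sv, vt = np.linalg.svd(design, full_matrices=True)
    sv6 = np.concatenate([sv, np.zeros(6 - len(sv))])
    if sv6[4] <= 1e-10 * sv6[0]:
        raise DegenerateInputError("degenerate point configuration (collinear?)")
    return vt[-1]


def _canonical_frame(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Centroid and isotropic scale mapping points to RMS radius √2."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean())
    if rms <= 0:
        raise DegenerateInputError("all points coincide")
    return centroid, rms / np.sqrt(2.0)


def _denormalise_conic(v: np.ndarray, centroid: np.ndarray, s: float) -> np.ndarray:
    """Map a conic in u = (p − centroid)/s coordinates back to pixels."""
    va, vb, vc, vd, ve, vf = v
    tx, ty = centroid
    a = va / s**2
    b = vb / s**2
    c = vc / s**2
    d = -2 * va * tx / s**2 - vb * ty / s**2 + vd / s
    e = -vb * tx / s**2 - 2 * vc * ty / s**2 + ve / s
    f = (
        va * tx**2 / s**2 + vb * tx * ty / s**2 + vc * ty**2 / s**2
        - vd * tx / s - ve * ty / s + vf
    )
    return np.array([a, b, c, d, e, f])


def fit_conic_lsq(points) -> ConicCoefficients:
    """Algebraic least-squares conic through ≥ 5 points via SVD.

    The points are canonically normalised (centroid at the origin, RMS
    radius √2) before building the design matrix, and the conic is mapped
    back afterwards; this conditions the problem and makes the fit
    exactly equivariant under similarity transforms.  Raises
    :class:`DegenerateInputError` for fewer than 5 distinct points or a
    rank-deficient design (collinear points).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateInputError("points must be an (n, 2) array")
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(np.unique(pts, axis=0)) < 5:
        raise DegenerateInputError("need at least 5 distinct points")
    centroid, s = _canonical_frame(pts)
    v = _conic_svd((pts - centroid) / s)
    coefs = _normalise_conic(_denormalise_conic(v, centroid, s))
    return ConicCoefficients(*coefs)


def conic_to_ellipse(conic: ConicCoefficients) -> EllipseGeometry:
    """Closed-form conversion from conic coefficients to ellipse geometry.

    Raises :class:`NonEllipseError` when the conic is a parabola,
    hyperbola or degenerate — callers mark the frame invalid instead of
    aborting.
    """
    a, b, c, d, e, f = conic.as_array()
    disc = b * b - 4.0 * a * c
    if not disc < 0.0:
        raise NonEllipseError(f"conic is not an ellipse (b² − 4ac = {disc:g})")
    # centre solves the gradient system [2a b; b 2c]·(xc, yc) = (−d, −e)
    m = np.array([[2.0 * a, b], [b, 2.0 * c]])
    xc, yc = np.linalg.solve(m, [-d, -e])
    f0 = conic.evaluate(xc, yc)
    quad = np.array([[a, b / 2.0], [b / 2.0, c]])
    eigval, eigvec = np.linalg.eigh(quad)
    axes2 = -f0 / eigval
    if np.any(axes2 <= 0) or not np.all(np.isfinite(axes2)):
        raise NonEllipseError("degenerate or imaginary ellipse")
    semi = np.sqrt(axes2)
    major = int(np.argmax(semi))
    minor = 1 - major
    phi = float(np.arctan2(eigvec[1, major], eigvec[0, major])) % np.pi
    return EllipseGeometry(
        xc=float(xc),
        yc=float(yc),
        a_semi=float(semi[major]),
        b_semi=float(semi[minor]),
        phi=phi,
    )


def ellipse_to_conic(ellipse: EllipseGeometry) -> ConicCoefficients:
    """Expand the rotated-ellipse equation into unit-norm conic form."""
    ca, sa = np.cos(ellipse.phi), np.sin(ellipse.phi)
    a2, b2 = ellipse.a_semi**2, ellipse.b_semi**2
    A = ca * ca / a2 + sa * sa / b2
    B = 2.0 * ca * sa * (1.0 / a2 - 1.0 / b2)
    C = sa * sa / a2 + ca * ca / b2
    xc, yc = ellipse.xc, ellipse.yc
    D = -2.0 * A * xc - B * yc
    E = -B * xc - 2.0 * C * yc
    F = A * xc * xc + B * xc * yc + C * yc * yc - 1.0
    return ConicCoefficients(*_normalise_conic(np.array([A, B, C, D, E, F])))


def ellipse_distances(points, ellipse: EllipseGeometry) -> np.ndarray:
    """Orthogonal (Euclidean) distances from points to the ellipse boundary.

    Works in the ellipse frame, folds each point into the first quadrant
    and solves the foot-point condition
    ``(a² − b²)·cosθ·sinθ − x·a·sinθ + y·b·cosθ = 0`` on [0, π/2] with a
    bisection-safeguarded Newton iteration (the root is unique for
    interior-quadrant points because the equation divided by sinθ·cosθ is
    strictly decreasing).  Candidate distances at both axis endpoints are
    also evaluated so on-axis feet are handled exactly.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    a, b = ellipse.a_semi, ellipse.b_semi
    ca, sa = np.cos(ellipse.phi), np.sin(ellipse.phi)
    dx = pts[:, 0] - ellipse.xc
    dy = pts[:, 1] - ellipse.yc
    x = np.abs(ca * dx + sa * dy)
    y = np.abs(-sa * dx + ca * dy)
    out = np.full(len(pts), np.nan)
    finite = np.isfinite(x) & np.isfinite(y)
    if a - b <= 1e-12 * a:  # circle: radial distance
        r = np.hypot(x, y)
        out[finite] = np.abs(r - a)[finite]
        return out if np.asarray(points).ndim == 2 else out[0]
    xf, yf = x[finite], y[finite]
    ab2 = a * a - b * b

    def g(theta):
        st, ct = np.sin(theta), np.cos(theta)
        return ab2 * ct * st - xf * a * st + yf * b * ct

    lo = np.zeros_like(xf)
    hi = np.full_like(xf, np.pi / 2.0)
    theta = np.arctan2(a * yf, b * xf)  # polar-angle initialisation
    for _ in range(60):
        gt = g(theta)
        pos = gt > 0
        lo = np.where(pos, theta, lo)
        hi = np.where(pos, hi, theta)
        st, ct = np.sin(theta), np.cos(theta)
        gp = ab2 * (ct * ct - st * st) - xf * a * ct - yf * b * st
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(gp) > 1e-300, gt / gp, 0.0)
        cand = theta - step
        inside = (cand > lo) & (cand < hi) & np.isfinite(cand)
        theta = np.where(inside, cand, 0.5 * (lo + hi))
        if np.all(hi - lo < 1e-14):
            break

    def dist_at(theta):
        return np.hypot(xf - a * np.cos(theta), yf - b * np.sin(theta))

    d = np.minimum(dist_at(theta), np.minimum(dist_at(lo * 0.0), dist_at(hi * 0.0 + np.pi / 2.0)))
    out[finite] = d
    return out if np.asarray(points).ndim == 2 else out[0]


def point_ellipse_distance(point, ellipse: EllipseGeometry) -> float:
    """Scalar orthogonal distance from one point to the ellipse boundary."""
    return float(ellipse_distances(np.asarray(point, float)[None, :], ellipse)[0])


def _distances(points: np.ndarray, ellipse: EllipseGeometry, metric: str) -> np.ndarray:
    if metric == "geometric":
        return ellipse_distances(points, ellipse)
    conic = ellipse_to_conic(ellipse)
    return np.abs(conic.evaluate(points[:, 0], points[:, 1]))


def _lmeds_initial_conic(pts: np.ndarray) -> ConicCoefficients:
    """Initial conic by exhaustive least-median-of-squares subset search.

    The plain algebraic fit has no resistance to gross keypoint outliers:
    with 6 free coefficients it bends toward a displaced point until the
    point's residual is *smaller* than those of boundary points, after
    which no residual threshold can isolate it.  With at most ~10
    boundary points per frame an exhaustive search is affordable instead:
    candidate conics are least-squares fits to the full set and to every
    subset obtained by dropping one or two points (never below 5), all
    computed in one shared canonical frame so candidate residuals are
    directly comparable (and rankings invariant under similarity
    transforms of the input).  The candidate minimising the median
    absolute algebraic residual over all points wins; ties keep the
    earliest candidate, so clean data reproduce the full-set fit exactly.
    """
    n = len(pts)
    centroid, s = _canonical_frame(pts)
    u = (pts - centroid) / s
    monomials = np.column_stack(
        [u[:, 0] ** 2, u[:, 0] * u[:, 1], u[:, 1] ** 2, u[:, 0], u[:, 1], np.ones(n)]
    )
    groups: list[np.ndarray] = [np.arange(n)[None, :]]
    if n - 1 >= 5:
        groups.append(np.stack([np.delete(np.arange(n), i) for i in range(n)]))
    if n - 2 >= 5:
        groups.append(
            np.stack(
                [
                    np.delete(np.arange(n), [i, j])
                    for i in range(n)
                    for j in range(i + 1, n)
                ]
            )
        )
    best_v = None
    best_med = np.inf
    for idx in groups:  # batched SVD per subset size
        designs = monomials[idx]  # (n_subsets, subset_size, 6)
        sv, vt = np.linalg.svd(designs, full_matrices=True)[1:]
        vs = vt[:, -1, :]
        sv6 = np.zeros((len(idx), 6))
        sv6[:, : sv.shape[1]] = sv
        ok = sv6[:, 4] > 1e-10 * sv6[:, 0]
        ok &= vs[:, 1] ** 2 - 4.0 * vs[:, 0] * vs[:, 2] < 0  # elliptical only
        if not ok.any():
            continue
        meds = np.full(len(idx), np.inf)
        meds[ok] = np.median(np.abs(monomials @ vs[ok].T), axis=0)
        j = int(np.argmin(meds))
        if meds[j] < best_med:
            best_med = meds[j]
            best_v = vs[j]
    if best_v is None:
        raise DegenerateInputError("no valid conic through any candidate subset")
    return ConicCoefficients(*_normalise_conic(_denormalise_conic(best_v, centroid, s)))


def robust_fit_ellipse(points, config: RobustFitConfig | None = None) -> RobustFitResult:
    """Two-stage robust ellipse fit: fit, reject outliers, refit.

    The initial ellipse comes from the least-median-of-squares subset
    search (or a plain least-squares fit with ``initial_fit='plain'``).
    Outliers are points whose distance to the initial ellipse strictly
    exceeds ``median + k_iqr·IQR`` of the distances (interpolation
    quantiles) or strictly exceeds ``alpha·a₀`` with a₀ the initial
    semi-major axis.  The refit on the inliers is a plain least-squares
    fit.  Any stage with fewer than ``min_points`` usable points, or a
    non-elliptical fit, produces an invalid result value (never an
    exception).
    """
    if config is None:
        config = RobustFitConfig()
    config.validate()
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        pts = pts.reshape(0, 2)
    finite = np.isfinite(pts).all(axis=1)
    flags = np.zeros(len(pts), bool)
    invalid = RobustFitResult(None, flags, np.nan, 0)
    if finite.sum() < config.min_points:
        return invalid
    valid_pts = pts[finite]
    try:
        if config.initial_fit == "lmeds":
            initial = conic_to_ellipse(_lmeds_initial_conic(valid_pts))
        else:
            initial = conic_to_ellipse(fit_conic_lsq(valid_pts))
    except (DegenerateInputError, NonEllipseError):
        return invalid
    dist = _distances(valid_pts, initial, config.distance_metric)
    q1, med, q3 = np.percentile(dist, [25, 50, 75])
    iqr = q3 - q1
    # relative floor keeps exact-arithmetic point sets (distances at the
    # fp noise level, median ~0) from losing points to rounding jitter
    floor = 1e-9 * initial.a_semi
    keep = (dist <= med + config.k_iqr * iqr + floor) & (
        dist <= config.alpha * initial.a_semi
    )
    if keep.sum() < config.min_points:
        return invalid
    try:
        refined = conic_to_ellipse(fit_conic_lsq(valid_pts[keep]))
    except (DegenerateInputError, NonEllipseError):
        return invalid
    flags[np.flatnonzero(finite)[keep]] = True
    return RobustFitResult(
        ellipse=refined,
        inlier_flags=flags,
        area_px2=refined.area,
        n_points_used=int(keep.sum()),
    )
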