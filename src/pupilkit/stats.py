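"""Non-parametric summaries, agreement analysis and paired tests.

The measurement pipeline's validation and stimulation-response analyses
are deliberately distribution-free: medians with interquartile ranges,
Bland–Altman agreement with percentile limits, Spearman correlation and
the exact Wilcoxon signed-rank test.  Quartiles throughout use the
median-exclusive-halves rule (for odd n the overall median is excluded
from both halves; each quartile is the median of its half), which matches
how such summaries are conventionally reported for small clinical samples.

The Wilcoxon implementation is exact under ties: zero differences are
dropped (Wilcoxon's original rule), absolute differences receive
mid-ranks, and the null distribution of W⁺ is built by enumerating sign
assignments over the *actual* mid-ranks via generating-function
convolution, so tied data still get an exact two-sided p-value.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import (
    ContractError,
    DegenerateTestError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from .scale import diameter_mm

__all__ = [
    "MedianIqrSummary",
    "AgreementReport",
    "WilcoxonResult",
    "ResponseResult",
    "summarize_median_iqr",
    "wilcoxon_signed_rank",
    "bland_altman_nonparametric",
    "spearman_rho",
    "shapiro_wilk",
    "pupillary_response",
]

EXACT_WILCOXON_MAX_N = 25
EXACT_SPEARMAN_MAX_N = 10


@dataclass(frozen=True)
class MedianIqrSummary:
    median: float
    q1: float
    q3: float

    def __str__(self) -> str:  # the conventional "median [Q1; Q3]" form
        return f"{self.median:g} [{self.q1:g}; {self.q3:g}]"


@dataclass(frozen=True)
class AgreementReport:
    """Non-parametric Bland–Altman agreement between two paired methods."""

    bias_median: float
    bias_q1: float
    bias_q3: float
    loa_low: float
    loa_high: float
    spearman_rho: float
    spearman_p: float
    n_pairs: int


@dataclass(frozen=True)
class WilcoxonResult:
    w_statistic: float
    n_effective: int
    p_two_sided: float
    method: str  # "exact" | "normal-approximation"


@dataclass(frozen=True)
class ResponseResult:
    """Pupillary response: mean stimulation minus mean baseline diameter."""

    baseline_mean_mm: float
    stim_mean_mm: float
    response_mm: float


def _exclusive_halves(sorted_values: np.ndarray) -> tuple[float, float]:
    n = len(sorted_values)
    half = n // 2
    lower = sorted_values[:half]
    upper = sorted_values[half + 1 :] if n % 2 else sorted_values[half:]
    return float(np.median(lower)), float(np.median(upper))


def summarize_median_iqr(values) -> MedianIqrSummary:
    """Median with quartiles by the median-exclusive-halves rule (n ≥ 3)."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ContractError("need at least 3 values for a median-IQR summary")
    v = np.sort(v)
    q1, q3 = _exclusive_halves(v)
    return MedianIqrSummary(median=float(np.median(v)), q1=q1, q3=q3)


def _wplus_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments by W⁺ on the doubled (integer) rank grid.

    Mid-ranks are multiples of 0.5, so doubling makes them integers; the
    distribution is the coefficient vector of ∏ᵢ (1 + z^{rᵢ}).
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    return dist


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Exact (n ≤ 25) or normal-approximate two-sided Wilcoxon test.

    Differences x − y; zeros dropped; |d| ranked with mid-ranks; the
    reported statistic is W = min(W⁺, W⁻).  The exact p enumerates all
    sign assignments over the observed mid-ranks; the approximation uses
    the tie-corrected normal variance without continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ContractError("x and y must be equal-length 1-d samples")
    d = x - y
    d = d[np.isfinite(d)]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all differences are zero; test undefined")
    ranks = _sps.rankdata(np.abs(d))
    wplus = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # n(n+1)/2
    w = min(wplus, total - wplus)
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = np.rint(2.0 * ranks).astype(int)
        dist = _wplus_distribution(doubled)
        k = int(np.rint(2.0 * wplus))
        cdf_lo = dist[: k + 1].sum()
        cdf_hi = dist[k:].sum()
        p = min(1.0, 2.0 * min(cdf_lo, cdf_hi) / dist.sum())
        method = "exact"
    else:
        mean = total / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        z = (wplus - mean) / np.sqrt(var)
        p = float(2.0 * _sps.norm.sf(abs(z)))
        method = "normal-approximation"
    return WilcoxonResult(w_statistic=w, n_effective=n, p_two_sided=p, method=method)


def spearman_rho(x, y) -> tuple[float, float]:
    """Mid-rank Spearman correlation with exact permutation p for n ≤ 10.

    For larger samples the usual t-approximation is used.  Raises
    :class:`UndefinedCorrelationError` when either variable has zero rank
    variance (all values tied).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be equal-length 1-d samples")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ContractError("need at least 3 pairs")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise UndefinedCorrelationError("zero rank variance; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs(rx_c @ ry_c)
        hits = 0
        count = 0
        it = itertools.permutations(range(n))
        while True:  # chunked enumeration keeps memory flat at n = 10 (10! perms)
            chunk = np.array(list(itertools.islice(it, 200_000)), dtype=np.int8)
            if chunk.size == 0:
                break
            stats_chunk = np.abs(ry_c[chunk] @ rx_c)
            hits += int((stats_chunk >= obs - 1e-12 * denom).sum())
            count += len(chunk)
        p = hits / count
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, np.finfo(float).tiny))
        p = float(2.0 * _sps.t.sf(abs(t), df=n - 2))
    return rho, p


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p) for 3 ≤ n ≤ 5000.

    Reported as a descriptive gate only; nothing downstream switches on
    its outcome automatically.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if not 3 <= len(v) <= 5000:
        raise ContractError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ContractError("Shapiro-Wilk undefined for a constant sample")
    w, p = _sps.shapiro(v)
    return float(w), float(p)


def bland_altman_nonparametric(m1, m2) -> AgreementReport:
    """Non-parametric Bland–Altman agreement between paired measurements.

    Bias is the median difference m1 − m2 with exclusive-halves quartiles;
    limits of agreement are the 2.5th and 97.5th percentiles of the
    differences (interpolation quantiles); association is the Spearman
    correlation over the pairs.  With tied ranks throughout (e.g.
    identical inputs) the correlation is reported as NaN with a warning.
    """
    m1 = np.asarray(m1, float)
    m2 = np.asarray(m2, float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ContractError("m1 and m2 must be equal-length 1-d samples")
    ok = np.isfinite(m1) & np.isfinite(m2)
    m1, m2 = m1[ok], m2[ok]
    if len(m1) < 4:
        raise InsufficientDataError("need at least 4 paired measurements")
    d = m1 - m2
    summary = summarize_median_iqr(d)
    loa_low, loa_high = np.percentile(d, [2.5, 97.5])
    if np.all(d == 0):
        warnings.warn("methods agree exactly; correlation is uninformative")
        rho, p = np.nan, np.nan
    else:
        try:
            rho, p = spearman_rho(m1, m2)
        except UndefinedCorrelationError:
            warnings.warn("zero rank variance; Spearman correlation undefined")
            rho, p = np.nan, np.nan
    return AgreementReport(
        bias_median=summary.median,
        bias_q1=summary.q1,
        bias_q3=summary.q3,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        spearman_rho=rho,
        spearman_p=p,
        n_pairs=len(m1),
    )


def pupillary_response(
    area_norm,
    baseline_window: tuple[int, int],
    stim_window: tuple[int, int],
    ref_mm: float = 8.0,
) -> ResponseResult:
    """Stimulation-evoked change in mean pupil diameter (mm).

    The normalised area is averaged over each window first (missing
    frames excluded) and the window means are then converted to diameters,
    so the response is the difference of equivalent-area-circle diameters.
    Windows are half-open frame ranges ``(start, stop)``.
    """
    a = np.asarray(area_norm, float)
    means = {}
    for name, (start, stop) in (("baseline", baseline_window), ("stimulation", stim_window)):
        if not (0 <= start < stop <= len(a)):
            raise ContractError(f"{name} window ({start}, {stop}) outside series of length {len(a)}")
        seg = a[start:stop]
        seg = seg[np.isfinite(seg)]
        if len(seg) == 0:
            raise InsufficientDataError(f"{name} window has no valid frames")
        means[name] = float(seg.mean())
    base_mm = diameter_mm(means["baseline"], ref_mm)
    stim_mm = diameter_mm(means["stimulation"], ref_mm)
    return ResponseResult(
        baseline_mean_mm=base_mm,
        stim_mean_mm=stim_mm,
        response_mm=stim_mm - base_mm,
    )
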