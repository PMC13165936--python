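# Methods

`pupilkit` turns markerless keypoint tracks of an eye — eight points on
the pupil boundary (P1–P8, at 45° spacing), a centre point (P9, tracked
but unused), and four endpoints of a skin-mounted reference sticker
(S1–S4) — into a calibrated pupil-diameter time series in millimetres,
and provides the agreement and stimulation-response statistics used to
qualify such a measurement chain.

## Measurement model

The pupil is modelled per frame as an ellipse.  Its area `A = π·a·b`
(px²) is normalised by the squared length `L` (px) of a reference of
known physical size (8 mm between S2 and S4 by default):

    A_norm = A / L²,     D = ref_mm · 2·√(A_norm / π)   [mm]

`D` is the diameter of the circle with the pupil's area.  Because both
`A` and `L²` scale with the square of the camera magnification, `A_norm`
— and hence `D` — is invariant under uniform scale changes (the head
moving toward or away from the camera).  The chain does *not* compensate
non-uniform changes such as head tilt out of the sticker plane; that
would need a two-dimensional reference of known area.

## Ellipse fitting

Each frame's boundary points are fitted with a general conic
`ax² + bxy + cy² + dx + ey + f = 0` by algebraic least squares: the
unit-norm coefficient vector minimising `‖M·v‖` over the monomial design
matrix `M`, obtained from the SVD.  Numerical choices:

* **Canonical preconditioning.** Points are shifted to their centroid
  and scaled to RMS radius √2 before the SVD, and the conic is mapped
  back afterwards.  Besides conditioning the quartic-range columns, this
  makes the fit *exactly* similarity-equivariant in floating point:
  scaling every pixel coordinate by `s` scales the fitted semi-axes by
  exactly `s`, which is what lets `A/L²` cancel camera scale to ~1e-13
  rather than ~1e-6.
* **Robust two-stage procedure.** Pose-estimation tracks contain
  occasional gross mislocalisations.  A single algebraic fit has no
  resistance to them: with 6 free coefficients the conic bends toward a
  displaced point until that point's residual is *smaller* than those of
  genuine boundary points, after which no residual threshold can isolate
  it.  The initial estimate is therefore a deterministic
  least-median-of-squares search: candidate fits to the full point set
  and to every subset obtained by dropping one or two points (never
  below 5), all computed in one shared canonical frame so their median
  absolute residuals are directly comparable (and the ranking is itself
  similarity-invariant); the candidate with the smallest median wins,
  ties keeping the full-set fit.  Outliers are then points whose
  orthogonal distance to the initial ellipse exceeds
  `median(d) + k·IQR(d)` (k = 1.5 by default; exposed because no
  canonical value exists) **or** exceeds `α·a₀` with `α = 0.1` and `a₀`
  the initial semi-major axis.  The final ellipse is a plain
  least-squares fit to the inliers.  Frames with fewer than 5 usable
  points, or where any fit is not an ellipse, yield an invalid frame
  (missing area), never an exception.
* **Point-to-ellipse distance.** "Distance to the conic" is the true
  orthogonal distance, not the algebraic residual (which is biased by
  eccentricity; an algebraic option remains as a config switch).  The
  foot-point equation is solved in the ellipse frame on the folded
  quadrant [0, π/2] by a bisection-safeguarded Newton iteration started
  from the point's polar angle; the root is unique for interior-quadrant
  points (the equation divided by sin·cos is strictly decreasing), and
  both axis endpoints are evaluated as candidates so on-axis feet are
  exact.  Accuracy is limited only by the 1e-14 bracket tolerance.
* **Known limitation.** With only 8 points per frame, two gross
  outliers can make an alternative conic through 6 of the 8 points fit
  *tighter than the noise level* of the true one; no frame-local
  criterion can then recover the truth.  Multi-frame pooling (up to 24
  markers over a 3-frame window, available as `pool_frames`) removes the
  ambiguity; with it ≥95% of injected gross outliers are excluded.  In
  the default per-frame mode, the temporal stages below absorb the rare
  mis-fit.

## Temporal cleaning

* Sliding **median filter** (window 3, step 1) on each keypoint's x and
  y; missing values are skipped, edge windows shrink, all-missing
  windows stay missing.  A single-frame keypoint spike is thereby
  removed before fitting.
* **Area-series outlier removal**: values outside
  `[Q1 − 1.5·IQR, Q3 + 3.0·IQR]` (interpolation quantiles) become
  missing.  The asymmetry is deliberate: dilation produces genuinely
  large areas, while blinks and failed fits produce spuriously small
  ones.
* **Gap-limited linear interpolation**: missing runs of ≤ 30 frames
  (~1 s at 30 frames/s) flanked by data on both sides are filled
  linearly; longer runs — sustained blinks or occlusions — and runs
  touching the series ends stay missing (no extrapolation).  The
  operation is idempotent and never alters present values.
* The **reference length** series is cleaned by manual plausibility
  gating (default ±50% around the session median when no thresholds are
  given), symmetric 1.5·IQR outlier removal (distinct from the
  asymmetric area rule), then the same gap-limited interpolation.
  Normalisation requires `L > 1e-6 px` to guard the division.

Quartile conventions: the cleaning stages use interpolation quantiles
(`numpy.percentile`); the *reported* summaries use median-exclusive-
halves quartiles (for odd n the overall median is excluded from both
halves), the convention under which small clinical samples are usually
summarised.

## Statistics

All analysis statistics are distribution-free.  A Shapiro–Wilk test (via
`scipy`) is reported as a gate but never switches methods silently.
Agreement between two measurement routes uses the non-parametric
Bland–Altman form: median difference with [Q1; Q3], limits of agreement
as the 2.5th/97.5th percentiles of the differences, plus Spearman
correlation (mid-ranks; exact permutation p for n ≤ 10, t-approximation
above).  The pupillary response averages *normalised area* over a 30 s
baseline window and a 9 s maximum-tolerable-intensity window, converts
each mean to mm, and subtracts — averaging before conversion, since area
is the quantity the pipeline measures.

The Wilcoxon signed-rank test is implemented in-package because exact
p-values under ties are needed: zero differences are dropped (Wilcoxon's
rule), absolute differences get mid-ranks, and for n ≤ 25 the null
distribution of W⁺ is built over the *observed* mid-ranks by
generating-function convolution on the half-integer grid — exact even
with ties.  Above n = 25 a tie-corrected normal approximation (no
continuity correction) takes over.  The reported statistic is
`W = min(W⁺, W⁻)`; the two-sided p doubles the smaller tail.

## Synthetic sessions

The generator emulates the acquisition geometry the pipeline targets:
30 frames/s video, a resting pupil near 5.7 mm, an 8 mm reference at
20 px/mm, boundary keypoints at 45° spacing with isotropic Gaussian
jitter (σ = 0.5 px), blinks (~12/min, 0.1–0.4 s, all pupil keypoints
missing, likelihood < 0.2), sporadic gross outliers (5% of keypoint-
frames, displaced 40 px in a random direction, likelihood 0.1), and a
±5% sinusoidal drift of the overall camera scale multiplying every
coordinate (slow head motion).  Dilation events are trapezoids (linear
rise, plateau, linear fall) added to the baseline diameter.  The
diameter→ellipse mapping preserves area (`a·b` fixed by the equivalent
circle, axis ratio free, default 0.85), so any axis ratio reproduces the
same diameter through the `A → D` chain.  One shared generator seeded
from the config drives all draws in a fixed order, so identical configs
give bitwise-identical sessions.

What the generator does **not** model: photorealistic appearance and
illumination, the pupillary light reflex, gaze-dependent foreshortening,
eyelid geometry, non-uniform scale changes, or temporally correlated
tracking error.  Passing the recovery tests therefore shows that the
*post-processing chain* is correct and robust to the listed artefact
types at realistic magnitudes — not that any particular tracking network
meets these error statistics on real video.

## Verification problem sizes

The test suite and the acceptance script size their simulations to keep
a full run comfortably on one CPU core: 20 recovery sessions of 1,800
frames (60 s) each for the diameter-error and response-recovery checks;
a 600-frame session for the scale-invariance probe (coordinates scaled
by 1.7, diameters required to agree within 1e-9 mm); 9 synthetic
participants per paradigm for the cohort analysis; 10,000 null
replicates at n = 9 for the exact test's type-I rate; and full 2ⁿ
enumeration oracles up to n = 12.

## Design choices on open points

* Smoothing-then-per-frame-fit is the default; pooled multi-frame fit
  input is an alternative mode (`pool_frames`), since the source
  procedure describes both without composing them.  On clean data the
  two agree within 2%.
* The reference endpoint pair defaults to (S2, S4) — the pair with the
  stated 8 mm calibration — and is configurable.
* Likelihood filtering is off by default (long sessions with movement
  artifacts make a fixed confidence threshold impractical); when
  enabled, it blanks low-confidence points before any other stage.
* Frame rate is configuration (default 30/s); keypoint files carry no
  timing.
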