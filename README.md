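# pupilkit

Webcam pupillometry post-processing: from markerless keypoint tracks of
an eye to a calibrated pupil-diameter time series in millimetres, with
the agreement-validation and stimulation-response statistics needed to
qualify such a measurement chain.

Pupil dilation indexes sympathetic (nociceptive) activation and is used
to monitor pain objectively.  When standard infrared pupillometers don't
fit the experimental setup — for example during electrophysiology
protocols where the participant lies on their side and the eye is filmed
by an ordinary webcam — the pupil can instead be tracked as a set of
keypoints by a pose-estimation network: eight points on the pupil
boundary (P1–P8), the pupil centre (P9) and four endpoints of a
skin-mounted reference sticker (S1–S4) whose S2–S4 separation is a known
8 mm.  `pupilkit` consumes the resulting per-frame CSV tracks
(three-header-row dialect with x, y, likelihood per keypoint) and
produces physical diameters:

1. **Robust ellipse fit** per frame: algebraic conic least squares via
   SVD with a deterministic least-median-of-squares initialisation,
   orthogonal-distance outlier rejection (`median + k·IQR`, plus an
   absolute `α·a₀` threshold), refit on inliers, area `A = π·a·b`.
2. **Temporal cleaning**: sliding median on coordinates, asymmetric
   IQR outlier removal on the area series, gap-limited linear
   interpolation (≤ 30 frames; longer blinks stay missing).
3. **Scale normalisation**: `A_norm = A/L²` with `L` the cleaned
   reference length, cancelling camera-scale changes.
4. **Calibration**: `D = 8 · 2√(A_norm/π)` mm — the equivalent-area
   circle diameter.

A synthetic-session generator with exact ground truth (blinks, keypoint
noise, gross outliers, scale drift, dilation events) makes the whole
chain testable without videos or a trained network, and a stats module
provides the accompanying non-parametric toolkit: median [Q1; Q3]
summaries (exclusive-halves quartiles), non-parametric Bland–Altman
agreement with percentile limits, Spearman correlation, Shapiro–Wilk,
and an exact Wilcoxon signed-rank test that handles ties.

## Worked example

```python
import numpy as np
from pupilkit import (DilationEvent, SynthConfig, generate_session,
                      process_track, response_from_series)

cfg = SynthConfig(
    n_frames=1800,                      # 60 s at 30 frames/s
    baseline_diameter_mm=5.7,
    dilation_events=(DilationEvent(900, 800, 0.9, 90),),  # +0.9 mm mid-session
    seed=7,
)
track, truth = generate_session(cfg)
series, counts = process_track(track)
print(f"{counts['frames_fitted']}/{counts['frames_total']} frames fitted")
err = np.abs(series.diameter_mm - truth.true_diameter_mm)
print(f"mean |error| = {np.nanmean(err):.3f} mm")
res = response_from_series(series, (0, 900), (1200, 1470))
print(f"pupillary response = {res.response_mm:.2f} mm")
```

prints

```
1742/1800 frames fitted
mean |error| = 0.030 mm
pupillary response = 0.90 mm
```

(58 frames fall inside blinks and are bridged by interpolation.)

— the pipeline recovers the 5.7 mm resting diameter to ~0.03 mm per
frame despite blinks, 0.5 px keypoint jitter, 5% gross outliers and a
±5% camera-scale drift, and retrieves the injected 0.9 mm dilation
(baseline window vs stimulation window) essentially exactly.

The same workflows are available from the shell:

```bash
pupilkit simulate session --n-frames 1800 --event 900,800,0.9,90
pupilkit process session_track.csv session_diam.csv
pupilkit validate run_a.csv run_b.csv agreement.json
pupilkit analyze --mn a.csv --mn b.csv --mm c.csv --mm d.csv report.json
```

Each run writes a JSON run log (config echo, per-stage counts, version)
next to its output; reruns with the same inputs are bitwise
reproducible.  See `examples/` for narrative scripts covering
simulation/recovery, agreement validation and the two-paradigm response
analysis.

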