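"""Pupillary response to two stimulation paradigms.

Builds a nine-participant synthetic cohort in which non-modulated pulses
(MN) dilate the pupil by 0.9 mm and 5 kHz-modulated pulses (MM) by
0.2 mm, recovers per-session responses from the processed diameter
series (30 s baseline vs the maximum-tolerable-intensity window), and
compares the paradigms with the exact Wilcoxon signed-rank test.
"""

import numpy as np

from pupilkit import (
    DilationEvent,
    SynthConfig,
    generate_session,
    ground_truth_response,
    process_track,
    response_from_series,
    summarize_median_iqr,
    wilcoxon_signed_rank,
)

BASELINE = (0, 900)   # 30 s at 30 frames/s
STIM = (1200, 1470)   # 9 s at the maximum tolerable intensity

responses = {}
for label, amplitude in (("MN", 0.9), ("MM", 0.2)):
    vals = []
    for participant in range(9):
        cfg = SynthConfig(
            n_frames=1800,
            seed=1000 * participant + (0 if label == "MN" else 1),
            dilation_events=(DilationEvent(900, 800, amplitude, 90),),
        )
        track, truth = generate_session(cfg)
        series, _ = process_track(track)
        res = response_from_series(series, BASELINE, STIM)
        vals.append(res.response_mm)
    responses[label] = np.array(vals)
    s = summarize_median_iqr(vals)
    print(f"{label}: response {s} mm (n = 9)")

test = wilcoxon_signed_rank(responses["MN"], responses["MM"])
print(f"MN vs MM: W = {test.w_statistic:g}, exact p = {test.p_two_sided:.4f}")
# The non-modulated paradigm shows the larger dilation; with all nine
# pairs in the same direction the exact test gives p = 2/512 ~ 0.004.
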