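"""Bundled example dataset: single-pulse stimulation tolerance study.

Per-participant maximum tolerable current (mA) and Visual Analogue Scale
pain score (0–10) for two transcutaneous spinal-cord stimulation
paradigms — single monopolar rectangular pulses without kHz modulation
(MN) and with 5 kHz modulation (MM) — in the nine participants who
reached a defined tolerance threshold.  Used by the examples and the
acceptance script to exercise the summary and paired-test routines on
real printed values.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MN_CURRENT_MA",
    "MN_VAS",
    "MM_CURRENT_MA",
    "MM_VAS",
    "PARTICIPANTS",
]

PARTICIPANTS = np.arange(1, 10)

#: Maximum tolerable current, non-modulated paradigm (mA).
MN_CURRENT_MA = np.array([240, 235, 240, 200, 90, 240, 240, 140, 100], float)
#: VAS pain score at maximum tolerable current, non-modulated paradigm.
MN_VAS = np.array([7, 8, 6, 7, 7, 8, 7, 9, 7], float)
#: Maximum tolerable current, 5 kHz-modulated paradigm (mA).
MM_CURRENT_MA = np.array([240, 230, 240, 200, 130, 250, 250, 240, 250], float)
#: VAS pain score at maximum tolerable current, 5 kHz-modulated paradigm.
MM_VAS = np.array([7, 5, 4, 5, 6, 7, 2, 7, 6], float)
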