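"""Reference stimulation-trial counts of the motivating clinical cohort.

Eight intraoperative median-nerve SSEP sessions (P1-P8); the per-patient
stimulation-trial counts are the published demographics table of the
validation cohort.  They are used to sanity-check summary statistics and
to pick realistic simulator trial counts.
"""

from __future__ import annotations

import math

__all__ = ["PATIENT_TRIAL_COUNTS", "trial_count_summary"]

PATIENT_TRIAL_COUNTS: dict[str, int] = {
    "P1": 66,
    "P2": 281,
    "P3": 164,
    "P4": 80,
    "P5": 95,
    "P6": 200,
    "P7": 101,
    "P8": 105,
}


def trial_count_summary() -> tuple[float, float]:
    """Mean and sample SD (n-1) of the cohort's trial counts."""
    counts = list(PATIENT_TRIAL_COUNTS.values())
    n = len(counts)
    mean = sum(counts) / n
    var = sum((c - mean) ** 2 for c in counts) / (n - 1)
    return mean, math.sqrt(var)
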