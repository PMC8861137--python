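"""Published cohort summary statistics for lumbar endplate CT-OAM.

Relative calcium concentrations (mg/ml, mean +/- sd) of the subchondral
bone plates in the reference cohorts this package's analysis emulates:
17 healthy forensic cases (all six lumbar levels each) versus 18
patients with degenerative disc disease (DDD, 5-15 affected discs per
level).  The original CT volumes were never deposited, so these printed
summaries are the only cohort-level numbers available; they serve as
worked-example inputs for the ratio statistics, not as fit targets.

``INFERIOR_SBP`` covers the plate on the caudal surface of each
vertebra (Th12-L5, facing discs Th12/L1-L5/S1).  Healthy n is 17 at
every level; the DDD n is the per-disc count.
"""

from __future__ import annotations

import pandas as pd

_INFERIOR_ROWS = [
    # level, healthy mean, healthy sd, ddd mean, ddd sd, n_healthy, n_ddd
    ("Th12", 322.0, 31.0, 380.0, 86.0, 17, 5),
    ("L1", 319.0, 26.0, 399.0, 75.0, 17, 6),
    ("L2", 335.0, 28.0, 414.0, 58.0, 17, 6),
    ("L3", 362.0, 31.0, 439.0, 67.0, 17, 7),
    ("L4", 372.0, 35.0, 500.0, 95.0, 17, 15),
    ("L5", 340.0, 42.0, 481.0, 131.0, 17, 10),
]

#: Inferior-SBP cohort means (mg/ml) per vertebral level.
INFERIOR_SBP = pd.DataFrame(
    _INFERIOR_ROWS,
    columns=[
        "level", "healthy_mean", "healthy_sd", "ddd_mean", "ddd_sd",
        "n_healthy", "n_ddd",
    ],
)

#: Reported integer percent-of-healthy at the inferior SBP.  The L1 entry
#: is 124 in the source report although the printed means give 125 — a
#: consequence of the report's own rounding of the underlying means.
INFERIOR_REPORTED_PERCENT = {
    "Th12": 118, "L1": 124, "L2": 124, "L3": 121, "L4": 134, "L5": 141,
}

#: Reported percent-of-healthy at the superior SBP (L1-S1).
SUPERIOR_REPORTED_PERCENT = {
    "L1": 132, "L2": 127, "L3": 120, "L4": 131, "L5": 148, "S1": 152,
}

#: Healthy per-subject inferior/superior plate ratios (mean, sd) per
#: motion segment (cranial plate over caudal plate of the same disc).
HEALTHY_SEGMENT_RATIOS = {
    "Th12/L1": (0.93, 0.05),
    "L1/L2": (0.95, 0.03),
    "L2/L3": (0.91, 0.03),
    "L3/L4": (0.89, 0.04),
    "L4/L5": (0.85, 0.06),
    "L5/S1": (1.07, 0.15),
}

__all__ = [
    "INFERIOR_SBP",
    "INFERIOR_REPORTED_PERCENT",
    "SUPERIOR_REPORTED_PERCENT",
    "HEALTHY_SEGMENT_RATIOS",
]
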