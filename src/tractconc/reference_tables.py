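"""Published reference tables used for validating the statistics layer.

These are the printed per-subject values from the clinical study this
pipeline re-implements: the cohort characteristics table and the
per-subject overlap-coefficient / Dice table for the two segmentation
methods.  The underlying imaging is not shareable, so these printed
numbers are the only recomputable ground truth for the cohort-level
statistics (means, spreads, paired tests).
"""

from __future__ import annotations

import pandas as pd

from .cohort import CohortTable
from .concordance import ConcordanceTable
from .ntms import NEG_OUT_M1, POS_IN_M1, POS_OUT_M1

__all__ = ["reference_cohort", "reference_concordance", "METHOD_PRIMARY", "METHOD_BASELINE"]

METHOD_PRIMARY = "UncSeg"
METHOD_BASELINE = "TractSeg"

# subject_id, age, sex, tumor_location, hemisphere, tumor_volume_cm3, diagnosis
_COHORT_ROWS = [
    (1, 34, "M", "Frontal", "Left", 98.1, "Anaplastic Astrocytoma WHO Grade 3"),
    (2, 51, "F", "Supplementary Motor Area", "Right", 45.3, "Anaplastic Astrocytoma WHO Grade 3"),
    (3, 47, "M", "Frontal", "Left", 129.0, "Anaplastic Oligodendroglioma WHO Grade 3"),
    (4, 40, "F", "Frontal", "Left", 207.0, "Anaplastic Oligodendroglioma WHO Grade 3"),
    (5, 25, "M", "Frontal", "Left", 10.1, "Oligodendroglioma WHO Grade 2"),
    (6, 36, "F", "Internal Capsule", "Right", 16.7, "Glioblastoma WHO Grade 4"),
    (7, 62, "F", "Subcentral", "Right", 6.67, "Glioblastoma WHO Grade 4"),
    (8, 59, "F", "Subcentral", "Left", 4.0, "Glioblastoma WHO Grade 4"),
    (9, 30, "M", "Supplementary Motor Area", "Left", 27.5, "Astrocytoma WHO Grade 2"),
    (10, 69, "M", "Fronto-Insular", "Left", 54.3, "Glioblastoma WHO Grade 4"),
    (11, 32, "M", "Temporo-Insular", "Left", 71.2, "Anaplastic Oligodendroglioma WHO Grade 3"),
    (12, 51, "M", "Temporo-Insular", "Left", 16.8, "Glioblastoma WHO Grade 4"),
    (13, 37, "M", "Temporo-Insular", "Left", 105.0, "Anaplastic Oligodendroglioma WHO Grade 3"),
    (14, 29, "M", "Temporo-Insular", "Left", 9.01, "Astrocytoma WHO Grade 2"),
    (15, 54, "F", "Frontal", "Right", 114.3, "Astrocytoma WHO Grade 3"),
    (16, 51, "F", "Frontal", "Left", 7.42, "Oligodendroglioma WHO Grade 2"),
]

# subject_id, OC primary (+M1+, -M1+, -M1-), OC baseline (+M1+, -M1+, -M1-),
# Dice between the two methods' tract masks
_OVERLAP_ROWS = [
    (1, 1.000, 0.684, 0.395, 1.000, 0.387, 0.024, 0.820),
    (2, 0.941, 0.000, 0.000, 0.980, 0.000, 0.000, 0.853),
    (3, 0.864, 0.000, 0.000, 0.857, 0.000, 0.000, 0.869),
    (4, 0.868, 0.310, 0.011, 0.919, 0.468, 0.107, 0.814),
    (5, 0.785, 0.000, 0.000, 0.780, 0.000, 0.000, 0.862),
    (6, 0.774, 0.000, 0.000, 0.816, 0.000, 0.000, 0.821),
    (7, 0.808, 0.000, 0.000, 0.922, 0.000, 0.000, 0.805),
    (8, 0.504, 0.000, 0.000, 0.540, 0.000, 0.000, 0.846),
    (9, 0.993, 0.343, 0.291, 1.000, 0.622, 0.318, 0.847),
    (10, 0.851, 0.000, 0.333, 0.823, 0.000, 0.000, 0.765),
    (11, 0.828, 0.000, 0.053, 0.761, 0.000, 0.000, 0.862),
    (12, 0.660, 0.055, 0.000, 0.741, 0.000, 0.000, 0.809),
    (13, 0.677, 0.075, 0.077, 0.787, 0.000, 0.000, 0.838),
    (14, 1.000, 0.375, 0.000, 1.000, 0.125, 0.000, 0.855),
    (15, 0.724, 0.000, 0.000, 0.897, 0.000, 0.000, 0.687),
    (16, 0.944, 0.006, 0.069, 0.944, 0.026, 0.106, 0.864),
]


def reference_cohort() -> CohortTable:
    """The published 16-subject cohort characteristics table."""
    frame = pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "subject_id",
            "age",
            "sex",
            "tumor_location",
            "hemisphere",
            "tumor_volume_cm3",
            "diagnosis",
        ],
    )
    return CohortTable(frame)


def reference_concordance() -> ConcordanceTable:
    """The published per-subject OC table for both segmentation methods."""
    oc_cols = [ConcordanceTable.OC_COLUMNS[k] for k in (POS_IN_M1, POS_OUT_M1, NEG_OUT_M1)]
    rows = []
    dice_rows = []
    for sid, u_p, u_m, u_n, t_p, t_m, t_n, d in _OVERLAP_ROWS:
        rows.append({"subject_id": sid, "method": METHOD_PRIMARY, **dict(zip(oc_cols, (u_p, u_m, u_n)))})
        rows.append({"subject_id": sid, "method": METHOD_BASELINE, **dict(zip(oc_cols, (t_p, t_m, t_n)))})
        dice_rows.append({"subject_id": sid, "method_a": METHOD_PRIMARY, "method_b": METHOD_BASELINE, "dice": d})
    return ConcordanceTable(pd.DataFrame(rows), pd.DataFrame(dice_rows))
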