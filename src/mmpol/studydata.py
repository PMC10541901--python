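"""Published summary counts of the pancreatic-tissue polarimetry study.

These constants are the printed per-label bookkeeping of the clinical
dataset that this package's synthetic cohorts emulate: 11 patients (5 with
both tissue zones), 15 biopsy samples (2 containing both normal and
abnormal regions), annotated pixel counts before and after removing
saturated pixels.  The raw images themselves are not public; only this
summary table is, and it is used as input for consistency checks and as
the template for the default :class:`~mmpol.phantom.CohortConfig`.

Note that patient and sample counts are *not* additive across labels --
patients/samples with both tissue types appear in both rows -- whereas
region area, total pixels and used pixels partition exactly.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["COHORT_SUMMARY", "PRINTED_TOTALS", "summary_totals"]

#: per-label rows as printed (area in mm^2; "used" excludes saturated pixels)
COHORT_SUMMARY = pd.DataFrame(
    [
        {
            "label": "normal",
            "patients": 9,
            "samples": 9,
            "region_area_mm2": 310,
            "total_pixels": 401_784,
            "used_pixels": 339_631,
        },
        {
            "label": "abnormal",
            "patients": 7,
            "samples": 8,
            "region_area_mm2": 151,
            "total_pixels": 195_611,
            "used_pixels": 177_073,
        },
    ]
)

#: the printed grand-total row
PRINTED_TOTALS = {
    "patients": 11,
    "samples": 15,
    "region_area_mm2": 461,
    "total_pixels": 597_395,
    "used_pixels": 516_704,
}

#: overlap between label rows: patients with both tissue zones, and samples
#: containing both region types
PATIENTS_WITH_BOTH = 5
SAMPLES_WITH_BOTH = 2


def summary_totals() -> dict[str, int]:
    """Column sums of the per-label rows.

    Region area and pixel counts partition across labels and therefore sum
    to the printed totals; patient and sample sums exceed the printed
    totals by exactly the double-counted overlaps.
    """
    sums = COHORT_SUMMARY.drop(columns="label").sum()
    return {k: int(v) for k, v in sums.items()}
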