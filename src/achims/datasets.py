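"""Worked-example reference tables.

Published summary tables from an FT-ICR-MS acetylcholine imaging study
of lung tissue, shipped as inputs for the worked examples and for
summary-statistics operations that reconstruct full statistics
(RSD%, standard-curve R², pairwise t tests) from mean ± SEM tables.
Intensities are in the source's units (×10³ a.u. for the dilution
series; a.u. for section means); amounts in pmol per 0.2 μL spot.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ach_dilution_summary", "lung_group_summary",
           "DILUTION_N_REPLICATES", "LUNG_N_MICE"]

#: Technical replicates per dilution level in the reference series.
DILUTION_N_REPLICATES = 8
#: Mice per treatment group in the reference section-mean summary.
LUNG_N_MICE = 6

# amount (pmol), mean intensity (x10^3 a.u.), SEM (x10^3 a.u.),
# printed RSD% for cross-checks
_DILUTION_ROWS = [
    (0.20, 0.61, 0.10, 46.55),
    (0.39, 2.03, 0.31, 43.09),
    (0.78, 4.08, 0.38, 26.17),
    (1.56, 8.05, 0.80, 28.17),
    (3.13, 16.04, 1.91, 33.72),
    (6.25, 30.58, 2.70, 24.95),
    (12.5, 61.57, 7.11, 32.67),
    (25.0, 88.20, 8.00, 25.65),
    (50.0, 167.20, 8.36, 14.14),
    (100.0, 280.27, 14.54, 14.67),
]

# group -> (mean section intensity a.u., SEM, n mice)
_LUNG_GROUPS = {
    "saline": (440.0, 53.0, LUNG_N_MICE),
    "HDM": (835.0, 110.0, LUNG_N_MICE),
    "HDM_Alum": (1586.0, 154.0, LUNG_N_MICE),
}


def ach_dilution_summary() -> pd.DataFrame:
    """Ten-level on-tissue ACh dilution series, mean ± SEM, n = 8.

    Columns: ``amount_pmol``, ``mean_intensity``, ``sem_intensity``
    (both ×10³ a.u.), ``rsd_printed`` (the RSD% row as published, for
    cross-checking reconstructions), ``n``.
    """
    df = pd.DataFrame(
        _DILUTION_ROWS,
        columns=["amount_pmol", "mean_intensity", "sem_intensity",
                 "rsd_printed"],
    )
    df["n"] = DILUTION_N_REPLICATES
    return df


def lung_group_summary() -> dict[str, tuple[float, float, int]]:
    """Section-mean normalized ACh intensity per group: (mean, SEM, n).

    Saline controls vs HDM-sensitised vs HDM/Alum-sensitised mice,
    n = 6 mice per group, technical replicates already collapsed.
    """
    return dict(_LUNG_GROUPS)
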