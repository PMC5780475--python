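"""Bundled reference measurements for PTA-stained murine kidneys.

Published morphometric and radio-opacity values measured on µCT scans of
PTA-stained mouse kidneys. They serve as worked-example inputs for the
summary-statistics entry points (the thickness index, fraction/volume
conversion, and the summary t-test) and as regression anchors in the test
suite; no scan data is required to use them.

``healthy_cohort()`` returns the eight healthy kidneys (four animals, both
kidneys) with whole-kidney volume, compartment percentages, mean 2D
cortical thickness, surface area and the printed √A/Cth index.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "healthy_cohort", "WORKED_EXAMPLE_FRACTIONS", "WORKED_EXAMPLE_TOTAL_MM3",
    "WORKED_EXAMPLE_VOLUMES_MM3", "CUBE_MEAN_GV_SHAM", "CUBE_MEAN_GV_UUO",
    "CUBE_MAX_GV_SHAM", "CUBE_MAX_GV_UUO", "WHOLE_CORTEX_GV_SHAM",
    "WHOLE_CORTEX_GV_UUO", "CORTICAL_VOLUME_LOSS_PERCENT",
    "SWELLING_PERCENT", "SHRINKAGE_PERCENT",
]

_HEALTHY_ROWS = [
    # strain, sex, age_months, V_kidney, pelvis%, medulla%, cortex%, Cth_mm, A_mm2, printed index
    ("C57/Bl6", "m", 8.0, 316.7, 8.70, 13.30, 78.10, 2.147, 46.46, 3.175),
    ("C57/Bl6", "m", 8.0, 341.1, 7.53, 11.68, 80.79, 2.115, 48.82, 3.304),
    ("C57/Bl6", "m", 12.0, 222.4, 12.76, 12.88, 74.37, 1.730, 36.71, 3.502),
    ("C57/Bl6", "m", 12.0, 195.2, 13.40, 18.20, 68.40, 1.692, 33.65, 3.428),
    ("C57/Bl6", "f", 19.5, 188.1, 10.42, 20.22, 69.37, 1.595, 32.83, 3.592),
    ("C57/Bl6", "f", 19.5, 201.2, 11.56, 24.84, 63.62, 1.621, 34.34, 3.615),
    ("C57/Bl6", "m", 4.0, 200.2, 16.20, 13.30, 70.50, 1.724, 34.22, 3.393),
    ("C57/Bl6", "m", 4.0, 195.2, 15.57, 13.50, 70.93, 1.628, 33.63, 3.550),
]

_COLUMNS = [
    "strain", "sex", "age_months", "v_kidney_mm3", "pelvis_percent",
    "medulla_percent", "cortex_percent", "cth_mm", "a_kidney_mm2",
    "index_printed",
]


def healthy_cohort() -> pd.DataFrame:
    """Morphometry of eight healthy murine kidneys (one row per kidney)."""
    return pd.DataFrame(_HEALTHY_ROWS, columns=_COLUMNS)


#: worked example of fraction <-> absolute-volume conversion for one kidney:
#: pelvis/medulla/cortex percentages and the matching absolute volumes
WORKED_EXAMPLE_FRACTIONS = (15.57, 13.50, 70.93)
WORKED_EXAMPLE_TOTAL_MM3 = 208.7
WORKED_EXAMPLE_VOLUMES_MM3 = (32.5, 28.2, 148.0)

#: cortical cube radio-opacity summaries, (mean GV, SD, n kidneys):
#: mean-of-cube-means and max-of-cube-maxima per group
CUBE_MEAN_GV_SHAM = (3575.0, 94.5, 4)
CUBE_MEAN_GV_UUO = (3039.0, 105.5, 4)
CUBE_MAX_GV_SHAM = (3916.0, 102.1, 4)
CUBE_MAX_GV_UUO = (3302.0, 61.9, 4)

#: whole-cortex grey-value summaries, (mean GV, SD, n kidneys)
WHOLE_CORTEX_GV_SHAM = (3703.0, 133.3, 4)
WHOLE_CORTEX_GV_UUO = (3009.5, 80.0, 4)

#: cortical mass lost in obstructed kidneys vs contralateral controls (mean, SD)
CORTICAL_VOLUME_LOSS_PERCENT = (61.8, 22.5)

#: organ volume change through staining (swelling) and through dehydration +
#: paraffin embedding (shrinkage), percent (mean, SD)
SWELLING_PERCENT = (11.8, 5.57)
SHRINKAGE_PERCENT = (-18.7, 7.26)
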