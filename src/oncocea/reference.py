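"""Published US benchmark results for first-line atezolizumab /
pembrolizumab / chemotherapy in stage IV NSCLC, stratified by PD-L1
expression.

These are printed results of the published analysis this package
re-implements; they are NOT computed here.  They serve as arithmetic
cross-checks: printed incremental costs/QALYs/ICERs must be internally
consistent with the printed totals, and the printed budget-impact matrix
must satisfy its own column-sum and geometric-decay identities.  The
absolute totals themselves depend on trial survival curves and supplementary
inputs that were never published, so they are validation anchors, not
reproduction targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# base-case totals and increments ($, QALYs), by PD-L1 stratum

PUBLISHED_TOTALS = pd.DataFrame(
    [
        ("any", "chemotherapy", 82_258.38, 0.9499),
        ("any", "pembrolizumab", 179_917.30, 1.1798),
        ("any", "atezolizumab", 193_773.70, 1.4244),
        ("high", "chemotherapy", 85_295.80, 0.8948),
        ("high", "pembrolizumab", 218_835.80, 1.8428),
        ("high", "atezolizumab", 290_933.70, 2.4669),
    ],
    columns=["population", "strategy", "total_cost", "total_qalys"],
)

#: printed decimals of each total cost above (drives rounding tolerances)
PUBLISHED_COST_DECIMALS = {
    ("any", "chemotherapy"): 2, ("any", "pembrolizumab"): 1,
    ("any", "atezolizumab"): 1, ("high", "chemotherapy"): 1,
    ("high", "pembrolizumab"): 1, ("high", "atezolizumab"): 1,
}

PUBLISHED_INCREMENTS = pd.DataFrame(
    [
        ("any", "atezolizumab", "chemotherapy",
         111_515.32, 0.4746, 234_990.23),
        ("any", "pembrolizumab", "chemotherapy",
         97_658.91, 0.2299, 424_797.10),
        ("any", "atezolizumab", "pembrolizumab",
         13_856.37, 0.2446, 56_635.92),
        ("high", "atezolizumab", "chemotherapy",
         205_637.90, 1.5721, 130_804.59),
        ("high", "pembrolizumab", "chemotherapy",
         133_540.00, 0.9479, 140_873.27),
        ("high", "atezolizumab", "pembrolizumab",
         72_097.90, 0.6241, 115_511.82),
    ],
    columns=["population", "intervention", "comparator",
             "delta_cost", "delta_qalys", "icer"],
)

# ---------------------------------------------------------------------------
# published 5-year incremental budget-impact matrix ($; atezolizumab
# replacing chemotherapy in the high-PD-L1 population, cohorts 2020–2024)

BIA_YEARS = np.array([2020, 2021, 2022, 2023, 2024])

PUBLISHED_BIA_ENTRIES = np.array([
    [16_084_719.60, 11_794_564.73, 8_127_814.90, 2_334_810.82, 2_201_432.19],
    [0.0, 15_763_025.20, 11_558_673.44, 7_965_258.60, 3_121_787.80],
    [0.0, 0.0, 15_447_764.70, 11_327_499.97, 7_805_953.43],
    [0.0, 0.0, 0.0, 15_138_809.41, 11_100_949.97],
    [0.0, 0.0, 0.0, 0.0, 14_836_033.22],
])

PUBLISHED_BIA_NET = np.array([
    16_084_719.60, 27_557_589.93, 35_134_253.03, 36_766_378.79, 39_066_156.61,
])

# population projection constants behind the matrix
SEER_STAGE_IV_CASES_2015 = 1312
INCIDENCE_DECLINE_PER_YEAR = 0.02
HIGH_PDL1_PROPORTION = 0.22
INCIDENT_CASES_2020 = 1185  # printed projection for the first model year
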