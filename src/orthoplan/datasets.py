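"""Bundled example data.

``example_cohort`` is a published planning summary for 24 bimaxillary-surgery
patients: per-patient net displacement of the maxillomandibular complex as
translations (mm) along the left-right, advance-setback and
impaction-elongation axes and rotations (degrees) in pitch, roll and yaw.
It drives the worked examples and the summary-statistics checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["COHORT_COLUMNS", "example_cohort"]

COHORT_COLUMNS = (
    "left_right",
    "advance_setback",
    "impaction_elongation",
    "pitch",
    "roll",
    "yaw",
)

_COHORT = np.array([
    [3.44, 0.19, 2.98, 0.00, -3.10, 1.15],
    [-1.38, 1.05, 0.59, 2.82, 3.35, -2.65],
    [-1.72, 0.12, -1.19, 5.57, 3.03, -3.33],
    [0.69, -0.49, 1.54, 6.27, 1.57, 1.18],
    [-0.24, 1.12, -1.87, 3.42, -4.67, 0.00],
    [-0.90, -2.76, 5.41, 8.31, 3.22, 0.00],
    [0.38, 1.88, 3.41, 8.22, 0.00, -1.27],
    [0.36, 0.01, 0.00, 0.00, 0.00, -1.14],
    [2.20, 1.90, 1.63, 1.83, 3.02, 0.00],
    [0.72, -1.43, 1.45, 5.41, -0.13, -2.68],
    [1.28, -0.28, -0.63, 4.13, -4.68, 2.41],
    [-1.91, 0.11, -1.09, 7.37, 1.56, 0.00],
    [-0.75, 3.99, 2.65, 2.86, 0.00, -1.10],
    [1.63, -0.54, 2.63, 7.51, -1.44, 2.84],
    [-0.71, -0.14, -0.71, 2.04, 4.60, -1.65],
    [2.09, 1.14, 2.86, 4.20, 1.51, 0.00],
    [0.57, 0.13, -0.68, 6.56, 0.00, 1.20],
    [1.02, -0.01, 1.30, 4.47, -3.33, 2.65],
    [0.06, -0.12, -0.47, 9.97, 3.69, 0.00],
    [-1.11, 1.14, -0.54, 9.02, 1.59, -2.69],
    [0.77, 0.09, -0.26, 12.56, 1.56, 1.32],
    [-1.32, 2.32, -0.97, 3.78, 1.48, -2.23],
    [-0.96, 1.30, 4.23, 5.97, 3.91, 0.00],
    [-1.50, -1.74, -1.05, 9.28, 0.00, -2.37],
])


def example_cohort() -> pd.DataFrame:
    """Planned-displacement table for the 24-patient example cohort."""
    return pd.DataFrame(
        _COHORT.copy(),
        columns=list(COHORT_COLUMNS),
        index=pd.RangeIndex(1, 25, name="patient"),
    )
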