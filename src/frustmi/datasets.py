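"""Bundled reference summary of a 12-participant frustration-BCI study.

These are published per-subject summary numbers (percent accuracies and an
averaged confusion matrix) shipped so the cohort-aggregation and
confusion-metric operations can be exercised and regression-tested against a
real cohort without any download.  They are inputs, not outputs: every
summary statistic is recomputed from them at run time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "reference_pbci_accuracy",
    "reference_mi_accuracy",
    "reference_method_accuracy",
    "reference_state_confusion",
]

_SUBJECTS = [f"S{i:02d}" for i in range(1, 13)]

# Frustration-level (3-class pBCI) decoder accuracy per participant (%).
_PBCI_ACC = [84.2, 87.5, 81.3, 83.6, 86.7, 82.9, 88.1, 84.5, 90.2, 83.7, 86.1, 83.3]

# MI decoding accuracy (%) per participant for state-specific training
# conditions and the state-agnostic ("all") condition.
_MI_ACC = {
    "low": [85.01, 91.02, 72.99, 70.04, 87.44, 68.18,
            87.12, 57.73, 97.55, 78.72, 74.33, 53.20],
    "mid": [70.00, 95.03, 67.67, 74.25, 78.65, 60.33,
            76.28, 60.09, 91.00, 74.17, 67.43, 60.10],
    "high": [55.21, 67.69, 59.23, 55.27, 53.25, 51.24,
             64.65, 64.40, 73.20, 83.36, 46.71, 64.69],
    "all": [63.17, 83.25, 54.41, 58.75, 64.03, 47.17,
            63.70, 65.81, 74.49, 56.93, 66.67, 54.73],
}

# MI decoding accuracy (%) per participant under the four decision
# strategies: hard switching (1), probabilistic fusion (2), pooled
# state-agnostic baseline (3-1) and calibration-only baseline (3-2).
_METHOD_ACC = {
    "1": [67.74, 86.27, 65.89, 70.21, 72.31, 57.55,
          71.23, 64.33, 91.22, 73.30, 64.32, 59.11],
    "2": [71.50, 86.22, 66.48, 72.23, 68.23, 62.58,
          74.33, 67.36, 91.24, 75.52, 68.22, 52.50],
    "3-1": [63.21, 83.22, 54.39, 58.68, 64.00, 47.17,
            63.71, 65.82, 74.51, 56.88, 66.72, 54.71],
    "3-2": [65.36, 84.73, 56.51, 63.22, 65.83, 43.47,
            66.83, 71.36, 72.37, 60.58, 68.19, 57.81],
}

# Cohort-averaged, row-normalized (%) confusion matrix of the 3-class
# frustration decoder; rows = true low/mid/high, columns = predicted.
_STATE_CONFUSION = [
    [88.1, 7.9, 4.0],
    [9.8, 80.3, 9.9],
    [3.7, 10.4, 85.9],
]


def reference_pbci_accuracy() -> pd.Series:
    """Per-subject 3-class frustration-decoder accuracy (%)."""
    return pd.Series(_PBCI_ACC, index=_SUBJECTS, name="pbci_accuracy")


def reference_mi_accuracy() -> pd.DataFrame:
    """Per-subject MI accuracy (%) by training condition (low/mid/high/all)."""
    return pd.DataFrame(_MI_ACC, index=_SUBJECTS)


def reference_method_accuracy() -> pd.DataFrame:
    """Per-subject MI accuracy (%) under the four decision strategies."""
    return pd.DataFrame(_METHOD_ACC, index=_SUBJECTS)


def reference_state_confusion() -> np.ndarray:
    """Cohort-averaged row-normalized confusion matrix (%), low/mid/high."""
    return np.array(_STATE_CONFUSION, dtype=float)
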