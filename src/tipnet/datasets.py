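"""Published baseline-characteristics table of the staged monocyte cohort.

Input data for the cohort statistics: per-group mean +/- SD summaries of the
continuous covariates and group x category counts of the categorical ones,
for 8 patients per stage (NCA = normal coronary angiography, IML =
intermediate lesion, AMI = acute myocardial infarction). These are the
printed summaries themselves, used to re-derive the reported test statistics.
"""

from __future__ import annotations

import numpy as np

from .cohort import ContingencyTable, GroupSummary

__all__ = ["STAGE_GROUPS", "baseline_continuous", "baseline_categorical"]

STAGE_GROUPS = ["NCA", "IML", "AMI"]

# variable -> (mean, sd) per group, n = 8 each
_CONTINUOUS = {
    "age": [(59.75, 8.71), (63.38, 9.04), (63.25, 8.29)],
    "bmi": [(24.75, 2.13), (22.72, 2.28), (26.00, 3.31)],
    "lvef": [(64.95, 6.70), (65.12, 4.36), (58.43, 9.76)],
}

# variable -> count with the attribute per group (out of 8)
_CATEGORICAL = {
    "male": [5, 6, 6],
    "diabetes": [2, 1, 3],
    "hypertension": [6, 5, 4],
    "dyslipidemia": [5, 5, 7],
    "family_history_cad": [0, 7, 1],
    "current_smoker": [1, 5, 3],
    "alcohol": [4, 1, 2],
}

GROUP_N = 8


def baseline_continuous() -> dict[str, list[GroupSummary]]:
    return {
        var: [GroupSummary(mean=m, sd=s, n=GROUP_N) for m, s in rows]
        for var, rows in _CONTINUOUS.items()
    }


def baseline_categorical() -> dict[str, ContingencyTable]:
    return {
        var: ContingencyTable(
            counts=np.array([[k, GROUP_N - k] for k in ks]),
            row_labels=STAGE_GROUPS,
            col_labels=["yes", "no"],
        )
        for var, ks in _CATEGORICAL.items()
    }
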