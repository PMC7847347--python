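"""Segmentation agreement and cohort-balance statistics.

The Dice similarity coefficient (DSC) quantifies overlap between two binary
tumor masks: ``2|A n B| / (|A| + |B|)``, 0 for disjoint and 1 for identical
masks.  Cohort balance between training and validation subsets is tested per
variable: 2 x k chi-square without continuity correction for categorical
variables (Fisher's exact test on 2 x 2 tables when any expected count falls
below 5) and the classical equal-variance two-sample t-test for continuous
variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DiceResult:
    dsc: float
    size_a: int
    size_b: int
    intersection: int


@dataclass
class VariableTest:
    variable: str
    kind: str       # "categorical" | "continuous"
    test: str       # "chi-square" | "fisher" | "t-test" | "skipped"
    statistic: float
    p_value: float
    note: str = ""


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> DiceResult:
    """Dice similarity coefficient of two same-shape binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("both masks are empty; DSC is undefined")
    inter = int((a & b).sum())
    return DiceResult(2.0 * inter / (na + nb), na, nb, inter)


def _categorical_test(variable: str, train, validation) -> VariableTest:
    levels = sorted(set(train) | set(validation))
    if len(levels) < 2:
        return VariableTest(variable, "categorical", "skipped", np.nan, np.nan,
                            "single level overall")
    table = np.array(
        [
            [int(np.sum(np.asarray(train) == lv)) for lv in levels],
            [int(np.sum(np.asarray(validation) == lv)) for lv in levels],
        ]
    )
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any() and table.shape == (2, 2):
        odds, p = stats.fisher_exact(table)
        return VariableTest(variable, "categorical", "fisher", float(odds), float(p),
                            "expected count < 5")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    note = "expected count < 5" if (expected < 5).any() else ""
    return VariableTest(variable, "categorical", "chi-square", float(chi2), float(p), note)


def _continuous_test(variable: str, train, validation) -> VariableTest:
    t, p = stats.ttest_ind(np.asarray(train, float), np.asarray(validation, float),
                           equal_var=True)
    return VariableTest(variable, "continuous", "t-test", float(t), float(p))


def cohort_balance(
    characteristics: pd.DataFrame,
    train_ids,
    validation_ids,
    continuous: tuple[str, ...] = ("age",),
) -> list[VariableTest]:
    """Compare each characteristic between training and validation cohorts.

    ``characteristics`` is indexed by subject id; columns named in
    ``continuous`` use the t-test, all others are treated as categorical.
    """
    train = characteristics.loc[list(train_ids)]
    validation = characteristics.loc[list(validation_ids)]
    report = []
    for col in characteristics.columns:
        if col in continuous:
            report.append(_continuous_test(col, train[col], validation[col]))
        else:
            report.append(_categorical_test(col, train[col], validation[col]))
    return report
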