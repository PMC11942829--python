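"""Paired statistical comparison of denoising methods and age stratification.

Per-image metric values of two methods are compared with a paired test:
Shapiro-Wilk on the pair differences (alpha 0.05) decides between the
paired t-test (normal differences) and the Wilcoxon signed-rank test
(non-normal), both two-tailed.  No multiplicity correction is applied to
the pairwise tables by default, with a Holm-corrected view behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedComparison", "choose_test", "paired_compare",
    "pairwise_table", "age_group_summary",
]

_ALPHA_NORMALITY = 0.05


@dataclass(frozen=True)
class PairedComparison:
    method_a: str
    method_b: str
    metric: str
    test_used: Literal["t", "wilcoxon", "none"]
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value == self.p_value and self.p_value < 0.05

    @property
    def degenerate(self) -> bool:
        return self.test_used == "none"


def choose_test(differences: Sequence[float]) -> str:
    """Pick 't' or 'wilcoxon' from a Shapiro-Wilk test on the differences."""
    differences = np.asarray(differences, dtype=float)
    if differences.size < 3:
        raise ValueError("need at least 3 paired differences")
    if np.all(differences == differences[0]):
        # constant differences: normality is undefined, flag upstream
        raise ValueError("degenerate (constant) differences; no test applies")
    p_normal = sps.shapiro(differences).pvalue
    return "t" if p_normal >= _ALPHA_NORMALITY else "wilcoxon"


def _wilcoxon_pvalue(differences: np.ndarray) -> float:
    """Two-tailed signed-rank p; exact null distribution for n <= 25
    (zero differences dropped first), normal approximation with continuity
    correction above."""
    nonzero = differences[differences != 0.0]
    method = "exact" if nonzero.size <= 25 else "approx"
    try:
        result = sps.wilcoxon(nonzero, alternative="two-sided",
                              zero_method="wilcox", method=method,
                              correction=(method == "approx"))
    except ValueError:
        # ties force the approximate path even at small n
        result = sps.wilcoxon(nonzero, alternative="two-sided",
                              zero_method="wilcox", method="approx",
                              correction=True)
    return float(result.pvalue)


def paired_compare(a: Sequence[float], b: Sequence[float],
                   method_a: str = "a", method_b: str = "b",
                   metric: str = "") -> PairedComparison:
    """Two-tailed paired comparison of aligned per-image metric values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must be aligned")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    diff = a - b
    if np.all(diff == 0.0):
        return PairedComparison(method_a, method_b, metric, "none",
                                float("nan"), a.size)
    if np.all(diff == diff[0]):
        # constant non-zero shift: normality untestable, fall back to ranks
        test = "wilcoxon"
    else:
        test = choose_test(diff)
    if test == "t":
        p = float(sps.ttest_rel(a, b).pvalue)
    else:
        p = _wilcoxon_pvalue(diff)
    return PairedComparison(method_a, method_b, metric, test, p, a.size)


def pairwise_table(metric_by_method: Dict[str, Sequence[float]],
                   metric: str = "", holm: bool = False) -> pd.DataFrame:
    """Upper-triangular p-value matrix over all unordered method pairs.

    Rows/columns follow the insertion order of ``metric_by_method``; the
    diagonal and lower triangle are NaN.  ``holm`` applies the Holm
    step-down correction across the table's comparisons.
    """
    methods = list(metric_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    n_obs = {len(np.asarray(v)) for v in metric_by_method.values()}
    if len(n_obs) != 1:
        raise ValueError("per-image metric vectors must be aligned")
    comparisons = [
        paired_compare(metric_by_method[a], metric_by_method[b], a, b, metric)
        for a, b in combinations(methods, 2)
    ]
    p_values = np.array([c.p_value for c in comparisons])
    if holm:
        order = np.argsort(p_values)
        m = p_values.size
        adjusted = np.empty_like(p_values)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p_values[idx]))
            adjusted[idx] = running
        p_values = adjusted
    table = pd.DataFrame(np.nan, index=methods, columns=methods)
    for comparison, p in zip(comparisons, p_values):
        table.loc[comparison.method_a, comparison.method_b] = p
    return table


def significance_flags(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Boolean mask of the table where p < alpha (NaN-safe)."""
    return table < alpha


def age_group_summary(reports: pd.DataFrame, group_width_years: int = 3,
                      metrics: Sequence[str] = ("snr_right", "snr_left", "ms_ssim"),
                      ) -> pd.DataFrame:
    """Per-age-group mean and standard deviation of each metric per method.

    Groups are [0, w), [w, 2w), ... covering ages 0-17; empty groups are
    simply absent from the output.
    """
    if "age" not in reports or reports["age"].isna().any():
        raise ValueError("every report row needs an age")
    if group_width_years < 1:
        raise ValueError("group width must be at least one year")
    edges = np.arange(0, 17 + group_width_years, group_width_years, dtype=float)
    edges[-1] = max(edges[-1], 17.0 + 1e-9)
    frame = reports.copy()
    labels = [f"[{int(lo)},{int(hi)})" for lo, hi in zip(edges[:-1], edges[1:])]
    frame["age_group"] = pd.cut(frame["age"], bins=edges, right=False,
                                labels=labels, include_lowest=True)
    keys = ["method", "age_group"] if "method" in frame else ["age_group"]
    grouped = frame.groupby(keys, observed=True)[list(metrics)].agg(["mean", "std"])
    return grouped
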