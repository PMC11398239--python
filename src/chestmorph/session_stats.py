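"""Inter-session paired comparison with a normality-driven test choice.

Each group (one value per subject) is checked with the Shapiro-Wilk test; if
both groups look normal at alpha the groups are compared with a paired
two-sided t-test, otherwise with the Wilcoxon signed-rank test on the pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PairedComparison:
    group_a: np.ndarray
    group_b: np.ndarray
    test: str                     # "paired-t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    alpha: float
    df: int | None                # t-test degrees of freedom, None for Wilcoxon
    normality_p: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> str:
        if self.test == "paired-t":
            head = f"t({self.df}) = {self.statistic:.2f}"
        elif self.test == "wilcoxon":
            head = f"W = {self.statistic:.0f}"
        else:
            head = "degenerate (all differences zero)"
        return f"{head}, p = {self.p_value:.2f}"


def compare_paired(a, b, alpha: float = 0.05) -> PairedComparison:
    """Shapiro-Wilk on each group, then paired t-test or Wilcoxon fallback."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D groups with at least 3 pairs")
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    if np.all(a == b):
        warnings.warn("all paired differences are zero: degenerate comparison",
                      stacklevel=2)
        return PairedComparison(a, b, "degenerate", 0.0, 1.0, alpha, None, (sw_a, sw_b))
    if sw_a > alpha and sw_b > alpha:
        res = stats.ttest_rel(a, b)
        return PairedComparison(a, b, "paired-t", float(res.statistic),
                                float(res.pvalue), alpha, len(a) - 1, (sw_a, sw_b))
    res = stats.wilcoxon(a, b)
    return PairedComparison(a, b, "wilcoxon", float(res.statistic),
                            float(res.pvalue), alpha, None, (sw_a, sw_b))
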