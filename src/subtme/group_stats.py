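"""Two-group and k-group nonparametric comparisons used throughout.

Two groups: two-sided Wilcoxon rank-sum (exact for small tie-free samples,
tie-corrected normal approximation otherwise). Three or more groups:
Kruskal-Wallis. Batched p-values are adjusted by Benjamini-Hochberg or
Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError


@dataclass
class GroupComparison:
    statistic_name: str
    statistic: float
    p: float
    group_sizes: dict[str, int]


def compare_groups(values, labels) -> GroupComparison:
    """Rank-based comparison of values across label groups.

    Dispatches on the number of groups: 2 -> Wilcoxon rank-sum,
    >= 3 -> Kruskal-Wallis. One group is an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValidationError("values and labels must align")
    groups = [values[labels == g] for g in pd.unique(labels)]
    sizes = {str(g): int((labels == g).sum()) for g in pd.unique(labels)}
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("empty group")
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method="auto")
        return GroupComparison("wilcoxon", float(res.statistic), float(res.pvalue), sizes)
    res = stats.kruskal(*groups)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return GroupComparison("kruskal", float(res.statistic), p, sizes)


def adjust_batch(p_values, method: str = "bh") -> np.ndarray:
    """Adjust a batch of p-values (step-up BH or Bonferroni)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]
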