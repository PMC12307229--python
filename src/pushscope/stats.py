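"""Thin wrappers over the hypothesis tests commonly reported on these tables."""

from __future__ import annotations

import numpy as np
from scipy import stats


def compare_groups(a, b, test: str = "mannwhitney") -> dict[str, float]:
    """Two-group comparison of scalar measurements.

    ``test``: ``mannwhitney`` (two-sided, default), ``ttest`` (Welch), or
    ``fisher`` (2x2 counts: pass ``a``/``b`` as (successes, failures)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "fisher":
        res = stats.fisher_exact([a.astype(int), b.astype(int)])
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"statistic": float(res[0]), "p_value": float(res[1])}


def normality(x) -> dict[str, float]:
    """D'Agostino-Pearson omnibus normality test."""
    stat, p = stats.normaltest(np.asarray(x, dtype=float))
    return {"statistic": float(stat), "p_value": float(p)}
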