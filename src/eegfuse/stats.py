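"""Group statistics: per-feature one-way ANOVA with Bonferroni correction.

Each feature (a band's relative power, or an electrode's permutation
entropy) is tested for a group difference with a one-way ANOVA; for two
groups the F statistic has (1, n1+n2-2) degrees of freedom and equals
the square of the pooled two-sample t statistic. Because a family of
features is tested jointly (six bands, or six electrodes), p-values are
Bonferroni-corrected: p_corrected = min(1, p * k) for a family of k
tests, with significance reported at alpha = 0.01 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["GroupTestResult", "anova_oneway", "bonferroni", "compare_groups"]


@dataclass
class GroupTestResult:
    feature: str
    f_value: float
    p_value: float
    p_corrected: float
    n_comparisons: int
    significant: bool
    alpha: float = 0.01


def anova_oneway(values_group1: np.ndarray, values_group2: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p for two groups of observations."""
    g1 = np.asarray(values_group1, dtype=float).ravel()
    g2 = np.asarray(values_group2, dtype=float).ravel()
    for i, g in enumerate((g1, g2), 1):
        if g.size < 2:
            raise ValueError(f"group {i} needs >= 2 observations, got {g.size}")
    if np.var(g1) == 0 and np.var(g2) == 0:
        if g1.mean() == g2.mean():
            return 0.0, 1.0
        raise ValueError("both groups are constant with different means: F is undefined")
    f, p = _sps.f_oneway(g1, g2)
    return float(f), float(p)


def bonferroni(
    p_values: Sequence[float],
    alpha: float = 0.01,
    n_comparisons: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: p_corrected = min(1, p * k).

    ``n_comparisons`` defaults to the number of p-values (the family
    size). Returns (corrected p-values, significance flags at alpha).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p) if n_comparisons is None else int(n_comparisons)
    if k < 1:
        raise ValueError(f"n_comparisons must be >= 1, got {k}")
    p_corr = np.minimum(1.0, p * k)
    return p_corr, p_corr < alpha


def compare_groups(
    group1: np.ndarray,
    group2: np.ndarray,
    feature_names: Sequence[str] | None = None,
    alpha: float = 0.01,
) -> list[GroupTestResult]:
    """ANOVA + Bonferroni for every column of two subjects x features matrices.

    The family size for correction is the number of features tested
    (e.g. 6 bands or 6 electrodes). Both raw and corrected p-values are
    reported.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.shape[1] != g2.shape[1]:
        raise ValueError("groups must have the same features")
    k = g1.shape[1]
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError(f"{len(names)} feature names for {k} features")
    fs, ps = zip(*(anova_oneway(g1[:, j], g2[:, j]) for j in range(k)))
    p_corr, sig = bonferroni(ps, alpha=alpha)
    return [
        GroupTestResult(
            feature=names[j],
            f_value=fs[j],
            p_value=ps[j],
            p_corrected=float(p_corr[j]),
            n_comparisons=k,
            significant=bool(sig[j]),
            alpha=alpha,
        )
        for j in range(k)
    ]
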