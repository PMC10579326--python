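"""Nonparametric comparison stack for rate tables.

Normality is screened with Shapiro-Wilk (a gate justifying the
nonparametric path, not a branch), group differences with Kruskal-Wallis,
pairwise contrasts with one-sided Wilcoxon rank-sum tests under
Benjamini-Hochberg adjustment, and exploratory associations with Spearman
rank correlation.  All tests are delegated to scipy / statsmodels; this
module fixes the conventions (exact vs asymptotic Wilcoxon, tie handling,
adjustment scope) so every caller applies the same stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "shapiro_wilk",
    "kruskal_wallis",
    "kruskal_wallis_permutation_p",
    "pairwise_wilcoxon_bh",
    "spearman_screen",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal-Wallis omnibus result plus BH-adjusted pairwise contrasts."""

    H: float
    df: int
    p: float
    pairwise: pd.DataFrame  # rows (group_a, group_b, alternative, p_raw, p_adj)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p)."""
    values = np.asarray(values, float)
    if values.size < 3:
        raise InsufficientDataError("Shapiro-Wilk needs n >= 3")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H (tie-corrected), df = k - 1, chi-squared p."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InsufficientDataError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), df, float(p)


def kruskal_wallis_permutation_p(groups: Sequence[Sequence[float]],
                                 max_total: int = 12) -> float:
    """Exact permutation p-value for the Kruskal-Wallis H at small n.

    Enumerates every assignment of the pooled observations to the group
    sizes (multinomial coefficient of the total); feasible for pooled
    n <= ``max_total``.  The chi-squared p of :func:`kruskal_wallis` is an
    approximation; this is the exact reference at desk scale.
    """
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    if pooled.size > max_total:
        raise ValueError(f"enumeration limited to pooled n <= {max_total}")
    sizes = [len(g) for g in arrays]
    H_obs, _, _ = kruskal_wallis(arrays)
    idx = np.arange(pooled.size)

    def assignments(remaining, sizes_left):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in assignments(rest, sizes_left[1:]):
                yield (combo,) + tail

    count = total = 0
    for assign in assignments(tuple(idx), sizes):
        gs = [pooled[list(c)] for c in assign]
        H, _, _ = kruskal_wallis(gs)
        count += H >= H_obs - 1e-12
        total += 1
    return count / total


def _wilcoxon_rank_sum(x, y, alternative: str) -> float:
    """One Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both groups have n <= 10 and the pooled
    data is tie-free; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative,
                                    method=method).pvalue)


def pairwise_wilcoxon_bh(
    groups: Mapping[str, Sequence[float]],
    alternatives: Mapping[tuple[str, str], str] | str = "two-sided",
) -> pd.DataFrame:
    """All pairwise Wilcoxon rank-sum tests with BH adjustment.

    ``alternatives`` is either one alternative for every pair or a mapping
    ``(group_a, group_b) -> {"less", "greater", "two-sided"}`` read as the
    position of ``group_a`` relative to ``group_b``.  The BH step-up
    adjustment is applied once across all pairs tested.
    """
    names = list(groups)
    rows = []
    for a, b in combinations(names, 2):
        if isinstance(alternatives, str):
            alt = alternatives
        else:
            alt = alternatives.get((a, b))
            if alt is None:
                flipped = alternatives.get((b, a), "two-sided")
                alt = {"less": "greater", "greater": "less"}.get(flipped,
                                                                 flipped)
        p = _wilcoxon_rank_sum(groups[a], groups[b], alt)
        rows.append((a, b, alt, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "alternative",
                                      "p_raw"])
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alternatives: Mapping[tuple[str, str], str] | str = "two-sided",
) -> GroupTestResult:
    """Omnibus Kruskal-Wallis plus BH-adjusted pairwise Wilcoxon tests."""
    H, df, p = kruskal_wallis(list(groups.values()))
    pairwise = pairwise_wilcoxon_bh(groups, alternatives)
    return GroupTestResult(H=H, df=df, p=p, pairwise=pairwise)


def spearman_screen(table: pd.DataFrame, min_n: int = 4) -> pd.DataFrame:
    """Spearman rank correlation for every column pair.

    Censored/missing entries must already be NaN; each pair uses its
    complete cases and pairs with fewer than ``min_n`` of them are reported
    as not estimable (NaN rho/p).  Ties receive average ranks.
    """
    cols = list(table.columns)
    rows = []
    for a, b in combinations(cols, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < min_n:
            rows.append((a, b, np.nan, np.nan, len(sub)))
            continue
        rho, p = stats.spearmanr(sub[a], sub[b])
        rows.append((a, b, float(rho), float(p), len(sub)))
    return pd.DataFrame(rows, columns=["param_a", "param_b", "rho", "p", "n"])


__all__.append("compare_groups")
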