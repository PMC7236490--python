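"""Distributional summaries and group comparisons of p9 methylation.

Implements the non-parametric battery applied per site: a Kolmogorov-
Smirnov check against normality, Spearman correlation of methylation
across the 11 sites, and Kruskal-Wallis comparisons between the four
diagnosis groups — the omnibus 4-group test plus all six pairwise
two-group tests with Bonferroni correction within the site (x6; the 11
site-level families are deliberately not pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUP_ORDER = ("NC", "AD", "PSP", "PA")
PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(GROUP_ORDER, 2))
N_PAIRS = len(PAIRS)  # Bonferroni factor within a site


@dataclass
class GroupComparison:
    """Per-site group summary: means +/- SD and the KW p-value matrix."""

    position: int
    group_stats: dict[str, tuple[float, float, int]]     # group -> (mean, sd, n)
    overall_h: float
    overall_p: float
    pairwise_raw: dict[tuple[str, str], float]
    pairwise_adj: dict[tuple[str, str], float]
    flags: tuple[str, ...] = ()

    def min_pairwise_adj(self) -> float:
        return min(self.pairwise_adj.values()) if self.pairwise_adj else float("nan")


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """One-sample KS test against a Normal fitted to the sample.

    Returns (D, p). Requires >= 8 non-missing values with nonzero variance.
    Note the fitted-parameter composite null makes the p-value conservative
    (Lilliefors situation), which suffices for a gross non-normality check.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise ValueError(f"need >= 8 non-missing values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("all values identical: KS test undefined at zero variance")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(
    matrix: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rho and p across the site columns.

    Average (mid)ranks for ties; p from the t approximation with the
    pairwise sample size. Cells with fewer than ``min_pairs`` complete
    pairs are left missing.
    """
    cols = list(matrix.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols, dtype=float)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols, dtype=float)
    np.fill_diagonal(pval.values, 0.0)
    for i, j in combinations(range(k), 2):
        x, y = matrix.iloc[:, i], matrix.iloc[:, j]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < min_pairs:
            r = p = float("nan")
        else:
            r, p = stats.spearmanr(x[ok], y[ok])
            r, p = float(r), float(p)
        rho.iloc[i, j] = rho.iloc[j, i] = r
        pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval


def _clean_groups(
    values: Sequence[float], groups: Sequence[str]
) -> dict[str, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    ok = ~np.isnan(v)
    out: dict[str, np.ndarray] = {}
    for name in dict.fromkeys(g[ok]):
        out[name] = v[ok & (g == name)]
    return out


def kruskal_overall(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across all groups, chi2 p on k-1 df."""
    by_group = _clean_groups(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in by_group.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 non-missing values")
    pooled = np.concatenate(list(by_group.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical: H undefined")
    h, p = stats.kruskal(*by_group.values())
    return float(h), float(p)


def pairwise_kw(
    values: Sequence[float],
    groups: Sequence[str],
    position: int = 0,
    group_order: Sequence[str] = GROUP_ORDER,
) -> GroupComparison:
    """All pairwise two-group Kruskal-Wallis tests, Bonferroni x6 per site.

    The two-group KW test is the tie-corrected Wilcoxon rank-sum on the
    chi-square scale. Missing groups reduce to the available pairs and set
    a flag; the Bonferroni factor stays 6 when all four groups are present,
    else the number of computed pairs.
    """
    by_group = _clean_groups(values, groups)
    present = [g for g in group_order if g in by_group and by_group[g].size >= 2]
    flags = []
    missing = [g for g in group_order if g not in present]
    if missing:
        flags.append("missing_groups:" + ",".join(missing))
    if len(present) < 2:
        raise ValueError("need at least 2 groups with n >= 2")

    stats_per_group = {
        g: (float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else float("nan"), int(a.size))
        for g, a in by_group.items()
    }
    pairs = list(combinations(present, 2))
    factor = N_PAIRS if len(present) == len(GROUP_ORDER) else len(pairs)
    raw: dict[tuple[str, str], float] = {}
    adj: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        try:
            _, p = stats.kruskal(by_group[a], by_group[b])
        except ValueError:  # all values identical in the pair
            p = 1.0
        raw[(a, b)] = float(p)
        adj[(a, b)] = min(1.0, float(p) * factor)
    try:
        h_all, p_all = kruskal_overall(values, groups)
    except ValueError:
        h_all, p_all = float("nan"), float("nan")
    return GroupComparison(
        position=position,
        group_stats=stats_per_group,
        overall_h=h_all,
        overall_p=p_all,
        pairwise_raw=raw,
        pairwise_adj=adj,
        flags=tuple(flags),
    )


def table_by_site(
    matrix: pd.DataFrame, meta: pd.DataFrame, group_col: str = "diagnosis"
) -> pd.DataFrame:
    """Per-site summary table: group mean +/- SD, omnibus p and the six
    adjusted pairwise p-values (one row per site).

    Both the 4-group omnibus KW p and the minimum adjusted pairwise p are
    emitted, labeled, since either reading of an "overall" column is
    defensible.
    """
    meta = meta.loc[matrix.index]
    groups = meta[group_col].to_numpy()
    rows = []
    for pos in matrix.columns:
        cmp_ = pairwise_kw(matrix[pos].to_numpy(), groups, position=int(pos))
        row: dict[str, object] = {"position": int(pos)}
        for g in GROUP_ORDER:
            mean, sd, n = cmp_.group_stats.get(g, (float("nan"), float("nan"), 0))
            row[f"{g}_mean"] = mean
            row[f"{g}_sd"] = sd
            row[f"{g}_n"] = n
        row["omnibus_H"] = cmp_.overall_h
        row["omnibus_p"] = cmp_.overall_p
        row["min_pairwise_adj_p"] = cmp_.min_pairwise_adj()
        for (a, b) in PAIRS:
            row[f"p_{a}_vs_{b}_adj"] = cmp_.pairwise_adj.get((a, b), float("nan"))
        row["flags"] = ";".join(cmp_.flags)
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")


def site_boxplots(matrix: pd.DataFrame, meta: pd.DataFrame, path: str | Path,
                  group_col: str = "diagnosis") -> None:
    """Simple per-site AAF boxplots by diagnosis group (one panel per site)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = meta.loc[matrix.index]
    n = len(matrix.columns)
    ncol = 4
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    for ax, pos in zip(axes.ravel(), matrix.columns):
        data = [
            matrix.loc[meta[group_col] == g, pos].dropna() for g in GROUP_ORDER
        ]
        ax.boxplot(data, tick_labels=GROUP_ORDER)
        ax.set_title(f"site {pos}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
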