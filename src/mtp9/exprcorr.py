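"""Expression normalisation and correlation with site-585 methylation.

TMM (trimmed mean of M-values) scaling factors are computed from scratch
following the published definition used by edgeR's ``calcNormFactors``:
the reference library is the one whose 75th count percentile (on the
library-size scale) is closest to the mean; per library, M (log2 ratio)
and A (average log2 abundance) values are formed on library-size-
normalised proportions over genes expressed in both libraries, the M
distribution is trimmed 30% on each side and the A distribution 5%, and
the factor is 2 to the precision-weighted mean M (inverse asymptotic
binomial variance weights). Factors are rescaled to geometric mean 1.

Downstream: CPM, a vectorised per-transcript Spearman screen against the
site-585 AAF with Benjamini-Hochberg FDR, top-set selection by |rho|, and
the visualisation math (unit-variance scaling, correlation-distance
average-linkage clustering, sample PCA).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM factor of one library against the reference library."""
    n_o, n_r = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_o) / (ref / n_r))
        abs_e = (np.log2(obs / n_o) + np.log2(ref / n_r)) / 2.0
        v = (n_o - obs) / (n_o * obs) + (n_r - ref) / (n_r * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame, weighted: bool = True) -> pd.Series:
    """Per-sample TMM normalisation factors (geometric mean 1).

    ``counts`` is transcripts x samples with non-negative integer counts;
    a sample with an all-zero library is rejected. ``weighted`` applies the
    inverse asymptotic-variance weights of the published algorithm; note
    the weights are computed on raw counts, so with weighting the factors
    are only asymptotically (not exactly) invariant to rescaling a single
    library, exactly as in the reference implementation.
    """
    x = counts.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = x.sum(axis=0)
    if (libsize == 0).any():
        bad = counts.columns[libsize == 0]
        raise ValueError(f"sample(s) with all-zero counts: {', '.join(map(str, bad))}")
    f75 = np.quantile(x, 0.75, axis=0) / libsize
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = x[:, ref_idx]
    factors = np.array(
        [_tmm_pair(x[:, j], ref, weighted=weighted) for j in range(x.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, log: bool = False
) -> pd.DataFrame:
    """Counts per million on effective library sizes (library x factor)."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.loc[counts.columns]
    out = counts.div(lib, axis=1) * 1e6
    if log:
        out = np.log2(out + 0.5)
    return out


def correlate_with_methylation(
    norm: pd.DataFrame, aaf_585: pd.Series, min_pairs: int = 10
) -> pd.DataFrame:
    """Spearman correlation of every transcript with site-585 methylation.

    Vectorised: midranks per transcript over the complete-case samples,
    Pearson on ranks, p from the t approximation, BH-FDR across the
    non-constant transcripts. Returns a frame indexed by transcript with
    rho/p/q/rank, ranked by |rho| (p as tie-break); constant transcripts
    carry NaN statistics and no rank.
    """
    shared = norm.columns.intersection(aaf_585.index)
    y = aaf_585.loc[shared]
    ok = y.notna()
    if int(ok.sum()) < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, got {int(ok.sum())}")
    x = norm.loc[:, shared.to_numpy()[ok.to_numpy()]].to_numpy(float)
    yv = y[ok].to_numpy(float)
    n = yv.size

    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(yv)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    sx = np.sqrt((rx_c**2).sum(axis=1))
    sy = np.sqrt((ry_c**2).sum())
    const = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx_c @ ry_c) / (sx * sy)
    rho[const] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[const] = np.nan

    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    out = pd.DataFrame(
        {"rho": rho, "p": p, "q": q, "n": n}, index=norm.index
    )
    out.index.name = "transcript"
    ranked = out[valid].sort_values(
        by=["p"], kind="mergesort"
    ).sort_values(by="rho", key=lambda s: -s.abs(), kind="mergesort")
    out["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1), index=ranked.index, dtype="float"
    )
    return out


def select_top(
    correlations: pd.DataFrame,
    n: int = 1000,
    t2g: pd.DataFrame | None = None,
) -> tuple[list[str], list[str]]:
    """Top-n transcripts by |rho| (p tie-break) and their unique genes.

    Requires the ``rank`` column from :func:`correlate_with_methylation`.
    Returns all available transcripts with a warning if n exceeds them.
    """
    ranked = correlations.dropna(subset=["rank"]).sort_values("rank")
    if n > len(ranked):
        warnings.warn(
            f"requested top {n} but only {len(ranked)} ranked transcripts available"
        )
        n = len(ranked)
    top = list(ranked.index[:n])
    genes: list[str] = []
    if t2g is not None and top:
        genes = list(dict.fromkeys(t2g.loc[top, "gene"]))
    return top, genes


def unit_variance_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to unit variance; zero-variance rows are
    dropped with a warning."""
    x = matrix.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = sd.ravel() == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zero-variance row(s)")
    scaled = (x[~zero] - mu[~zero]) / sd[~zero]
    return pd.DataFrame(scaled, index=matrix.index[~zero], columns=matrix.columns)


def _corr_dist(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation distance between rows."""
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    d[d < 0] = 0.0
    return squareform(d, checks=False)


def heatmap_structure(matrix: pd.DataFrame) -> dict:
    """Clustering structure behind the expression heatmap.

    Rows (transcripts) are unit-variance scaled; rows and columns are
    clustered with average linkage on correlation distance (1 - Pearson r).
    Returns the scaled matrix, both scipy linkage matrices and leaf orders.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    scaled = unit_variance_scale(matrix)
    row_link = average(_corr_dist(scaled.to_numpy()))
    col_link = average(_corr_dist(scaled.to_numpy().T))
    return {
        "scaled": scaled,
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_order": [scaled.index[i] for i in leaves_list(row_link)],
        "col_order": [scaled.columns[i] for i in leaves_list(col_link)],
    }


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            bl = node.dist - child.dist
            parts.append(f"{walk(child)}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"

    return walk(tree) + ";"


def pca_samples(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of a row-scaled expression matrix via SVD.

    ``matrix`` is features x samples with rows already unit-variance scaled
    (so each feature is centered across samples). Returns (scores frame
    PC1..PCk indexed by sample, fraction of variance per component).
    """
    x = matrix.to_numpy(float).T  # samples x features
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    k = min(n_components, rank)
    var = s**2 / (s**2).sum()
    # deterministic sign: largest-magnitude score positive
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    frame = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, var[:k]
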