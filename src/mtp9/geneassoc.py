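"""Gene-based association of nuclear SNPs with p9 methylation.

The scan mirrors a standard gene-based GWAS of a quantitative trait:

1. phenotype = log10 methylation (AAF) at one p9 site;
2. genotype PCA for population-structure covariates (eigenvectors 1-10);
3. PLINK-style windowed LD pruning (``--indep-pairwise 50 5 0.2``);
4. per-SNP ordinary least squares adjusting for age, sex and eigenvectors;
5. positional SNP-to-gene mapping within a +/- 10 kb window;
6. gene-level aggregation of SNP p-values, by default a permutation-
   calibrated min-p statistic (Freedman-Lane residual permutation, which
   preserves LD between the SNPs of a gene) with a Sidak closed form as
   the fast alternative;
7. a Bonferroni genome-wide threshold of alpha / N_genes.

The multi-model MAGMA gene statistic is deliberately not replicated; the
permutation min-p test is the package's own, statistically explicit
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeMatrix:
    """SNP table (id, chrom, pos) plus a sample x SNP dosage matrix.

    Dosages are 0/1/2 alternate-allele counts; missing entries are NaN.
    """

    snps: pd.DataFrame       # index snp id; columns chrom, pos
    dosage: pd.DataFrame     # index sample; columns snp ids

    def __post_init__(self) -> None:
        if not self.snps.index.is_unique:
            raise ValueError("SNP ids must be unique")
        if list(self.snps.index) != list(self.dosage.columns):
            self.dosage = self.dosage[list(self.snps.index)]
        vals = self.dosage.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        """Read the PLINK-like TSV dialect: one row per SNP, columns
        snp/chrom/pos then one dosage column per sample."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        snps = df[["chrom", "pos"]].copy()
        snps["chrom"] = snps["chrom"].astype(str)
        dosage = df.drop(columns=["chrom", "pos"]).T.astype(float)
        dosage.index.name = "sample"
        return cls(snps=snps, dosage=dosage)


def _imputed_dosage(dosage: pd.DataFrame) -> np.ndarray:
    """Per-SNP mean imputation of missing dosages (float matrix)."""
    x = dosage.to_numpy(float)
    means = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x = x.copy()
    x[idx] = np.take(means, idx[1])
    return x


def pca_eigenvectors(
    geno: GenotypeMatrix, k: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k genotype eigenvectors for population-structure adjustment.

    SNPs are mean-imputed, centered at 2p and scaled by sqrt(2p(1-p)) with
    p the sample allele frequency (the usual genotype standardisation);
    monomorphic SNPs are skipped. Returns (sample x k eigenvector frame
    with orthonormal columns EV1..EVk ordered by eigenvalue, eigenvalues).
    """
    x = _imputed_dosage(geno.dosage)
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    x = (x[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    ev = pd.DataFrame(
        evecs, index=geno.dosage.index, columns=[f"EV{i + 1}" for i in range(k)]
    )
    return ev, evals


def ld_prune(
    geno: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> list[str]:
    """Greedy windowed LD pruning a la PLINK ``--indep-pairwise``.

    Slides a ``window``-SNP window by ``step`` along each chromosome
    (position order); while any kept pair in the window has squared
    composite-LD correlation r^2 > ``r2_max``, the member with the lower
    minor-allele frequency is dropped (ties drop the later SNP). r^2 is
    computed on mean-imputed centered dosages; the kept set has no
    within-window violating pair and is independent of sample order.
    """
    snps = geno.snps
    x = _imputed_dosage(geno.dosage)
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    p = x.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    col_of = {s: i for i, s in enumerate(geno.dosage.columns)}

    def r2(a: int, b: int) -> float:
        if norms[a] == 0 or norms[b] == 0:
            return 0.0  # monomorphic: undefined correlation, treated as unlinked
        r = float(xc[:, a] @ xc[:, b] / (norms[a] * norms[b]))
        return r * r

    kept_all: list[str] = []
    order = snps.sort_values(["chrom", "pos"], kind="mergesort")
    for _, chrom_snps in order.groupby("chrom", sort=True):
        ids = list(chrom_snps.index)
        alive = {s: True for s in ids}
        start = 0
        while start < len(ids):
            win = [s for s in ids[start : start + window] if alive[s]]
            changed = True
            while changed:
                changed = False
                for i in range(len(win)):
                    for j in range(i + 1, len(win)):
                        a, b = win[i], win[j]
                        if r2(col_of[a], col_of[b]) > r2_max:
                            drop = a if maf[col_of[a]] < maf[col_of[b]] else b
                            alive[drop] = False
                            win = [s for s in win if alive[s]]
                            changed = True
                            break
                    if changed:
                        break
            if start + window >= len(ids):
                break
            start += step
        kept_all.extend([s for s in ids if alive[s]])
    return kept_all


def log10_phenotype(aaf: pd.Series, offset: float | None = None) -> pd.Series:
    """log10(aaf + offset); default offset = half the smallest nonzero AAF.

    The offset guards the zero cells a finite-depth AAF can produce; it is
    0 when every value is positive.
    """
    x = aaf.astype(float)
    if offset is None:
        nz = x[(x > 0)]
        if len(nz) == 0:
            raise ValueError("all AAF values are zero or missing")
        offset = 0.0 if (x.dropna() > 0).all() else float(nz.min()) / 2.0
    return np.log10(x + offset)


def _design(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    cols = {"const": pd.Series(1.0, index=index)}
    if covariates is not None:
        for c in covariates.columns:
            cols[c] = covariates[c].astype(float)
    return pd.DataFrame(cols)


def _check_collinear(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    for j in range(1, x.shape[1]):
        if np.linalg.matrix_rank(x[:, : j + 1]) <= np.linalg.matrix_rank(x[:, :j]):
            raise ValueError(
                f"covariate {design.columns[j]!r} is collinear with the preceding columns"
            )
    raise ValueError("covariate matrix is rank deficient")


def snp_assoc(
    dosage: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS of phenotype on dosage plus covariates (with intercept).

    Complete-case over phenotype and covariates; missing dosages are
    mean-imputed per SNP. Implemented via Frisch-Waugh residualisation so
    thousands of SNPs share one covariate projection; the reported beta,
    SE, t and two-sided p are identical to the full OLS fit (matching df).
    Returns a frame indexed by SNP id with columns beta/se/t/p/n.
    """
    cov = _design(covariates, phenotype.index)
    keep = phenotype.notna() & cov.notna().all(axis=1)
    samples = phenotype.index[keep]
    if len(samples) < cov.shape[1] + 2:
        raise ValueError("too few complete-case samples for the design")
    y = phenotype.loc[samples].to_numpy(float)
    c = cov.loc[samples].to_numpy(float)
    _check_collinear(cov.loc[samples])
    x = _imputed_dosage(dosage.loc[samples])

    q, _ = np.linalg.qr(c)
    y_r = y - q @ (q.T @ y)
    x_r = x - q @ (q.T @ x)

    n = len(samples)
    df = n - c.shape[1] - 1
    sxx = (x_r**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (x_r * y_r[:, None]).sum(axis=0) / sxx
        rss = (y_r**2).sum() - beta**2 * sxx
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {"beta": beta, "se": se, "t": t, "p": p, "n": n}, index=dosage.columns
    )
    out.index.name = "snp"
    return out


def map_snps_to_genes(
    snps: pd.DataFrame, annotation: pd.DataFrame, window: int = 10_000
) -> dict[str, list[str]]:
    """Positional SNP-to-gene mapping within [start - window, end + window].

    ``snps``: frame indexed by snp id with chrom/pos; ``annotation``: frame
    indexed by gene id with chrom/start/end (1-based inclusive). A SNP may
    map to several overlapping genes; unmapped SNPs are simply absent.
    """
    mapping: dict[str, list[str]] = {}
    chrom = snps["chrom"].astype(str)
    pos = snps["pos"].astype(int)
    for gene, row in annotation.iterrows():
        lo, hi = int(row["start"]) - window, int(row["end"]) + window
        hit = snps.index[(chrom == str(row["chrom"])) & (pos >= lo) & (pos <= hi)]
        if len(hit):
            mapping[str(gene)] = list(hit)
    return mapping


def gene_p(
    snp_results: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]],
    method: str = "minp-perm",
    n_perm: int = 10_000,
    seed: int = 0,
    dosage: pd.DataFrame | None = None,
    phenotype: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    early_stop_exceedances: int = 50,
) -> pd.DataFrame:
    """Aggregate per-SNP p-values into gene-level p-values.

    ``sidak``: gene p = 1 - (1 - min p)^m with m the SNPs mapped to the
    gene (exact for independent SNPs, conservative under positive LD).

    ``minp-perm`` (default): the gene statistic is the largest absolute
    partial correlation of its SNPs with the phenotype; its null is built
    by permuting the covariate-residualised phenotype (Freedman-Lane),
    which preserves the LD between the gene's SNPs. Gene p =
    (1 + exceedances) / (1 + permutations), evaluated in batches with an
    early stop once every gene has ``early_stop_exceedances`` hits.
    Requires dosage/phenotype (and covariates as in the scan).

    Genes with no mapped SNP are omitted. The significance flag compares
    against 0.05 / N_genes over the genes reported.
    """
    genes = [g for g, snps_ in mapping.items() if len(snps_) > 0]
    if not genes:
        raise ValueError("no gene has mapped SNPs")
    rows = []
    if method == "sidak":
        for g in genes:
            sub = snp_results.loc[list(mapping[g])]
            m = len(sub)
            minp = float(sub["p"].min())
            top = sub["p"].idxmin()
            gp = 1.0 - (1.0 - minp) ** m
            gp = max(gp, minp)  # guard rounding at tiny p
            rows.append((g, m, gp, top, minp))
    elif method == "minp-perm":
        if dosage is None or phenotype is None:
            raise ValueError("minp-perm needs dosage and phenotype")
        cov = _design(covariates, phenotype.index)
        keep = phenotype.notna() & cov.notna().all(axis=1)
        samples = phenotype.index[keep]
        y = phenotype.loc[samples].to_numpy(float)
        c = cov.loc[samples].to_numpy(float)
        snp_ids = sorted({s for g in genes for s in mapping[g]})
        x = _imputed_dosage(dosage.loc[samples, snp_ids])
        q, _ = np.linalg.qr(c)
        y_r = y - q @ (q.T @ y)
        x_r = x - q @ (q.T @ x)
        xn = x_r / np.linalg.norm(x_r, axis=0).clip(min=1e-30)
        yn = y_r / np.linalg.norm(y_r)
        obs = np.abs(yn @ xn)                       # |partial corr| per SNP
        col = {s: i for i, s in enumerate(snp_ids)}
        gene_cols = [np.array([col[s] for s in mapping[g]]) for g in genes]
        obs_gene = np.array([obs[ix].max() for ix in gene_cols])

        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(genes), dtype=int)
        done = 0
        batch = max(200, min(n_perm, 2000))
        while done < n_perm:
            b = min(batch, n_perm - done)
            perm = np.empty((b, len(y_r)))
            for i in range(b):
                perm[i] = rng.permutation(y_r)
            perm /= np.linalg.norm(perm, axis=1, keepdims=True)
            corr = np.abs(perm @ xn)                # b x n_snps
            for gi, ix in enumerate(gene_cols):
                exceed[gi] += int((corr[:, ix].max(axis=1) >= obs_gene[gi]).sum())
            done += b
            if np.all(exceed >= early_stop_exceedances):
                break
        for gi, g in enumerate(genes):
            sub = snp_results.loc[list(mapping[g])]
            top = sub["p"].idxmin()
            gp = (1.0 + exceed[gi]) / (1.0 + done)
            rows.append((g, len(sub), gp, top, float(sub["p"].min())))
    else:
        raise ValueError(f"unknown method {method!r}")

    out = pd.DataFrame(rows, columns=["gene", "n_snps", "p", "top_snp", "top_snp_p"])
    # permutation p-values are discrete (resolution 1/(n_perm+1)); ties are
    # broken by the parametric min-p of the gene's top SNP
    out = out.set_index("gene").sort_values(["p", "top_snp_p"], kind="mergesort")
    thresh = bonferroni_threshold(len(out))
    out["significant"] = out["p"] < thresh
    out.attrs["threshold"] = thresh
    return out


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Genome-wide Bonferroni threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    return alpha / n_genes


def genomic_control_lambda(pvalues: Sequence[float]) -> float:
    """Genomic-control inflation factor: median chi2(1) quantile ratio."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def beta_for_power(
    n: int,
    maf: float,
    resid_sd: float,
    alpha: float,
    power: float = 0.8,
) -> float:
    """Additive effect size giving the stated analytic power for one SNP.

    Normal-theory two-sided test of the dosage coefficient: the effect with
    power ``power`` at level ``alpha`` is (z_{1-alpha/2} + z_power) * SE
    with SE = resid_sd / sqrt(n * 2 maf (1 - maf)).
    """
    se = resid_sd / np.sqrt(n * 2.0 * maf * (1.0 - maf))
    return float((stats.norm.isf(alpha / 2.0) + stats.norm.ppf(power)) * se)
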