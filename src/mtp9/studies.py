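"""Repeated-simulation calibration and recovery studies.

These functions run the pipeline's statistical machinery over many
independently seeded synthetic cohorts and summarise operating
characteristics: methylation-recovery error, type-I control of the
pairwise group tests, power to recover the AD/PSP hypermethylation
pattern, recovery of the planted causal gene by the permutation gene
test, and the false-discovery rate of a null expression screen. They are
shared by the test suite and the acceptance script so both report the
same computations.

All child seeds are spawned deterministically from one master seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import exprcorr, geneassoc, groupstats, p9quant, synth
from .sites import P9_POSITIONS, read_site_table


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def methylation_recovery_mae(
    seed: int = 1, cfg: synth.SimConfig | None = None, workdir: str | None = None
) -> float:
    """Mean |inferred AAF - true methylation| over a written cohort.

    Exercises the full file path: the cohort is written to disk, pileups
    are re-parsed with the Q20 filter and the AAF matrix is compared cell
    by cell against the generator's truth (depth 1000, rho = 1,
    eps = 0.001 by default).
    """
    if cfg is None:
        cfg = synth.SimConfig(seed=seed)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        truth = synth.simulate_cohort(cfg, tmp)
        sites = read_site_table(Path(tmp) / "sites.tsv")
        matrix, _ = p9quant.quantify_directory(Path(tmp) / "pileups", sites)
    err = np.abs(matrix.to_numpy() - truth.methyl_true.loc[matrix.index].to_numpy())
    return float(np.nanmean(err))


def pairwise_type_i_rate(
    n_reps: int = 200, seed: int = 1, cfg: synth.SimConfig | None = None
) -> float:
    """Fraction of Bonferroni-adjusted pairwise KW tests below 0.05 when
    every group shares the same methylation distribution."""
    if cfg is None:
        cfg = synth.SimConfig(methyl_shift=0.0)
    hits = total = 0
    for s in _child_seeds(seed, n_reps):
        meta, _, aaf = synth.simulate_aaf(cfg, seed=s)
        groups = meta["diagnosis"].to_numpy()
        for pos in P9_POSITIONS:
            cmp_ = groupstats.pairwise_kw(aaf[pos].to_numpy(), groups, position=pos)
            for p in cmp_.pairwise_adj.values():
                hits += p < 0.05
                total += 1
    return hits / total


def pattern_recovery_rate(
    n_seeds: int = 100, seed: int = 1, site: int = 585,
    cfg: synth.SimConfig | None = None,
) -> float:
    """Fraction of cohorts reproducing the headline contrast at one site:
    AD vs NC and PSP vs NC significant (adjusted p < 0.05), NC vs PA not.

    Defaults to the study's group sizes with a +0.05 methylation shift in
    AD and PSP.
    """
    if cfg is None:
        cfg = synth.study_sizes()
    ok = 0
    for s in _child_seeds(seed, n_seeds):
        meta, _, aaf = synth.simulate_aaf(cfg, seed=s)
        cmp_ = groupstats.pairwise_kw(
            aaf[site].to_numpy(), meta["diagnosis"].to_numpy(), position=site
        )
        adj = cmp_.pairwise_adj
        ok += (
            adj[("NC", "AD")] < 0.05
            and adj[("NC", "PSP")] < 0.05
            and adj[("NC", "PA")] >= 0.05
        )
    return ok / n_seeds


def analytic_causal_beta(
    cfg: synth.SimConfig, power: float = 0.8, calib_seed: int = 20_250_101,
    n_calib: int = 20, n_perm: int | None = 2000,
) -> float:
    """Causal effect size targeted at the stated gene-test power.

    The sampling SE of the causal SNP's coefficient is estimated
    empirically: ``n_calib`` null cohorts (causal_beta = 0) under a fixed
    calibration seed are run through the actual covariate-adjusted scan
    and the causal SNP's reported SEs are averaged. This folds in
    everything the closed form misses — the heavy left tail of the
    log10-Beta phenotype and the dosage variance absorbed by the genotype
    eigenvectors. The per-SNP significance level accounts for the
    Bonferroni gene threshold, the discreteness of a ``n_perm``-permutation
    p-value, the within-gene min-p multiplicity over the gene's SNPs
    (Sidak), and the requirement that the causal gene also outrank every
    null gene; the returned beta solves

        mean over calibration SEs of P(|T'(df, beta/SE)| > t_alpha) = target,

    with T' the noncentral t of the scan's residual df, i.e. ``power`` is
    the analytic average power of the full recovery event over the SE
    spread the cohorts actually exhibit.
    """
    from scipy import stats

    null_cfg = synth.SimConfig(**{**cfg.__dict__, "causal_beta": 0.0})
    ses = []
    for s in _child_seeds(calib_seed, n_calib):
        meta, _, aaf, geno = synth.simulate_aaf(null_cfg, seed=s, with_genotypes=True)
        gm = geneassoc.GenotypeMatrix(snps=geno["snps"], dosage=geno["dosage"])
        ev, _ = geneassoc.pca_eigenvectors(gm, k=10)
        pheno = geneassoc.log10_phenotype(aaf[585])
        covs = pd.concat(
            [meta[["age"]].astype(float),
             (meta["sex"] == "F").astype(float).rename("sex"), ev],
            axis=1,
        )
        res = geneassoc.snp_assoc(gm.dosage, pheno, covs)
        ses.append(float(res.loc[geno["causal_snp_id"], "se"]))
    n_genes = cfg.n_snps // cfg.snps_per_gene
    alpha_gene = 0.05 / n_genes
    if n_perm is not None:
        # the permutation p is discrete: significance needs at most
        # floor(alpha*(B+1)) - 1 exceedances, i.e. an effective level of
        # about (that count + 0.5)/B
        max_exceed = int(np.floor(alpha_gene * (n_perm + 1))) - 1
        alpha_gene = (max_exceed + 0.5) / n_perm
    # Sidak within the gene for the min-p multiplicity over its SNPs
    alpha_snp = 1.0 - (1.0 - alpha_gene) ** (1.0 / cfg.snps_per_gene)
    n = sum(cfg.group_sizes().values())
    df = n - 13 - 1  # intercept + age + sex + 10 EVs, then the dosage
    t_alpha = stats.t.isf(alpha_snp / 2.0, df)
    ses = np.asarray(ses)
    # a significant causal gene must additionally outrank the best of the
    # null genes, which claws back roughly the null genes' chance of an
    # equally extreme min-p near the operating threshold
    target = min(0.999, power / (1.0 - (n_genes - 1) * alpha_gene))

    def _nct_sf(t: float, ncp: np.ndarray) -> np.ndarray:
        # Johnson-Kotz normal approximation of the noncentral t survival
        # function; stable at any noncentrality, accurate for df >> 1
        num = ncp - t * (1.0 - 1.0 / (4.0 * df))
        den = np.sqrt(1.0 + t * t / (2.0 * df))
        return stats.norm.cdf(num / den)

    def mean_power(beta: float) -> float:
        ncp = beta / ses
        return float(np.mean(_nct_sf(t_alpha, ncp) + _nct_sf(t_alpha, -ncp)))

    from scipy.optimize import brentq

    hi = (t_alpha + 8.0) * float(ses.max())  # power is ~1 well before this
    return float(brentq(lambda b: mean_power(b) - target, 1e-8, hi))


def _scan_one_cohort(cfg: synth.SimConfig, seed: int, n_perm: int) -> tuple[str, pd.DataFrame]:
    """One full gene-based scan on an in-memory cohort; returns
    (causal gene id, gene-level results)."""
    meta, _, aaf, geno = synth.simulate_aaf(cfg, seed=seed, with_genotypes=True)
    gm = geneassoc.GenotypeMatrix(snps=geno["snps"], dosage=geno["dosage"])
    kept = geneassoc.ld_prune(gm)
    pruned = geneassoc.GenotypeMatrix(snps=gm.snps.loc[kept], dosage=gm.dosage[kept])
    ev, _ = geneassoc.pca_eigenvectors(pruned, k=10)
    pheno = geneassoc.log10_phenotype(aaf[585])
    covs = pd.concat(
        [meta[["age"]].astype(float),
         (meta["sex"] == "F").astype(float).rename("sex"), ev],
        axis=1,
    )
    snp_res = geneassoc.snp_assoc(pruned.dosage, pheno, covs)
    mapping = geneassoc.map_snps_to_genes(pruned.snps, geno["genes"])
    genes = geneassoc.gene_p(
        snp_res, mapping, method="minp-perm", n_perm=n_perm, seed=seed,
        dosage=pruned.dosage, phenotype=pheno, covariates=covs,
        early_stop_exceedances=50,
    )
    return geno["causal_gene"], genes


def causal_gene_recovery_rate(
    n_seeds: int = 50, n_perm: int = 2000, seed: int = 1,
    cfg: synth.SimConfig | None = None, power: float = 0.8,
) -> float:
    """Fraction of cohorts in which the planted gene attains the minimum
    gene p AND clears the Bonferroni threshold (permutation min-p test).

    The causal effect is sized for the stated analytic power via
    :func:`analytic_causal_beta`, at the study's sample size.
    """
    if cfg is None:
        cfg = synth.study_sizes()
    beta = analytic_causal_beta(cfg, power=power)
    cfg = synth.SimConfig(**{**cfg.__dict__, "causal_beta": beta})
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        causal, genes = _scan_one_cohort(cfg, s, n_perm)
        hits += (genes.index[0] == causal) and bool(genes.loc[causal, "significant"])
    return hits / n_seeds


def null_expression_fdr_rate(
    n_seeds: int = 100, seed: int = 1, cfg: synth.SimConfig | None = None
) -> float:
    """Mean fraction of transcripts at q < 0.05 when no transcript is
    linked to methylation (BH-FDR calibration of the expression screen)."""
    if cfg is None:
        cfg = synth.SimConfig(n_linked=0)
    fracs = []
    for s in _child_seeds(seed, n_seeds):
        meta, _, aaf = synth.simulate_aaf(cfg, seed=s)
        rng = np.random.default_rng(s + 1)
        counts = pd.DataFrame(
            synth._simulate_expression(cfg, rng, meta, aaf[585].to_numpy())[0]
        )
        norm = exprcorr.cpm(counts, exprcorr.tmm_factors(counts), log=True)
        corr = exprcorr.correlate_with_methylation(norm, aaf[585])
        fracs.append(float((corr["q"] < 0.05).mean()))
    return float(np.mean(fracs))
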