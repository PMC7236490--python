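"""Genotype PCA, LD pruning, SNP association and gene-level aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import ols_normal_equations
from mtp9 import geneassoc, synth
from mtp9.geneassoc import (
    GenotypeMatrix,
    bonferroni_threshold,
    gene_p,
    genomic_control_lambda,
    ld_prune,
    log10_phenotype,
    map_snps_to_genes,
    pca_eigenvectors,
    snp_assoc,
)


def _geno(dosage: np.ndarray, chrom="1", spacing=1000) -> GenotypeMatrix:
    n, m = dosage.shape
    ids = [f"rs{i}" for i in range(m)]
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": 1000 + spacing * np.arange(m)},
        index=pd.Index(ids, name="snp"),
    )
    dd = pd.DataFrame(dosage, index=[f"s{i}" for i in range(n)], columns=ids)
    return GenotypeMatrix(snps=snps, dosage=dd)


class TestPca:
    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(0)
        g = _geno(rng.binomial(2, 0.3, size=(40, 100)).astype(float))
        ev, evals = pca_eigenvectors(g, k=5)
        assert np.allclose(ev.T @ ev, np.eye(5), atol=1e-8)
        assert (np.diff(evals) <= 1e-9).all()

    def test_matches_dense_eigensolver_on_toy(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.4, size=(6, 8)).astype(float)
        ev, evals = pca_eigenvectors(_geno(x), k=2)
        # independent route: standardize and eigendecompose explicitly
        p = x.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        z = (x[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        w, v = np.linalg.eig(z @ z.T / keep.sum())
        order = np.argsort(w.real)[::-1]
        assert np.allclose(evals, w.real[order][:2], atol=1e-8)
        for j in range(2):
            assert abs(np.corrcoef(ev.iloc[:, j], v.real[:, order[j]])[0, 1]) > 1 - 1e-8

    def test_planted_subpopulations_separate_on_ev1(self):
        rng = np.random.default_rng(2)
        f1 = rng.uniform(0.1, 0.4, size=100)
        f2 = np.clip(f1 + 0.3, 0, 0.95)
        pop = np.r_[np.zeros(100), np.ones(100)]
        dosage = np.vstack([
            rng.binomial(2, f1, size=(100, 100)),
            rng.binomial(2, f2, size=(100, 100)),
        ]).astype(float)
        ev, _ = pca_eigenvectors(_geno(dosage), k=2)
        r = np.corrcoef(ev["EV1"], pop)[0, 1]
        assert abs(r) > 0.9


class TestLdPrune:
    def test_duplicated_adjacent_snp_leaves_one(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.3, size=(50, 1)).astype(float)
        others = rng.binomial(2, 0.3, size=(50, 4)).astype(float)
        dosage = np.hstack([base, base, others])
        kept = ld_prune(_geno(dosage))
        assert sum(k in ("rs0", "rs1") for k in kept) == 1

    def test_independent_snps_mostly_survive(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, rng.uniform(0.1, 0.5, 200),
                              size=(500, 200)).astype(float)
        kept = ld_prune(_geno(dosage))
        assert len(kept) >= 0.95 * 200

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        x = rng.binomial(2, 0.3, size=(60, 30)).astype(float)
        x[:, 5] = x[:, 6]  # force one removal
        g = _geno(x)
        kept = ld_prune(g)
        g2 = GenotypeMatrix(snps=g.snps.loc[kept], dosage=g.dosage[kept])
        assert ld_prune(g2) == kept

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(6)
        x = rng.binomial(2, 0.3, size=(80, 40)).astype(float)
        x[:, 10] = np.clip(x[:, 11] + rng.binomial(1, 0.05, 80), 0, 2)
        g = _geno(x)
        perm = rng.permutation(80)
        g_shuf = GenotypeMatrix(snps=g.snps, dosage=g.dosage.iloc[perm])
        assert ld_prune(g) == ld_prune(g_shuf)


class TestSnpAssoc:
    def test_exact_linear_relation_recovered(self):
        d = pd.DataFrame({"rs1": [0.0, 1, 2, 0, 1, 2]}, index=list("abcdef"))
        y = pd.Series([0.0, 0.5, 1.0, 0.0, 0.5, 1.0], index=list("abcdef"))
        res = snp_assoc(d, y)
        assert res.loc["rs1", "beta"] == pytest.approx(0.5)
        assert res.loc["rs1", "p"] < 1e-10

    def test_four_point_hand_example(self):
        d = pd.DataFrame({"rs1": [0.0, 1, 1, 2]}, index=list("abcd"))
        y = pd.Series([1.0, 2, 2, 3], index=list("abcd"))
        res = snp_assoc(d, y)
        assert res.loc["rs1", "beta"] == pytest.approx(1.0)
        assert res.loc["rs1", "p"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(20, 60))
            idx = [f"s{i}" for i in range(n)]
            dosage = pd.DataFrame(
                rng.binomial(2, 0.3, size=(n, 3)).astype(float),
                index=idx, columns=["rs1", "rs2", "rs3"],
            )
            covs = pd.DataFrame(rng.normal(size=(n, 2)), index=idx,
                                columns=["age", "sex"])
            y = pd.Series(rng.normal(size=n), index=idx)
            res = snp_assoc(dosage, y, covs)
            for snp in dosage.columns:
                x = np.column_stack([
                    np.ones(n), covs["age"], covs["sex"], dosage[snp],
                ])
                beta, se = ols_normal_equations(x, y.to_numpy())
                assert res.loc[snp, "beta"] == pytest.approx(beta[-1], abs=1e-8)
                assert res.loc[snp, "se"] == pytest.approx(se[-1], abs=1e-8)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        n = 200
        idx = [f"s{i}" for i in range(n)]
        dosage = pd.DataFrame(rng.binomial(2, 0.3, size=(n, 1000)).astype(float),
                              index=idx, columns=[f"rs{i}" for i in range(1000)])
        y = pd.Series(rng.normal(size=n), index=idx)
        res = snp_assoc(dosage, y)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_collinear_covariate_named(self):
        rng = np.random.default_rng(9)
        n = 30
        idx = [f"s{i}" for i in range(n)]
        dosage = pd.DataFrame({"rs1": rng.binomial(2, 0.3, n).astype(float)}, index=idx)
        age = rng.normal(size=n)
        covs = pd.DataFrame({"age": age, "age_copy": 2 * age}, index=idx)
        with pytest.raises(ValueError, match="age_copy"):
            snp_assoc(dosage, pd.Series(rng.normal(size=n), index=idx), covs)

    def test_genomic_control_lambda_near_one_under_null(self):
        rng = np.random.default_rng(10)
        n = 300
        idx = [f"s{i}" for i in range(n)]
        dosage = pd.DataFrame(rng.binomial(2, 0.3, size=(n, 2000)).astype(float),
                              index=idx, columns=[f"rs{i}" for i in range(2000)])
        y = pd.Series(rng.normal(size=n), index=idx)
        lam = genomic_control_lambda(snp_assoc(dosage, y)["p"])
        assert 0.9 <= lam <= 1.1


class TestLog10Phenotype:
    def test_offset_is_half_smallest_nonzero_when_zeros_present(self):
        aaf = pd.Series([0.0, 0.02, 0.1])
        out = log10_phenotype(aaf)
        assert out.iloc[0] == pytest.approx(np.log10(0.01))
        assert out.iloc[1] == pytest.approx(np.log10(0.03))

    def test_no_offset_when_all_positive(self):
        aaf = pd.Series([0.05, 0.2])
        assert log10_phenotype(aaf).iloc[0] == pytest.approx(np.log10(0.05))


class TestGeneMapping:
    def _annot(self):
        return pd.DataFrame(
            {"chrom": ["1", "1"], "start": [50_000, 58_000], "end": [60_000, 70_000]},
            index=pd.Index(["GA", "GB"], name="gene"),
        )

    @pytest.mark.parametrize("pos,mapped", [(40_000, True), (39_999, False)])
    def test_window_boundary_inclusive(self, pos, mapped):
        snps = pd.DataFrame({"chrom": ["1"], "pos": [pos]},
                            index=pd.Index(["rs1"], name="snp"))
        m = map_snps_to_genes(snps, self._annot(), window=10_000)
        assert ("rs1" in m.get("GA", [])) == mapped

    def test_snp_in_overlapping_genes_maps_to_both(self):
        snps = pd.DataFrame({"chrom": ["1"], "pos": [59_000]},
                            index=pd.Index(["rs1"], name="snp"))
        m = map_snps_to_genes(snps, self._annot(), window=0)
        assert "rs1" in m["GA"] and "rs1" in m["GB"]


class TestGeneP:
    def test_single_snp_sidak_equals_snp_p(self):
        res = pd.DataFrame({"p": [0.01], "beta": [1.0]},
                           index=pd.Index(["rs1"], name="snp"))
        out = gene_p(res, {"G1": ["rs1"]}, method="sidak")
        assert out.loc["G1", "p"] == pytest.approx(0.01)

    def test_sidak_null_gene_p_uniform_for_independent_snps(self):
        rng = np.random.default_rng(11)
        n, m = 150, 5000
        idx = [f"s{i}" for i in range(n)]
        dosage = pd.DataFrame(rng.binomial(2, 0.3, size=(n, m)).astype(float),
                              index=idx, columns=[f"rs{i}" for i in range(m)])
        y = pd.Series(rng.normal(size=n), index=idx)
        res = snp_assoc(dosage, y)
        mapping = {f"G{j}": [f"rs{i}" for i in range(10 * j, 10 * j + 10)]
                   for j in range(m // 10)}
        out = gene_p(res, mapping, method="sidak")
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01

    def test_perm_and_sidak_agree_for_independent_snps(self):
        rng = np.random.default_rng(12)
        n, m = 120, 40
        idx = [f"s{i}" for i in range(n)]
        dosage = pd.DataFrame(rng.binomial(2, 0.3, size=(n, m)).astype(float),
                              index=idx, columns=[f"rs{i}" for i in range(m)])
        y = pd.Series(rng.normal(size=n), index=idx)
        res = snp_assoc(dosage, y)
        mapping = {f"G{j}": [f"rs{i}" for i in range(5 * j, 5 * j + 5)]
                   for j in range(m // 5)}
        sidak = gene_p(res, mapping, method="sidak")
        n_perm = 4000
        perm = gene_p(res, mapping, method="minp-perm", n_perm=n_perm, seed=1,
                      dosage=dosage, phenotype=y,
                      early_stop_exceedances=n_perm)
        for g in mapping:
            ps, pp = sidak.loc[g, "p"], perm.loc[g, "p"]
            mc = 4 * np.sqrt(ps * (1 - ps) / n_perm) + 2 / n_perm
            assert abs(pp - ps) < mc + 0.02

    def test_causal_gene_recovered_with_large_effect(self):
        cfg = synth.SimConfig(n_per_group=40, causal_beta=0.3, seed=13)
        from mtp9.studies import _scan_one_cohort

        causal, genes = _scan_one_cohort(cfg, seed=99, n_perm=1000)
        assert genes.index[0] == causal
        assert bool(genes.loc[causal, "significant"])

    def test_gene_with_no_snps_omitted(self):
        res = pd.DataFrame({"p": [0.5], "beta": [0.0]},
                           index=pd.Index(["rs1"], name="snp"))
        out = gene_p(res, {"G1": ["rs1"], "G2": []}, method="sidak")
        assert list(out.index) == ["G1"]


class TestBonferroni:
    def test_reproduces_genome_wide_threshold(self):
        t = bonferroni_threshold(17079)
        assert t == pytest.approx(2.93e-6, rel=5e-3)

    @pytest.mark.parametrize("n,expected", [(1, 0.05), (20, 2.5e-3)])
    def test_simple_cases(self, n, expected):
        assert bonferroni_threshold(n) == pytest.approx(expected)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
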