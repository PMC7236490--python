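"""TMM normalisation, the correlation screen and the visualisation math."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import cophenet

from helpers import average_linkage_heights, bh_bruteforce
from mtp9.exprcorr import (
    correlate_with_methylation,
    cpm,
    heatmap_structure,
    linkage_to_newick,
    pca_samples,
    select_top,
    tmm_factors,
    unit_variance_scale,
)


def _counts(arr, prefix="g", cols=None):
    arr = np.asarray(arr)
    cols = cols or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=cols)


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        c = _counts(np.tile([[10], [50], [200], [5]], (1, 2)))
        assert np.allclose(tmm_factors(c), [1.0, 1.0])

    def test_scalar_multiple_library_gives_unit_factors(self):
        """3x scaling is pure library size: all M-values are 0."""
        rng = np.random.default_rng(0)
        a = rng.integers(1, 500, size=50)
        c = _counts(np.column_stack([a, 3 * a]))
        assert np.allclose(tmm_factors(c), [1.0, 1.0])

    def test_asymmetric_up_gene_pulls_factor_down(self):
        rng = np.random.default_rng(1)
        a = rng.integers(50, 200, size=30)
        b = a.copy()
        b[0] *= 100  # one transcript massively up in B only
        f = tmm_factors(_counts(np.column_stack([a, b])))
        assert f.iloc[1] < f.iloc[0]

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        c = _counts(rng.negative_binomial(5, 0.05, size=(200, 5)))
        f = tmm_factors(c)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_invariant_to_scaling_one_sample(self):
        """Library scaling is absorbed: exactly for the unweighted trimmed
        mean, to ~2% with the count-based precision weights."""
        rng = np.random.default_rng(3)
        c = _counts(rng.negative_binomial(5, 0.05, size=(200, 4)))
        c2 = c.copy()
        c2["s1"] = c2["s1"] * 7
        assert np.allclose(tmm_factors(c, weighted=False),
                           tmm_factors(c2, weighted=False), atol=1e-10)
        assert np.allclose(tmm_factors(c), tmm_factors(c2), rtol=0.05)

    def test_all_zero_sample_rejected(self):
        c = _counts([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(c)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Independent oracle: edgeR's TMM on a random count matrix."""
        rng = np.random.default_rng(4)
        c = _counts(rng.negative_binomial(5, 0.05, size=(300, 6)))
        c.iloc[:25, 2] *= 6
        c.to_csv(tmp_path / "c.tsv", sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            'x <- as.matrix(read.delim("c.tsv", row.names=1));'
            'cat(sprintf("%.10f\\n", calcNormFactors(x, method="TMM")))'
        )
        out = subprocess.run(["Rscript", "-e", script], cwd=tmp_path,
                             capture_output=True, text=True, check=True)
        r_factors = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(tmm_factors(c), r_factors, atol=1e-6)


class TestCpm:
    def test_plain_cpm_with_unit_factors(self):
        c = _counts([[100, 0], [900, 1000]])
        out = cpm(c, pd.Series([1.0, 1.0], index=c.columns))
        assert out.loc["g0", "s0"] == pytest.approx(1e5)
        assert out.loc["g0", "s1"] == 0.0

    def test_doubling_counts_leaves_cpm_unchanged_after_renormalising(self):
        rng = np.random.default_rng(5)
        c = _counts(rng.negative_binomial(5, 0.05, size=(100, 3)))
        c2 = c.copy()
        c2["s0"] = c2["s0"] * 2
        n1 = cpm(c, tmm_factors(c, weighted=False))
        n2 = cpm(c2, tmm_factors(c2, weighted=False))
        assert np.allclose(n1["s0"], n2["s0"], rtol=1e-10)


class TestCorrelationScreen:
    def _aaf(self, values, cols):
        return pd.Series(values, index=cols)

    def test_rank_identical_transcript_has_rho_one(self):
        rng = np.random.default_rng(6)
        aaf = rng.uniform(0.05, 0.3, size=30)
        cols = [f"s{j}" for j in range(30)]
        x = np.vstack([aaf * 100, rng.normal(size=30)])
        corr = correlate_with_methylation(_counts(x, cols=cols), self._aaf(aaf, cols))
        assert corr.loc["g0", "rho"] == pytest.approx(1.0)
        assert corr.loc["g0", "q"] == corr["q"].min()
        assert corr.loc["g0", "rank"] == 1

    def test_matches_scipy_spearman_per_transcript(self):
        rng = np.random.default_rng(7)
        cols = [f"s{j}" for j in range(25)]
        x = rng.normal(size=(15, 25))
        aaf = self._aaf(rng.uniform(size=25), cols)
        corr = correlate_with_methylation(_counts(x, cols=cols), aaf)
        for i in range(15):
            r, p = stats.spearmanr(x[i], aaf)
            assert corr.iloc[i]["rho"] == pytest.approx(r, abs=1e-12)
            assert corr.iloc[i]["p"] == pytest.approx(p, rel=1e-6)

    def test_constant_transcript_excluded_from_fdr(self):
        rng = np.random.default_rng(8)
        cols = [f"s{j}" for j in range(20)]
        x = np.vstack([np.full(20, 7.0), rng.normal(size=(3, 20))])
        corr = correlate_with_methylation(_counts(x, cols=cols),
                                          self._aaf(rng.uniform(size=20), cols))
        assert np.isnan(corr.loc["g0", "rho"]) and np.isnan(corr.loc["g0", "q"])
        assert corr["q"].notna().sum() == 3

    def test_too_few_pairs_rejected(self):
        cols = [f"s{j}" for j in range(5)]
        with pytest.raises(ValueError, match="complete pairs"):
            correlate_with_methylation(
                _counts(np.ones((2, 5)), cols=cols),
                self._aaf(np.linspace(0, 1, 5), cols),
            )

    def test_bh_matches_bruteforce_definition(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 40))
            from statsmodels.stats.multitest import multipletests

            q = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh_bruteforce(p), atol=1e-12)


class TestSelectTop:
    def _corr(self):
        return pd.DataFrame(
            {"rho": [0.9, -0.95, 0.1], "p": [1e-5, 1e-6, 0.5],
             "q": [1e-4, 1e-5, 0.6], "rank": [2.0, 1.0, 3.0]},
            index=pd.Index(["t1", "t2", "t3"], name="transcript"),
        )

    def test_zero_returns_empty(self):
        top, genes = select_top(self._corr(), n=0)
        assert top == [] and genes == []

    def test_top_one_is_largest_absolute_rho(self):
        top, _ = select_top(self._corr(), n=1)
        assert top == ["t2"]

    def test_duplicate_genes_collapse(self):
        t2g = pd.DataFrame({"gene": ["gA", "gA", "gB"]},
                           index=pd.Index(["t1", "t2", "t3"], name="transcript"))
        _, genes = select_top(self._corr(), n=3, t2g=t2g)
        assert genes == ["gA", "gB"]

    def test_overlong_request_warns_and_truncates(self):
        with pytest.warns(UserWarning, match="only"):
            top, _ = select_top(self._corr(), n=10)
        assert len(top) == 3


class TestHeatmapStructure:
    def test_identical_rows_merge_first_at_height_zero(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=8)
        m = _counts(np.vstack([base, base, rng.normal(size=(2, 8))]))
        out = heatmap_structure(m)
        assert out["row_linkage"][0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(out["row_linkage"][0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_rows_at_maximum_distance(self):
        x = np.linspace(0, 1, 10)
        m = _counts(np.vstack([x, -x]))
        out = heatmap_structure(m)
        # the merge joining the anticorrelated pair happens at distance 2
        assert out["row_linkage"][:, 2].max() == pytest.approx(2.0, rel=1e-6)

    def test_linkage_heights_match_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = _counts(rng.normal(size=(4, 6)))
            out = heatmap_structure(m)
            scaled = out["scaled"].to_numpy()
            d = 1 - np.corrcoef(scaled)
            heights = sorted(average_linkage_heights(d))
            assert np.allclose(sorted(out["row_linkage"][:, 2]), heights, atol=1e-10)

    def test_zero_variance_row_dropped_with_warning(self):
        m = _counts(np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0)[::-1]]))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = heatmap_structure(m)
        assert list(out["scaled"].index) == ["g1", "g2"]

    def test_leaf_order_deterministic(self):
        rng = np.random.default_rng(12)
        m = _counts(rng.normal(size=(6, 9)))
        assert heatmap_structure(m)["row_order"] == heatmap_structure(m)["row_order"]

    def test_newick_exports_all_leaves(self):
        rng = np.random.default_rng(13)
        m = _counts(rng.normal(size=(5, 7)))
        out = heatmap_structure(m)
        nwk = linkage_to_newick(out["row_linkage"], list(out["scaled"].index))
        assert nwk.endswith(";")
        for leaf in out["scaled"].index:
            assert leaf in nwk


class TestPcaSamples:
    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(14)
        m = _counts(rng.normal(size=(10, 5)))
        m["s5"] = m["s0"]
        scores, _ = pca_samples(unit_variance_scale(m))
        assert np.allclose(scores.loc["s0"], scores.loc["s5"], atol=1e-8)

    def test_variance_fractions_are_a_partition(self):
        rng = np.random.default_rng(15)
        scores, var = pca_samples(unit_variance_scale(_counts(rng.normal(size=(20, 8)))))
        assert (var >= 0).all() and var.sum() <= 1 + 1e-12
        assert (np.diff(var) <= 1e-12).all()

    def test_matches_dense_eigensolver_on_toy(self):
        rng = np.random.default_rng(16)
        m = unit_variance_scale(_counts(rng.normal(size=(5, 4))))
        scores, var = pca_samples(m, n_components=2)
        x = m.to_numpy().T
        w, v = np.linalg.eigh(x @ x.T)
        order = np.argsort(w)[::-1]
        expected_var = w[order] / w.sum()
        assert np.allclose(var, expected_var[:2], atol=1e-10)
        for j in range(2):
            r = np.corrcoef(scores.iloc[:, j], v[:, order[j]])[0, 1]
            assert abs(abs(r) - 1) < 1e-8
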