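"""Unit tests for normalization, QC filters, cis pairing and covariates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pureqtl import (
    compute_expression_factors,
    compute_genotype_pcs,
    filter_genes_expressed,
    filter_variants_maf,
    map_cis_pairs,
    purity_transfer,
    quantile_normalize_and_int,
    simulate_purity,
)


class TestInverseNormalTransform:
    def test_three_point_blom_quantiles(self):
        # rows are permutations of the same values, so cross-sample quantile
        # normalization is the identity and the INT step is isolated
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [3.0, 1.0, 2.0]],
            index=["s0", "s1", "s2"],
            columns=["gA", "gB", "gC"],
        )
        out = quantile_normalize_and_int(expr)
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])  # (-0.9674, 0, 0.9674)
        np.testing.assert_allclose(np.sort(out["gA"].to_numpy()), expected, atol=1e-12)
        assert expected[0] == pytest.approx(-0.9674, abs=1e-4)

    def test_each_gene_standardized(self, rng):
        expr = pd.DataFrame(rng.lognormal(size=(60, 8)))
        out = quantile_normalize_and_int(expr)
        # mean is 0 up to tie handling introduced by quantile normalization
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=0.05)
        np.testing.assert_allclose(out.std(axis=0, ddof=0), 1.0, atol=0.1)

    def test_rank_transform_preserves_within_gene_order(self, rng):
        # rows share one value multiset, so quantile normalization is the
        # identity and only the monotone rank transform acts per gene
        base = rng.normal(size=10)
        expr = pd.DataFrame([rng.permutation(base) for _ in range(40)])
        out = quantile_normalize_and_int(expr)
        for col in expr.columns:
            np.testing.assert_array_equal(
                stats.rankdata(expr[col]), stats.rankdata(out[col])
            )

    def test_transformed_gene_is_ks_normal(self, rng):
        expr = pd.DataFrame(rng.exponential(size=(150, 60)))
        out = quantile_normalize_and_int(expr)
        for col in out.columns[:10]:
            assert stats.kstest(out[col], "norm").pvalue > 0.01

    def test_constant_genes_dropped_with_warning(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        expr["c"] = 5.0
        with pytest.warns(UserWarning, match="constant gene"):
            out = quantile_normalize_and_int(expr)
        assert list(out.columns) == ["a", "b"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            quantile_normalize_and_int(pd.DataFrame([[1.0, 2.0]]))


class TestExpressionFilter:
    @pytest.mark.parametrize(
        "n_expressed, n_samples, kept",
        [(74, 100, False), (100, 100, True), (3, 4, True), (75, 100, True)],
    )
    def test_expressed_fraction_threshold(self, n_expressed, n_samples, kept):
        values = np.zeros(n_samples)
        values[:n_expressed] = 1.0
        expr = pd.DataFrame({"g": values, "anchor": np.ones(n_samples)})
        out = filter_genes_expressed(expr)
        assert ("g" in out.columns) is kept

    def test_idempotent(self, rng):
        expr = pd.DataFrame(rng.exponential(size=(40, 10)) - 0.5)
        once = filter_genes_expressed(expr)
        pd.testing.assert_frame_equal(filter_genes_expressed(once), once)

    def test_empty_result_errors(self):
        expr = pd.DataFrame(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="no genes"):
            filter_genes_expressed(expr)


class TestMafFilter:
    def test_maf_rules(self):
        n = 20
        geno = pd.DataFrame(
            {
                "mono": np.zeros(n),
                "one_het": np.r_[1, np.zeros(n - 1)],  # MAF 1/40 = 0.025
                "common": np.r_[np.zeros(5), np.ones(10), np.full(5, 2)],  # MAF 0.5
            }
        )
        out = filter_variants_maf(geno)
        assert list(out.columns) == ["common"]

    def test_idempotent_and_symmetric_in_allele_coding(self, rng):
        geno = pd.DataFrame(rng.integers(0, 3, size=(50, 8)).astype(float))
        once = filter_variants_maf(geno)
        pd.testing.assert_frame_equal(filter_variants_maf(once), once)
        flipped = 2 - geno
        pd.testing.assert_frame_equal(
            filter_variants_maf(flipped), 2 - filter_variants_maf(geno),
            check_names=False,
        )


class TestCisPairs:
    def test_window_boundaries_inclusive(self):
        variants = pd.DataFrame(
            {"variant_id": ["v1"], "chrom": ["1"], "pos": [1_000_000]}
        )
        genes = pd.DataFrame(
            {
                "gene_id": ["near", "far"],
                "chrom": ["1", "1"],
                "tss": [1_499_999, 1_500_001],
            }
        )
        pairs = map_cis_pairs(variants, genes)
        assert pairs["gene_id"].tolist() == ["near"]
        assert pairs["distance"].tolist() == [-499_999]

    def test_matches_brute_force_scan(self, rng):
        for trial in range(5):
            variants = pd.DataFrame(
                {
                    "variant_id": [f"v{i}" for i in range(30)],
                    "chrom": rng.choice(["1", "2"], 30),
                    "pos": rng.integers(1, 2_000_000, 30),
                }
            )
            genes = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(20)],
                    "chrom": rng.choice(["1", "2"], 20),
                    "tss": rng.integers(1, 2_000_000, 20),
                }
            )
            window = int(rng.integers(10_000, 700_000))
            got = map_cis_pairs(variants, genes, window)
            expected = {
                (v.variant_id, g.gene_id)
                for v in variants.itertuples()
                for g in genes.itertuples()
                if v.chrom == g.chrom and abs(v.pos - g.tss) <= window
            }
            assert set(zip(got["variant_id"], got["gene_id"])) == expected

    def test_minus_strand_anchor_is_gene_end(self):
        variants = pd.DataFrame({"variant_id": ["v"], "chrom": ["1"], "pos": [900_000]})
        genes = pd.DataFrame(
            {
                "gene_id": ["g"],
                "chrom": ["1"],
                "start": [100],
                "end": [880_000],
                "strand": ["-"],
            }
        )
        pairs = map_cis_pairs(variants, genes)
        assert pairs["distance"].tolist() == [20_000]

    def test_orphan_chromosome_warns(self):
        variants = pd.DataFrame({"variant_id": ["v"], "chrom": ["chrX"], "pos": [5]})
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["1"], "tss": [5]})
        with pytest.warns(UserWarning, match="without counterpart"):
            pairs = map_cis_pairs(variants, genes)
        assert pairs.empty


class TestGenotypePcs:
    def test_scores_match_svd_oracle_up_to_sign(self, rng):
        geno = pd.DataFrame(rng.integers(0, 3, size=(12, 6)).astype(float))
        scores = compute_genotype_pcs(geno, k=3)
        z = (geno - geno.mean()) / geno.std(ddof=0)
        u, s, _ = np.linalg.svd(z.to_numpy() - z.to_numpy().mean(0), full_matrices=False)
        oracle = u[:, :3] * s[:3]
        for j in range(3):
            got = scores.iloc[:, j].to_numpy()
            assert min(
                np.abs(got - oracle[:, j]).max(), np.abs(got + oracle[:, j]).max()
            ) < 1e-8

    def test_scores_orthogonal(self, rng):
        geno = pd.DataFrame(rng.integers(0, 3, size=(30, 10)).astype(float))
        scores = compute_genotype_pcs(geno, k=3).to_numpy()
        gram = scores.T @ scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_genotype_pcs(pd.DataFrame(np.ones((5, 3))))
        tiny = pd.DataFrame([[0.0, 1], [0, 1], [0, 1], [2, 0]])
        with pytest.raises(ValueError, match="rank"):
            compute_genotype_pcs(tiny, k=3)


class TestExpressionFactors:
    def test_zero_factors_is_empty_block(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 5)))
        out = compute_expression_factors(expr, k=0)
        assert out.shape == (20, 0)

    def test_factors_orthogonal_to_regressed_out_covariates(self, rng):
        n = 80
        covar = pd.DataFrame({"purity": rng.uniform(size=n)})
        # expression partly driven by the covariate plus structured noise
        expr = pd.DataFrame(
            covar["purity"].to_numpy()[:, None] * rng.normal(size=10)
            + rng.normal(size=(n, 10))
        )
        factors = compute_expression_factors(expr, covar, k=3)
        centered_cov = covar.to_numpy() - covar.to_numpy().mean(0)
        dots = factors.to_numpy().T @ centered_cov
        np.testing.assert_allclose(dots, 0.0, atol=1e-8)

    def test_residualizing_covariate_out_of_itself_gives_zero(self, rng):
        covar = pd.DataFrame({"c": rng.normal(size=30)})
        expr = pd.DataFrame({"g": covar["c"].to_numpy()})
        with pytest.raises(ValueError, match="rank"):
            # residuals are numerically zero -> no principal structure left
            compute_expression_factors(expr, covar, k=1)


@pytest.fixture(scope="module")
def cohorts():
    rng = np.random.default_rng(21)
    n, g = 250, 60
    purity = simulate_purity(n, seed=22)
    loadings = np.zeros(g)
    loadings[:50] = rng.normal(1.0, 0.3, 50)  # 50 purity-driven genes
    expr = pd.DataFrame(
        purity.to_numpy()[:, None] * loadings + rng.normal(0, 0.2, size=(n, g)),
        index=purity.index,
        columns=[f"g{i}" for i in range(g)],
    )
    return expr, purity


class TestPurityTransfer:
    def test_self_transfer_recovers_reference_distribution(self, cohorts):
        expr, purity = cohorts
        pred = purity_transfer(expr, expr, purity)
        np.testing.assert_allclose(
            np.sort(pred.to_numpy()), np.sort(purity.to_numpy())
        )
        assert np.corrcoef(pred.to_numpy(), purity.to_numpy())[0, 1] > 0.8

    def test_transfer_to_new_cohort_tracks_truth(self, cohorts):
        expr, purity = cohorts
        rng = np.random.default_rng(33)
        target_purity = simulate_purity(120, seed=34)
        loadings = np.zeros(expr.shape[1])
        loadings[:50] = 1.0
        target_expr = pd.DataFrame(
            target_purity.to_numpy()[:, None] * loadings
            + rng.normal(0, 0.2, size=(120, expr.shape[1])),
            index=target_purity.index,
            columns=expr.columns,
        )
        pred = purity_transfer(target_expr, expr, purity)
        assert np.corrcoef(pred.to_numpy(), target_purity.to_numpy())[0, 1] > 0.6
        assert pred.min() >= purity.min() and pred.max() <= purity.max()

    def test_too_few_shared_genes_rejected(self, cohorts):
        expr, purity = cohorts
        with pytest.raises(ValueError, match="shared genes"):
            purity_transfer(expr.iloc[:, :5], expr.iloc[:, :5], purity)
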