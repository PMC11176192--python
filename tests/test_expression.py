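"""Normalization, per-gene OLS differential expression, and BH adjustment."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from metseed import cohortgen, expression


def small_matrix():
    counts = pd.DataFrame(
        {"a": [4, 4, 4, 0], "b": [2, 4, 6, 8], "c": [10, 20, 40, 80]},
        index=["g1", "g2", "g3", "g4"],
    )
    return counts


class TestUQSizeFactors:
    def test_constant_nonzero_counts(self):
        s = expression.uq_size_factors(small_matrix())
        assert s["a"] == 4.0

    def test_linear_interpolation_percentile(self):
        s = expression.uq_size_factors(small_matrix())
        assert s["b"] == 6.5  # 75th pct of [2,4,6,8]

    def test_homogeneity_under_scaling(self):
        counts = small_matrix()
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 10
        assert (
            expression.uq_size_factors(scaled)["b"]
            == 10 * expression.uq_size_factors(counts)["b"]
        )

    def test_all_zero_sample_error_names_sample(self):
        counts = small_matrix()
        counts["bad"] = 0
        with pytest.raises(ValueError, match="bad"):
            expression.uq_size_factors(counts)


class TestLogNormalize:
    @pytest.mark.parametrize("k,s,expected", [(0, 1.0, 0.0), (7, 4.0, 1.0), (63, 16.0, 2.0)])
    def test_exact_values(self, k, s, expected):
        counts = pd.DataFrame({"x": [k]}, index=["g"])
        y = expression.log_normalize(counts, pd.Series({"x": s}))
        assert y.loc["g", "x"] == expected  # bit-exact under double precision

    def test_tsv_round_trip_is_exact(self, tmp_path):
        counts = small_matrix()
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        reloaded = pd.read_csv(path, sep="\t", index_col=0)
        s = expression.uq_size_factors(counts)
        pd.testing.assert_frame_equal(
            expression.log_normalize(counts, s),
            expression.log_normalize(reloaded, s),
        )

    def test_non_positive_size_factor_error(self):
        with pytest.raises(ValueError):
            expression.log_normalize(small_matrix(), pd.Series({"a": 0.0, "b": 1.0, "c": 1.0}))


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert expression.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        assert expression.bh_adjust([0.005, 0.5]) == pytest.approx([0.01, 0.5])

    def test_single_p_unchanged(self):
        assert expression.bh_adjust([0.123]) == pytest.approx([0.123])

    def test_nan_propagates(self):
        out = expression.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert not np.isnan(out[0])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(expression.bh_adjust(p), expected, atol=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_properties(self, p):
        adj = expression.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)  # p_adj >= p
        assert np.all(adj <= 1.0)


class TestDELinearModel:
    def normalized(self, cfg):
        counts, meta, truth = cohortgen.generate_counts(cfg)
        s = expression.uq_size_factors(counts)
        return expression.log_normalize(counts, s), meta, truth

    def test_degenerate_gene_flagged(self):
        Y, meta, _ = self.normalized(
            cohortgen.CountsConfig(n_genes=20, n_met=5, n_pt=5, seed=1)
        )
        Y.iloc[0] = 3.0  # constant across samples
        res = expression.de_linear_model(Y, meta)
        assert res.table["flag"].iloc[0] == "degenerate"
        assert np.isnan(res.table["p"].iloc[0])

    def test_swapped_labels_negate_coefficient(self):
        Y, meta, _ = self.normalized(
            cohortgen.CountsConfig(
                n_genes=30, n_met=10, n_pt=10, spike_table=(("G0002", 1.5),), seed=2
            )
        )
        res = expression.de_linear_model(Y, meta)
        flipped = meta.copy()
        flipped["tissue"] = np.where(flipped["tissue"] == "met", "pt", "met")
        res_fl = expression.de_linear_model(Y, flipped)
        np.testing.assert_allclose(
            res.table["log2fc"], -res_fl.table["log2fc"], atol=1e-10
        )

    def test_matches_statsmodels_ols_per_gene(self):
        import statsmodels.api as sm

        Y, meta, _ = self.normalized(
            cohortgen.CountsConfig(n_genes=10, n_met=8, n_pt=12, seed=3)
        )
        res = expression.de_linear_model(Y, meta)
        X = pd.DataFrame(
            {
                "const": 1.0,
                "tissue_met": (meta["tissue"] == "met").astype(float),
                "batch_B1": (meta["batch"] == "B1").astype(float),
                "sex_M": (meta["sex"] == "M").astype(float),
                "age": meta["age"].astype(float),
            }
        )
        for gene in Y.index[:3]:
            ols = sm.OLS(Y.loc[gene].to_numpy(), X.to_numpy()).fit()
            assert res.table.loc[gene, "log2fc"] == pytest.approx(ols.params[1], abs=1e-10)
            assert res.table.loc[gene, "p"] == pytest.approx(ols.pvalues[1], abs=1e-10)

    def test_confounded_design_error(self):
        counts, meta, _ = cohortgen.generate_counts(
            cohortgen.CountsConfig(n_genes=10, n_met=4, n_pt=4, seed=4)
        )
        meta = meta.copy()
        meta["batch"] = np.where(meta["tissue"] == "met", "B0", "B1")
        s = expression.uq_size_factors(counts)
        Y = expression.log_normalize(counts, s)
        with pytest.raises(ValueError, match="confounded|rank"):
            expression.de_linear_model(Y, meta)

    def test_null_pvalues_approximately_uniform(self):
        Y, meta, _ = self.normalized(
            cohortgen.CountsConfig(n_genes=2000, n_met=45, n_pt=130, seed=5)
        )
        res = expression.de_linear_model(Y, meta)
        p = res.table["p"].dropna().to_numpy()
        grid = np.sort(p)
        ks = np.max(np.abs(grid - np.arange(1, len(grid) + 1) / len(grid)))
        assert ks < 0.05


class TestConditionalDE:
    def test_orthogonal_focal_gene_changes_nothing(self):
        counts, meta, _ = cohortgen.generate_counts(
            cohortgen.CountsConfig(n_genes=40, n_met=15, n_pt=15, seed=6)
        )
        s = expression.uq_size_factors(counts)
        Y = expression.log_normalize(counts, s)
        # focal row independent of everything (pure noise, orthogonalized
        # against the design so the remaining coefficients are untouched)
        rng = np.random.default_rng(0)
        noise = rng.normal(size=Y.shape[1])
        X = pd.DataFrame(
            {
                "const": 1.0,
                "t": (meta["tissue"] == "met").astype(float),
                "b": (meta["batch"] == "B1").astype(float),
                "s": (meta["sex"] == "M").astype(float),
                "a": meta["age"].astype(float),
            }
        ).to_numpy()
        resid = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        Y.loc["FOCAL"] = resid
        cond = expression.conditional_de(Y, meta, "FOCAL")
        plain = expression.de_linear_model(Y.drop(index="FOCAL"), meta)
        np.testing.assert_allclose(
            cond.table["log2fc"], plain.table["log2fc"], atol=1e-8
        )

    def test_focal_gene_absent_error(self):
        counts, meta, _ = cohortgen.generate_counts(
            cohortgen.CountsConfig(n_genes=10, n_met=4, n_pt=4, seed=7)
        )
        Y = expression.log_normalize(counts, expression.uq_size_factors(counts))
        with pytest.raises(ValueError, match="focal"):
            expression.conditional_de(Y, meta, "NOPE")

    def test_mediated_genes_lose_significance(self):
        mediated = tuple(f"G{i:04d}" for i in range(2, 10))
        cfg = cohortgen.CountsConfig(
            n_genes=800,
            spike_table=(("G0001", 2.0),),
            factor_gene="G0000",
            shared_factor_genes=mediated,
            dispersion=0.05,
            seed=8,
        )
        counts, meta, _ = cohortgen.generate_counts(cfg)
        Y = expression.log_normalize(counts, expression.uq_size_factors(counts))
        marginal = expression.de_linear_model(Y, meta)
        assert (marginal.table.loc[list(mediated), "p_adj"] < 0.05).all()
        cond = expression.conditional_de(Y, meta, "G0000")
        assert (cond.table.loc[list(mediated), "p_adj"] >= 0.05).all()
        # a gene with an independent tissue effect stays significant
        assert cond.table.loc["G0001", "p_adj"] < 0.05


class TestMedianOfRatios:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        s, _ = expression.mor_size_factors_and_filter(counts, min_mean=0.0)
        assert s.tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_factor_ratio_two(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        s, _ = expression.mor_size_factors_and_filter(counts, min_mean=0.0)
        assert s["b"] / s["a"] == pytest.approx(2.0)

    def test_three_sample_hand_computation(self):
        counts = pd.DataFrame(
            {"A": [10, 20, 40], "B": [20, 40, 80], "C": [5, 10, 20]}
        )
        s, _ = expression.mor_size_factors_and_filter(counts, min_mean=0.0)
        ratios = s / s["A"]
        assert ratios.tolist() == pytest.approx([1.0, 2.0, 0.5])

    def test_low_abundance_rows_removed(self):
        counts = pd.DataFrame({"a": [100, 1, 0], "b": [100, 1, 1]})
        _, filtered = expression.mor_size_factors_and_filter(counts, min_mean=1.0)
        assert len(filtered) < 3
        assert 0 in filtered.index

    def test_no_common_nonzero_gene_error(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError, match="reference"):
            expression.mor_size_factors_and_filter(counts)
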