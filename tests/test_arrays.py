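"""Array normalization chain: ratios, centering, trimming, outlier-aware
averaging, interpolation and the low-expression filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germomics import (
    ArrayNormalizationParams,
    SimulationConfig,
    average_replicates,
    center_scale_array,
    interpolate_internal_missing,
    log2_ratio,
    low_expression_filter,
    normalize_arrays,
    pearson_with_pvalue,
    quantile_trim,
    simulate_transcriptome,
)
from germomics.errors import UsageError, ValidationError

from conftest import toy_matrix


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [(8.0, 8.0, 0.0), (8.0, 2.0, 2.0), (2.0, 8.0, -2.0)],
    )
    def test_cellwise_log2(self, grid, alpha, beta, expected):
        m = toy_matrix(
            grid,
            {("0.0", 1, "alpha"): [alpha] * 3, ("0.0", 1, "beta"): [beta] * 3},
        )
        ratios, n_invalid = log2_ratio(m)
        assert ratios.iloc[0, 0] == pytest.approx(expected)
        assert n_invalid == 0

    def test_zero_alpha_becomes_missing_not_minus_inf(self, grid):
        m = toy_matrix(
            grid,
            {("0.0", 1, "alpha"): [0.0, 4, 2], ("0.0", 1, "beta"): [5.0, 2, 2]},
        )
        ratios, _ = log2_ratio(m)
        assert np.isnan(ratios.iloc[0, 0])
        assert ratios.iloc[1, 0] == pytest.approx(1.0)

    def test_nonpositive_beta_flagged_invalid(self, grid):
        m = toy_matrix(
            grid,
            {("0.0", 1, "alpha"): [3.0, 4, 2], ("0.0", 1, "beta"): [0.0, 2, 2]},
        )
        ratios, n_invalid = log2_ratio(m)
        assert np.isnan(ratios.iloc[0, 0]) and n_invalid == 1


class TestCenterScale:
    def test_reference_example(self):
        out = center_scale_array(np.array([1.0, 2, 3, 4, 5]))
        assert np.allclose(out, [-2, -1, 0, 1, 2])

    def test_degenerate_array_rejected(self):
        with pytest.raises(ValidationError):
            center_scale_array(np.array([4.0, 4.0, 4.0]), name="arr7")

    def test_fewer_than_three_finite_rejected(self):
        with pytest.raises(ValidationError):
            center_scale_array(np.array([1.0, 2.0, np.nan]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=5, max_size=40, unique=True
        )
    )
    def test_postcondition_median_zero_mad_one(self, vals):
        out = center_scale_array(np.array(vals))
        assert np.nanmedian(out) == pytest.approx(0.0, abs=1e-12)
        med = np.nanmedian(out)
        assert np.nanmedian(np.abs(out - med)) == pytest.approx(1.0, rel=1e-12)


class TestQuantileTrim:
    def test_q_zero_is_identity(self):
        vals = np.arange(10.0)
        out, n = quantile_trim(vals, 0.0)
        assert n == 0 and np.allclose(out, vals)

    def test_hundred_values_q002_removes_at_most_four(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.arange(100.0))
        out, n = quantile_trim(vals, 0.02)
        assert n <= 4
        # sort-and-count oracle: survivors exclude only extreme ranks
        removed = set(np.nonzero(~np.isfinite(out))[0])
        ranks = {int(np.argsort(vals)[i]) for i in (0, 1, 98, 99)}
        assert removed <= ranks

    def test_ten_values_q002_removes_at_most_min_and_max(self):
        vals = np.arange(10.0)
        out, n = quantile_trim(vals, 0.02)
        assert n <= 2
        assert np.isfinite(out[1:-1]).all()


class TestAveraging:
    def params(self):
        return ArrayNormalizationParams()

    def test_geometric_mean_on_ratio_scale(self, grid):
        ratios = pd.DataFrame(
            {("0.0", r): [2.0, 1.0, 3.0] for r in (1, 2, 3)},
            index=["a", "b", "c"],
        )
        ratios.columns = pd.MultiIndex.from_tuples(
            ratios.columns, names=["time", "replicate"]
        )
        profiles, n = average_replicates(ratios, grid, self.params())
        assert profiles.loc["a", "0.0"] == pytest.approx(4.0)  # 2^2
        assert n.loc["a", "0.0"] == 3

    def test_dixon_flagged_spike_excluded_from_mean(self, grid):
        vals = {"a": [1.0, 1.1, 1.2, 5.0]}
        ratios = pd.DataFrame(
            {("0.0", r): [vals["a"][r - 1]] for r in (1, 2, 3, 4)}, index=["a"]
        )
        ratios.columns = pd.MultiIndex.from_tuples(
            ratios.columns, names=["time", "replicate"]
        )
        profiles, n = average_replicates(ratios, grid, self.params())
        assert profiles.loc["a", "0.0"] == pytest.approx(2 ** np.mean([1.0, 1.1, 1.2]))
        assert n.loc["a", "0.0"] == 3

    def test_pool_of_two_gets_plain_mean(self, grid):
        ratios = pd.DataFrame({("0.0", 1): [0.0], ("0.0", 2): [4.0]}, index=["a"])
        ratios.columns = pd.MultiIndex.from_tuples(
            ratios.columns, names=["time", "replicate"]
        )
        profiles, _ = average_replicates(ratios, grid, self.params())
        assert profiles.loc["a", "0.0"] == pytest.approx(4.0)  # 2^2

    def test_empty_pool_yields_missing(self, grid):
        ratios = pd.DataFrame({("0.0", 1): [np.nan]}, index=["a"])
        ratios.columns = pd.MultiIndex.from_tuples(
            ratios.columns, names=["time", "replicate"]
        )
        profiles, n = average_replicates(ratios, grid, self.params())
        assert np.isnan(profiles.loc["a", "0.0"]) and n.loc["a", "0.0"] == 0

    def test_replicate_order_invariance(self, grid):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 6))
        cols = [("1.0", r) for r in range(1, 7)]
        r1 = pd.DataFrame(vals, columns=pd.MultiIndex.from_tuples(cols, names=["time", "replicate"]))
        perm = rng.permutation(6)
        r2 = pd.DataFrame(
            vals[:, perm],
            columns=pd.MultiIndex.from_tuples([cols[i] for i in perm], names=["time", "replicate"]),
        )
        p1, _ = average_replicates(r1, grid)
        p2, _ = average_replicates(r2, grid)
        pd.testing.assert_frame_equal(p1, p2)


class TestInterpolation:
    def mk(self, row, grid):
        cols = list(grid.labels)[: len(row)]
        return pd.DataFrame([row], index=["g"], columns=cols, dtype=float)

    def test_single_internal_gap_filled(self, grid):
        prof = self.mk([1.0, np.nan, 3.0], grid)
        out, n = interpolate_internal_missing(prof)
        assert out.loc["g"].tolist() == [1.0, 2.0, 3.0] and n == 1

    def test_leading_gap_untouched(self, grid):
        prof = self.mk([np.nan, 2.0, 3.0], grid)
        out, n = interpolate_internal_missing(prof)
        assert np.isnan(out.iloc[0, 0]) and n == 0

    def test_double_gap_untouched(self, grid):
        prof = self.mk([1.0, np.nan, np.nan, 4.0], grid)
        out, n = interpolate_internal_missing(prof)
        assert np.isnan(out.iloc[0, 1]) and np.isnan(out.iloc[0, 2]) and n == 0


class TestLowExpressionFilter:
    def build(self, medians, grid, peak_gene=None):
        """Matrix with 2 replicates at each of 3 time points, constant per
        gene at its target median; optionally one gene peaking at '0.5'."""
        ids = [f"g{i}" for i in range(len(medians))]
        cols = {}
        for t in ("0.0", "0.5", "1.0"):
            for r in (1, 2):
                vals = np.array(medians, dtype=float)
                if peak_gene is not None and t == "0.5":
                    vals[peak_gene] *= 50
                cols[(t, r, "alpha")] = vals
                cols[(t, r, "beta")] = np.ones(len(medians))
        return toy_matrix(grid, cols, ids=ids)

    def profiles_for(self, matrix, grid):
        ratios, _ = log2_ratio(matrix)
        profiles, _ = average_replicates(ratios, grid)
        return profiles

    def test_quartile_filter_keeps_three_quarters(self, grid):
        medians = list(range(1, 101))
        m = self.build(medians, grid)
        profiles = self.profiles_for(m, grid)
        kept, removed, rescued = low_expression_filter(
            profiles, m, ArrayNormalizationParams()
        )
        assert len(kept) == 75 and len(removed) == 25 and not rescued

    def test_single_peak_gene_rescued(self, grid):
        medians = [1.0] + list(range(2, 101))
        m = self.build(medians, grid, peak_gene=0)
        profiles = self.profiles_for(m, grid)
        kept, removed, rescued = low_expression_filter(
            profiles, m, ArrayNormalizationParams()
        )
        assert "g0" in rescued and "g0" in kept.index

    def test_monotone_in_filter_quartile(self, grid):
        rng = np.random.default_rng(5)
        medians = rng.lognormal(3, 1, 80)
        m = self.build(list(medians), grid)
        profiles = self.profiles_for(m, grid)
        kept_sizes = []
        for q in (0.1, 0.25, 0.5, 0.75):
            params = ArrayNormalizationParams(filter_quartile=q)
            kept, _, _ = low_expression_filter(profiles, m, params)
            kept_sizes.append(len(kept))
        assert kept_sizes == sorted(kept_sizes, reverse=True)


class TestFullChain:
    def test_noise_free_chain_reproduces_planted_profiles(self):
        """Without noise, outliers, missing cells or array artifacts, the
        chain (no centering needed) returns each follower's planted
        standardized profile exactly (r = 1)."""
        cfg = SimulationConfig(
            n_genes=60,
            seed=2,
            loading_fractions=(0.5, 0.3, 0.2),
            noise_cv=0.0,
            outlier_rate=0.0,
            missing_rate=0.0,
            array_offset_log2_sd=0.0,
            array_scale_sd=0.0,
        )
        matrix, truth = simulate_transcriptome(cfg)
        # no artifacts to center away, no outliers to trim: both off
        result = normalize_arrays(
            matrix, ArrayNormalizationParams(center=False, trim_quantile=0.0)
        )
        for gene in result.profiles.index:
            log_prof = np.log2(result.profiles.loc[gene])
            r, _ = pearson_with_pvalue(log_prof, truth.standardized_profiles.loc[gene])
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_centering_removes_planted_array_artifacts(self):
        """Median/MAD centering cancels per-array offset and gain exactly in
        the noise-free limit: centered ratios match the artifact-free run."""
        base = dict(
            n_genes=80,
            seed=4,
            noise_cv=0.0,
            outlier_rate=0.0,
            missing_rate=0.0,
        )
        m_artifacts, _ = simulate_transcriptome(
            SimulationConfig(**base, array_offset_log2_sd=0.5, array_scale_sd=0.3)
        )
        m_clean, _ = simulate_transcriptome(
            SimulationConfig(**base, array_offset_log2_sd=0.0, array_scale_sd=0.0)
        )
        r_art, _ = log2_ratio(m_artifacts)
        r_clean, _ = log2_ratio(m_clean)
        for col in r_art.columns:
            a = center_scale_array(r_art[col].to_numpy())
            b = center_scale_array(r_clean[col].to_numpy())
            assert np.allclose(a, b, atol=1e-9)
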