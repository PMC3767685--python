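"""Standardization, PCA decomposition, correlation tests, alignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from germomics import (
    TimeGrid,
    align_components,
    correlate_with_loading,
    germination_grid,
    pca_decompose,
    pearson_with_pvalue,
    standardize_profiles,
)
from germomics.errors import UsageError
from germomics.experiments import run_recovery, run_shift_detection


def profile_frame(rows):
    """A profiles DataFrame plus a matching uniform TimeGrid."""
    rows = np.asarray(rows, dtype=float)
    labels = [f"{h / 2:.1f}" for h in range(rows.shape[1])]
    frame = pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))], columns=labels
    )
    return frame, TimeGrid.from_labels(labels)


def standardized(rows):
    frame, grid = profile_frame(rows)
    return standardize_profiles(frame, grid)


class TestStandardize:
    def test_three_point_profile(self):
        std = standardized([[1.0, 2.0, 3.0]])
        # population SD of [1,2,3] is sqrt(2/3)
        expected = np.array([-1, 0, 1]) / np.sqrt(2 / 3)
        assert np.allclose(std.values.iloc[0], expected)

    def test_constant_profile_excluded(self):
        std = standardized([[2.0, 2.0, 2.0], [1.0, 2.0, 4.0]])
        assert std.excluded == ["g0"] and list(std.values.index) == ["g1"]

    def test_profile_with_missing_point_excluded(self):
        std = standardized([[1.0, np.nan, 3.0], [1.0, 2.0, 4.0]])
        assert std.excluded == ["g0"]

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        frame, grid = profile_frame(rng.normal(size=(5, 4)))
        once = standardize_profiles(frame, grid)
        twice = standardize_profiles(once.values, grid)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_rows_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        std = standardized(rng.lognormal(size=(20, 13)))
        assert np.allclose(std.values.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(std.values.std(axis=1, ddof=0), 1, atol=1e-9)


class TestDecompose:
    def test_rank_one_matrix_has_full_first_variance_fraction(self):
        v = np.sin(np.arange(13))
        std = standardized([v * a for a in (1.0, 2.0, -1.5, 0.7)])
        d = pca_decompose(std, 2)
        assert d.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one_and_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        std = standardized(rng.normal(size=(40, 13)))
        d = pca_decompose(std, 5)
        assert d.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        L = d.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(5), atol=1e-9)
        assert (np.diff(d.eigenvalues) <= 1e-12).all()

    def test_two_planted_orthogonal_components_recovered(self):
        """Brute-force eigendecomposition oracle on a small noise-free set."""
        rng = np.random.default_rng(5)
        t = np.arange(13.0)
        v1 = np.cos(2 * np.pi * t / 12)
        v2 = np.sin(2 * np.pi * t / 12)
        rows = [a * v1 for a in rng.uniform(1, 2, 30)] + [
            a * v2 for a in rng.uniform(0.5, 1, 15)
        ]
        std = standardized(rows)
        d = pca_decompose(std, 2)
        # oracle: eigh of the covariance built independently
        X = std.values.to_numpy()
        _, V = np.linalg.eigh(X.T @ X / len(X))
        for c, vec in enumerate([V[:, -1], V[:, -2]]):
            r, _ = pearson_with_pvalue(d.loadings.iloc[:, c], vec)
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(6)
        frame, grid = profile_frame(rng.normal(size=(30, 13)))
        d1 = pca_decompose(standardize_profiles(frame, grid), 3)
        d2 = pca_decompose(standardize_profiles(frame.copy(), grid), 3)
        pd.testing.assert_frame_equal(d1.loadings, d2.loadings)
        for c in range(3):
            v = d1.loadings.iloc[:, c].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_k_beyond_time_points_rejected(self):
        rng = np.random.default_rng(7)
        std = standardized(rng.normal(size=(5, 13)))
        with pytest.raises(UsageError):
            pca_decompose(std, 14)


class TestPearson:
    def test_self_correlation(self):
        x = np.arange(13.0)
        r, p = pearson_with_pvalue(x, x)
        assert r == 1.0 and p == 0.0
        r, p = pearson_with_pvalue(x, -x)
        assert r == -1.0 and p == 0.0

    def test_degenerate_input_returns_missing(self):
        r, p = pearson_with_pvalue([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            x, y = rng.normal(size=(2, 13))
            r, p = pearson_with_pvalue(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_permutation_null(self):
        """t-based p agrees with a 2x10^5-permutation null within 0.01."""
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 13))
        r, p = pearson_with_pvalue(x, y)
        n_perm = 200_000
        perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        xc = x - x.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rs = (pc @ xc) / np.sqrt((pc * pc).sum(axis=1) * (xc @ xc))
        p_perm = (np.abs(rs) >= abs(r) - 1e-12).mean()
        assert p == pytest.approx(p_perm, abs=0.01)


class TestCorrelateWithLoading:
    def test_entity_equal_to_loading_is_significant(self):
        rng = np.random.default_rng(10)
        rows = rng.normal(size=(20, 13))
        std = standardized(rows)
        d = pca_decompose(std, 2)
        frame, grid = profile_frame(
            np.vstack([d.loadings.iloc[:, 0].to_numpy(), rows[:5]])
        )
        std2 = standardize_profiles(frame, grid)
        res = correlate_with_loading(std2, d, 1, 0.05)
        assert res.loc["g0", "r"] == pytest.approx(1.0)
        assert bool(res.loc["g0", "significant"])

    def test_alpha_zero_empties_significant_set(self):
        rng = np.random.default_rng(11)
        std = standardized(rng.normal(size=(30, 13)))
        d = pca_decompose(std, 1)
        res = correlate_with_loading(std, d, 1, alpha=0.0)
        assert not res["significant"].any()

    def test_negative_correlates_never_flagged(self):
        rng = np.random.default_rng(12)
        std = standardized(rng.normal(size=(50, 13)))
        d = pca_decompose(std, 1)
        res = correlate_with_loading(std, d, 1, 0.05)
        assert not (res["significant"] & (res["r"] < 0)).any()


class TestAlignment:
    def test_self_alignment_shift_zero(self):
        rng = np.random.default_rng(13)
        std = standardized(rng.normal(size=(40, 13)))
        d = pca_decompose(std, 5)
        al = align_components(d, d, 3)
        assert al.shift == 0
        assert all(i == j and r == pytest.approx(1.0) for i, j, r in al.pairs)

    def test_pairs_are_one_to_one_and_within_bounds(self):
        rng = np.random.default_rng(14)
        a = pca_decompose(standardized(rng.normal(size=(30, 13))), 3)
        b = pca_decompose(standardized(rng.normal(size=(30, 13))), 5)
        al = align_components(a, b, 3)
        assert len({i for i, _, _ in al.pairs}) == len(al.pairs)
        assert len({j for _, j, _ in al.pairs}) == len(al.pairs)
        assert all(1 <= j <= 5 for _, j, _ in al.pairs)
        assert set(al.shift_scores) <= set(range(-2, 3))

    def test_twelve_point_radio_grid_aligns_on_shared_labels(self):
        rng = np.random.default_rng(15)
        rows = rng.normal(size=(30, 13))
        grid13 = germination_grid()
        frame13 = pd.DataFrame(
            rows, index=[f"g{i}" for i in range(30)], columns=list(grid13.labels)
        )
        d13 = pca_decompose(standardize_profiles(frame13, grid13), 3)
        grid12 = grid13.drop_dormant()
        frame12 = frame13[list(grid12.labels)]
        d12 = pca_decompose(standardize_profiles(frame12, grid12), 3)
        al = align_components(d13, d12, 3)
        assert isinstance(al.shift, int)
        assert al.correlation.shape == (3, 3)

    def test_too_few_shared_labels_rejected(self):
        rng = np.random.default_rng(16)
        a = pca_decompose(standardized(rng.normal(size=(20, 13))), 3)
        short = TimeGrid.from_labels(["20.0", "21.0", "22.0"])
        frame = pd.DataFrame(
            rng.normal(size=(20, 3)),
            index=[f"g{i}" for i in range(20)],
            columns=list(short.labels),
        )
        b = pca_decompose(standardize_profiles(frame, short), 3)
        with pytest.raises(UsageError):
            align_components(a, b, 3)

    def test_planted_unit_shift_detected(self):
        assert run_shift_detection(seed=101, n_genes=800, n_spots=300) == 1


class TestRecoveryExperiment:
    def test_planted_components_and_fraction_recovered(self):
        res = run_recovery(seed=5, n_genes=1000)
        assert min(res.loadings_r) >= 0.9
        assert res.pc1_significant_fraction == pytest.approx(
            res.planted_pc1_fraction, abs=0.05
        )
        # planted variance order is preserved
        assert (np.diff(res.variance_fractions[:3]) < 0).all()
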