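import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edaffect.errors import DegeneracyError, EmptySelectionError, ValidationError
from edaffect.selection import (
    CONTEXTUAL_SETS,
    PRESETS,
    coefficient_of_variation,
    contextual_set,
    cv_filter,
    pca_transform,
    preset_set,
    wcss_1d,
    wcss_filter,
)

from .conftest import make_matrix
from .oracles import brute_wcss_two_clusters


class TestCoefficientOfVariation:
    def test_zero_spread(self):
        assert coefficient_of_variation([2, 2, 2]) == 0.0

    def test_hand_computed(self):
        assert coefficient_of_variation([2, 4, 6]) == pytest.approx(0.5)

    def test_sign_flips_with_negation(self):
        assert coefficient_of_variation([-2, -4, -6]) == pytest.approx(-0.5)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegeneracyError):
            coefficient_of_variation([-1, 1])


class TestCvFilter:
    def test_tie_at_threshold_kept(self):
        fm = make_matrix(np.array([[2.0], [4.0], [6.0]]), columns=["a"])
        kept, report = cv_filter(fm, threshold=0.5)
        assert kept.feature_names == ["a"]
        assert report.cv["a"] == pytest.approx(0.5)

    def test_constant_and_low_variability_rejected(self):
        data = np.column_stack([
            np.full(6, 3.0),                       # cv = 0
            np.array([10, 10.5, 9.5, 10, 10.2, 9.8]),  # low cv, rpm-like
            np.array([1, 5, 9, 2, 8, 4.0]),        # high cv
        ])
        fm = make_matrix(data, columns=["const", "rpm_like", "varied"])
        kept, report = cv_filter(fm, threshold=0.5)
        assert kept.feature_names == ["varied"]
        assert report.reason["rpm_like"] == "cv_reject"

    def test_all_rejected_raises(self):
        fm = make_matrix(np.full((4, 2), 7.0))
        with pytest.raises(EmptySelectionError):
            cv_filter(fm)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        fm = make_matrix(rng.lognormal(0, 1.2, size=(10, 5)))
        once, _ = cv_filter(fm)
        twice, _ = cv_filter(once)
        assert twice.feature_names == once.feature_names
        np.testing.assert_array_equal(twice.values(), once.values())


class TestWcss1d:
    @pytest.mark.parametrize("values,expected", [
        ([0, 0, 10, 10], 0.0),
        ([0, 1, 9, 10], 1.0),
        ([5, 5, 5], 0.0),
    ])
    def test_examples(self, values, expected):
        assert wcss_1d(values) == pytest.approx(expected)

    def test_fewer_values_than_clusters_rejected(self):
        with pytest.raises(ValidationError):
            wcss_1d([1.0], k=2)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-50, 50, allow_nan=False, width=32),
                    min_size=2, max_size=12))
    def test_matches_exhaustive_enumeration(self, values):
        assert wcss_1d(values, k=2) == pytest.approx(
            brute_wcss_two_clusters(values), abs=1e-6
        )

    def test_single_cluster_is_total_scatter(self):
        x = np.array([1.0, 4.0, 7.0])
        assert wcss_1d(x, k=1) == pytest.approx(((x - x.mean()) ** 2).sum())


class TestWcssFilter:
    def test_threshold_keeps_small_wcss(self):
        fm = make_matrix(np.column_stack([
            [0.0, 0.1, 5.0, 5.1],       # wcss ~ 0.01
            [0.0, 20.0, 40.0, 60.0],    # wcss large
        ]), columns=["tight", "spread"])
        kept, report = wcss_filter(fm, threshold=10.0)
        assert kept.feature_names == ["tight"]
        assert report.wcss["spread"] > 10.0

    def test_threshold_below_everything_raises(self):
        fm = make_matrix(np.array([[0.0, 0.0], [3.0, 9.0], [6.0, 18.0]]))
        with pytest.raises(EmptySelectionError):
            wcss_filter(fm, threshold=1e-9)

    def test_top_k_returns_exact_cardinality(self, cohort):
        from edaffect.pipeline import compute_features

        fm = compute_features(cohort.sessions)[1]
        kept, _ = wcss_filter(fm, top_k=13)
        assert len(kept.feature_names) == 13

    def test_requires_exactly_one_mode(self):
        fm = make_matrix(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValidationError):
            wcss_filter(fm)
        with pytest.raises(ValidationError):
            wcss_filter(fm, threshold=1.0, top_k=2)

    def test_idempotent_under_same_threshold(self):
        rng = np.random.default_rng(1)
        fm = make_matrix(rng.normal(0, 3, size=(12, 6)))
        once, _ = wcss_filter(fm, threshold=50.0)
        twice, _ = wcss_filter(once, threshold=50.0)
        assert twice.feature_names == once.feature_names


class TestNamedSets:
    def test_contextual_sets(self, cohort):
        from edaffect.pipeline import compute_features

        fm = compute_features(cohort.sessions)[3]
        assert len(contextual_set(fm, "signal").feature_names) == 4
        assert len(contextual_set(fm, "error").feature_names) == 4
        assert len(contextual_set(fm, "statistical").feature_names) == 5

    def test_missing_feature_is_named(self, cohort):
        from edaffect.pipeline import compute_features

        fm = compute_features(cohort.sessions)[3]
        crippled = fm.select([n for n in fm.feature_names if n != "kurtosis"])
        with pytest.raises(ValidationError, match="kurtosis"):
            contextual_set(crippled, "statistical")

    def test_paper_presets_cardinalities(self, cohort):
        from edaffect.pipeline import compute_features

        fm = compute_features(cohort.sessions)[1]
        assert len(preset_set(fm, "paper_ex1").feature_names) == 4
        assert len(preset_set(fm, "paper_ex2").feature_names) == 10
        assert len(preset_set(fm, "paper_ex3").feature_names) == 13

    def test_unknown_names_rejected(self, two_cloud_matrix):
        with pytest.raises(ValidationError):
            contextual_set(two_cloud_matrix, "bogus")
        with pytest.raises(ValidationError):
            preset_set(two_cloud_matrix, "bogus")


class TestPca:
    def test_component_count_preserved(self, two_cloud_matrix):
        out = pca_transform(two_cloud_matrix)
        assert out.data.shape == two_cloud_matrix.data.shape

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(2)
        fm = make_matrix(rng.normal(size=(10, 4)))
        out = pca_transform(fm, standardize=True)
        total = out.values().var(axis=0, ddof=1).sum()
        assert total == pytest.approx(4.0, abs=1e-9)  # 4 standardized columns

    def test_pairwise_distances_preserved(self):
        rng = np.random.default_rng(3)
        fm = make_matrix(rng.normal(size=(8, 5)))
        out = pca_transform(fm, standardize=True)
        X = fm.values()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        Z = Z - Z.mean(0)
        Y = out.values()
        for i in range(8):
            for j in range(i + 1, 8):
                dz = np.linalg.norm(Z[i] - Z[j])
                dy = np.linalg.norm(Y[i] - Y[j])
                assert dy == pytest.approx(dz, abs=1e-9)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        data = np.column_stack([rng.normal(size=6), np.full(6, 3.0)])
        fm = make_matrix(data, columns=["a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            out = pca_transform(fm, standardize=True)
        assert out.data.shape[1] == 1

    def test_fewer_than_two_rows_rejected(self):
        fm = make_matrix(np.array([[1.0, 2.0]]))
        with pytest.raises(ValidationError):
            pca_transform(fm)

    def test_components_ordered_by_variance(self):
        rng = np.random.default_rng(5)
        fm = make_matrix(rng.normal(size=(20, 6)))
        out = pca_transform(fm)
        variances = out.values().var(axis=0, ddof=1)
        assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))
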