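import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tamflow.stats import (classify_response, factor_analysis, loading_report,
                           printed_statistics_report, stepwise_regression)


class TestClassifyResponse:
    @pytest.mark.parametrize("change,expected", [
        (68.0, "best"),     # e.g. a 68% YBOCS reduction
        (86.0, "best"),
        (-3.0, "none"),     # worsening counts as no response
        (5.0, "none"),
        (28.0, "moderate"),
        (33.0, "moderate"),
        (50.0, "best"),     # boundary: >= 50
        (10.0, "moderate"),  # boundary: exactly 10 is not 'none'
        (9.999, "none"),
    ])
    def test_classification(self, change, expected):
        assert classify_response(change) == expected

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-200, 200))
    def test_partition_of_reals(self, change):
        assert classify_response(change) in {"best", "moderate", "none"}

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_response(float("nan"))


def two_factor_matrix(n=40, noise=0.05, seed=0):
    """Two orthogonal latent factors, 3 columns each (block loadings)."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=(2, n))
    cols = {}
    for j in range(3):
        cols[f"a{j}"] = f1 * rng.uniform(0.8, 1.2) + noise * rng.normal(size=n)
    for j in range(3):
        cols[f"b{j}"] = f2 * rng.uniform(0.8, 1.2) + noise * rng.normal(size=n)
    return pd.DataFrame(cols), f1, f2


class TestFactorAnalysis:
    def test_rank_one_two_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        mat = pd.DataFrame({"u": x, "v": 2.0 * x})
        fm = factor_analysis(mat, eigen_threshold=1.5)
        assert fm.n_retained == 1
        assert fm.cumulative_variance_pct == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(sorted(np.round(fm.eigenvalues, 9)), [0.0, 2.0])

    def test_eigenvalue_sum_equals_column_count(self):
        mat, _, _ = two_factor_matrix()
        fm = factor_analysis(mat, eigen_threshold=1.0)
        assert fm.eigenvalues.sum() == pytest.approx(mat.shape[1], abs=1e-9)

    def test_two_latent_factors_recovered(self):
        # equal-size blocks give near-equal eigenvalues, where unrotated
        # components mix the blocks; varimax rotation identifies them
        mat, f1, f2 = two_factor_matrix()
        fm = factor_analysis(mat, eigen_threshold=2.0, rotate=True)
        assert fm.n_retained == 2
        # each block loads on exactly one factor up to sign
        a_load = fm.loadings.loc[["a0", "a1", "a2"]]
        b_load = fm.loadings.loc[["b0", "b1", "b2"]]
        a_main = a_load.abs().mean().idxmax()
        b_main = b_load.abs().mean().idxmax()
        assert a_main != b_main
        assert a_load[a_main].abs().min() > 0.9
        assert b_load[b_main].abs().min() > 0.9

    def test_eigenvalues_match_independent_pca(self):
        """Cross-check against scikit-learn's PCA on the standardized
        matrix: explained variances equal the correlation eigenvalues."""
        from sklearn.decomposition import PCA

        mat, _, _ = two_factor_matrix(seed=11)
        X = np.asarray(mat, dtype=float)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = PCA().fit(Z).explained_variance_
        fm = factor_analysis(mat, eigen_threshold=1.0)
        assert np.allclose(np.sort(fm.eigenvalues)[::-1][:len(ref)], ref,
                           atol=1e-9)

    def test_constant_column_rejected_by_name(self):
        mat = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="c"):
            factor_analysis(mat)

    def test_reconstruction_from_scores_and_loadings(self):
        """Standardized data ~ scores @ loadings.T on exact-rank data."""
        mat, _, _ = two_factor_matrix(noise=0.0)
        fm = factor_analysis(mat, eigen_threshold=0.5)
        X = np.asarray(mat, dtype=float)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = np.asarray(fm.scores) @ np.asarray(fm.loadings).T
        # residual variance equals the discarded eigenvalue mass (zero here)
        assert np.abs(Z - recon).max() < 1e-8

    def test_retention_bounded_by_rank(self):
        # with n rows the correlation matrix has rank <= n - 1, so no more
        # than n - 1 factors can ever be retained
        import warnings

        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(3, 8)),
                           columns=[f"c{i}" for i in range(8)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm = factor_analysis(mat, eigen_threshold=1e-9)
        assert fm.n_retained <= 2


class TestStepwiseRegression:
    def test_perfect_single_factor_fit(self):
        mat, f1, f2 = two_factor_matrix(noise=0.0)
        fm = factor_analysis(mat, eigen_threshold=0.5)
        # outcome exactly proportional to the factor aligned with block a
        a_main = fm.loadings.loc[["a0", "a1", "a2"]].abs().mean().idxmax()
        y = 3.0 * np.asarray(fm.scores[a_main])
        sw = stepwise_regression(fm.scores, y)
        assert sw.selected == [a_main]
        assert abs(sw.standardized_beta[a_main]) == pytest.approx(1.0, abs=1e-9)
        assert sw.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_sign_recovery_two_negative_effects(self):
        mat, f1, f2 = two_factor_matrix(noise=0.02, seed=3)
        fm = factor_analysis(mat, eigen_threshold=2.0)
        rng = np.random.default_rng(0)
        s = np.asarray(fm.scores)
        y = -0.8 * s[:, 0] - 0.5 * s[:, 1] + 0.05 * rng.normal(size=len(s))
        sw = stepwise_regression(fm.scores, y)
        assert set(sw.selected) == {"F1", "F2"}
        assert sw.standardized_beta["F1"] < 0
        assert sw.standardized_beta["F2"] < 0

    def test_false_entry_rate_matches_selection_rule(self):
        """Pure-noise candidates at p_enter=0.05: some but few selections
        (family-wise false entry with 4 candidates, n=12)."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 100
        for _ in range(reps):
            scores = pd.DataFrame(rng.normal(size=(12, 4)),
                                  columns=list("ABCD"))
            y = rng.normal(size=12)
            with np.errstate(all="ignore"):
                import warnings as w

                with w.catch_warnings():
                    w.simplefilter("ignore")
                    sw = stepwise_regression(scores, y)
            hits += bool(sw.selected)
        assert 0.02 <= hits / reps <= 0.35

    def test_column_order_invariance(self):
        mat, _, _ = two_factor_matrix(seed=5)
        fm = factor_analysis(mat, eigen_threshold=2.0)
        y = -0.7 * np.asarray(fm.scores["F1"]) + 0.1 * np.random.default_rng(0).normal(size=len(fm.scores))
        sw1 = stepwise_regression(fm.scores, y)
        sw2 = stepwise_regression(fm.scores[fm.scores.columns[::-1]], y)
        assert set(sw1.selected) == set(sw2.selected)
        for k in sw1.standardized_beta:
            assert sw1.standardized_beta[k] == pytest.approx(
                sw2.standardized_beta[k], abs=1e-10)

    def test_zero_variance_outcome_rejected(self):
        scores = pd.DataFrame({"F1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            stepwise_regression(scores, [5.0, 5.0, 5.0])


class TestLoadingReport:
    def test_rank_one_lists_both_variables(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        mat = pd.DataFrame({"u": x, "v": 2.0 * x})
        fm = factor_analysis(mat, eigen_threshold=1.5)
        rep = loading_report(fm, threshold=0.9)
        assert set(rep["F1"]) == {"u", "v"}

    def test_unreachable_threshold_gives_empty_lists(self):
        mat, _, _ = two_factor_matrix()
        fm = factor_analysis(mat, eigen_threshold=2.0)
        rep = loading_report(fm, threshold=1.01)
        assert all(len(v) == 0 for v in rep.values())

    def test_block_structure_recovered(self):
        mat, _, _ = two_factor_matrix(noise=0.02)
        fm = factor_analysis(mat, eigen_threshold=2.0, rotate=True)
        rep = loading_report(fm, threshold=0.9)
        blocks = [set(v) for v in rep.values() if v]
        assert {"a0", "a1", "a2"} in blocks
        assert {"b0", "b1", "b2"} in blocks


class TestPrintedStatisticsReport:
    def test_report_is_internally_consistent(self):
        mat, _, _ = two_factor_matrix(n=20, noise=0.05, seed=9)
        rng = np.random.default_rng(2)
        y = (40.0 - 15.0 * np.asarray(mat["b0"]) + 2.0 * rng.normal(size=20))
        rep = printed_statistics_report(mat, y, eigen_threshold=2.0)
        assert rep["n_factors"] >= 1
        assert 0 < rep["cumulative_variance_pct"] <= 100.0
        assert rep["adjusted_r2"] <= 1.0
        assert len(rep["standardized_betas"]) == len(rep["selected_factors"])
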