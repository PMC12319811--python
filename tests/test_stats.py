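"""PLS-1 inference, FDR, and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dyadsync import (
    ValidationError,
    cohens_d,
    correlation,
    fdr_correct,
    group_compare,
    pls1_fit,
    pls_bootstrap_z,
    pls_inference,
    pls_permutation_test,
    two_way_anova,
    welch_t,
)

from .oracles import bh_reject, pearson


class TestPls1:
    def test_weights_are_normalized_cross_covariance(self, rng):
        for _ in range(10):
            X = rng.normal(size=(10, 6))
            y = rng.normal(size=10)
            m = pls1_fit(X, y)
            xc = X - X.mean(axis=0)
            yc = y - y.mean()
            w = xc.T @ yc
            w = w / np.linalg.norm(w)
            np.testing.assert_allclose(np.abs(m.weights_), np.abs(w), atol=1e-10)
            np.testing.assert_allclose(np.linalg.norm(m.weights_), 1.0, atol=1e-12)

    def test_single_roi_reduces_to_pearson(self, rng):
        X = rng.normal(size=(15, 1))
        y = 0.7 * X[:, 0] + rng.normal(size=15)
        m = pls1_fit(X, y)
        assert abs(m.weights_[0]) == pytest.approx(1.0)
        assert pearson(m.scores_, y) == pytest.approx(pearson(X[:, 0], y), abs=1e-12)

    def test_sign_convention_score_correlates_positively(self, rng):
        X = rng.normal(size=(12, 4))
        y = -X[:, 0] + 0.1 * rng.normal(size=12)
        m = pls1_fit(X, y)
        assert pearson(m.scores_, y) >= 0

    def test_matches_sklearn_first_component(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(20, 7))
        y = X @ rng.normal(size=7) + rng.normal(size=20)
        m = pls1_fit(X, y)
        ref = PLSRegression(n_components=1, scale=False).fit(X, y)
        w_ref = ref.x_weights_[:, 0]
        w_ref = w_ref / np.linalg.norm(w_ref) * np.sign(w_ref @ m.weights_)
        np.testing.assert_allclose(m.weights_, w_ref, atol=1e-10)

    def test_zero_variance_y_errors(self, rng):
        with pytest.raises(ValidationError):
            pls1_fit(rng.normal(size=(8, 3)), np.ones(8))


class TestPermutationTest:
    def test_perfect_signal_attains_minimum_p(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0])
        p, _ = pls_permutation_test(X, y, n_perm=200, seed=0)
        assert p == pytest.approx(1.0 / 201.0)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        p1, null1 = pls_permutation_test(X, y, n_perm=150, seed=9)
        p2, null2 = pls_permutation_test(X, y, n_perm=150, seed=9)
        assert p1 == p2
        np.testing.assert_array_equal(null1, null2)

    def test_null_statistic_matches_estimator_refit(self, rng):
        # the batched permutation statistic must equal a literal refit
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        _, null = pls_permutation_test(X, y, n_perm=100, seed=3)
        # recompute the first few permutations exactly as the test draws them
        rng3 = np.random.default_rng(3)
        for i in range(5):
            yp = rng3.permutation(y)
            assert null[i] == pytest.approx(
                pls1_fit(X, yp).covariance_explained_, abs=1e-12
            )

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValidationError):
            pls_permutation_test(rng.normal(size=(10, 3)), rng.normal(size=10),
                                 n_perm=50)


class TestBootstrap:
    def test_signal_roi_has_largest_z(self, rng):
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(rep)
            X = r.normal(size=(40, 5))
            y = 2.0 * X[:, 2] + 0.5 * r.normal(size=40)
            tab = pls_bootstrap_z(X, y, n_boot=100, seed=rep)
            hits += int(np.argmax(np.abs(tab["z"])) == 2)
        assert hits >= 9

    def test_duplicating_dyads_shrinks_se(self, rng):
        X = rng.normal(size=(20, 4))
        y = X[:, 0] + rng.normal(size=20)
        base = pls_bootstrap_z(X, y, n_boot=200, seed=0)
        doubled = pls_bootstrap_z(
            np.vstack([X, X]), np.concatenate([y, y]), n_boot=200, seed=0
        )
        assert doubled["se"].mean() < base["se"].mean()
        assert doubled["z"].abs().mean() > base["z"].abs().mean()

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        a = pls_bootstrap_z(X, y, n_boot=100, seed=4)
        b = pls_bootstrap_z(X, y, n_boot=100, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_brackets_weight(self, rng):
        X = rng.normal(size=(25, 4))
        y = X[:, 1] + rng.normal(size=25)
        tab = pls_bootstrap_z(X, y, n_boot=150, seed=1)
        assert (tab["ci_low"] <= tab["weight"]).all()
        assert (tab["ci_high"] >= tab["weight"]).all()


class TestFdr:
    def test_hand_example(self):
        mask, _ = fdr_correct([0.01, 0.02, 0.04, 0.20], q=0.05)
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_all_small_all_rejected(self):
        mask, _ = fdr_correct([0.001] * 6, q=0.05)
        assert mask.all()

    def test_all_large_none_rejected(self):
        mask, _ = fdr_correct([0.9] * 6, q=0.05)
        assert not mask.any()

    def test_matches_hand_bh_on_random_p(self, rng):
        for _ in range(20):
            p = rng.uniform(size=12)
            mask, _ = fdr_correct(p, q=0.1)
            np.testing.assert_array_equal(mask, bh_reject(p, 0.1))

    def test_rejections_are_prefix_of_sorted_p(self, rng):
        p = rng.uniform(size=15)
        mask, p_adj = fdr_correct(p, q=0.2)
        order = np.argsort(p)
        sorted_mask = mask[order]
        assert not np.any(np.diff(sorted_mask.astype(int)) > 0)  # no False->True
        assert np.all(np.diff(p_adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            fdr_correct([0.5, 1.2])


class TestGroupTests:
    def test_identical_groups_t_and_d_zero(self, rng):
        a = rng.normal(size=10)
        res = welch_t(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_with_tiny_jitter(self, rng):
        a = 0.0 + 1e-6 * rng.normal(size=6)
        b = 1.0 + 1e-6 * rng.normal(size=6)
        res = welch_t(b, a)
        assert res.statistic > 1e4
        assert res.cohens_d > 1e4

    def test_welch_matches_pingouin(self, rng):
        import pingouin as pg

        a, b = rng.normal(size=12), rng.normal(loc=0.4, size=15)
        res = welch_t(a, b)
        ref = pg.ttest(a, b, correction=True)
        assert res.statistic == pytest.approx(float(ref["T"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_cohens_d_sign_follows_mean_difference(self, rng):
        a, b = rng.normal(loc=1, size=20), rng.normal(loc=0, size=20)
        assert cohens_d(a, b) > 0 and cohens_d(b, a) < 0

    def test_anova_matches_pingouin(self, rng):
        import pingouin as pg

        n = 12
        rows = []
        for state in ("movie", "rest"):
            for status in ("high", "low", "random"):
                base = {"movie": 0.3, "rest": 0.1}[state]
                shift = {"high": 0.2, "low": 0.1, "random": 0.0}[status]
                for v in base + shift + 0.1 * rng.normal(size=n):
                    rows.append({"ists": v, "state": state, "status": status})
        df = pd.DataFrame(rows)
        table = two_way_anova(df, "ists", "state", "status")
        ref = pg.anova(data=df, dv="ists", between=["state", "status"])
        ref = ref.set_index("Source")
        assert table.loc["C(state)", "F"] == pytest.approx(
            float(ref.loc["state", "F"]), abs=1e-6
        )
        assert table.loc["C(state):C(status)", "F"] == pytest.approx(
            float(ref.loc["state * status", "F"]), abs=1e-6
        )

    def test_correlations_match_scipy(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = correlation(x, y, "pearson")
        r, p = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(r) and res.p == pytest.approx(p)
        res_s = correlation(x, y, "spearman")
        r_s, p_s = sps.spearmanr(x, y)
        assert res_s.statistic == pytest.approx(r_s)

    def test_group_compare_table(self, rng):
        out = group_compare(
            {"high": rng.normal(1, 1, 10), "low": rng.normal(0, 1, 10),
             "random": rng.normal(-1, 1, 10)}
        )
        assert len(out) == 3
        assert set(out.columns) == {"group_a", "group_b", "t", "df", "p", "cohens_d"}

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            group_compare({"a": np.array([]), "b": np.array([1.0, 2.0])})


class TestPlsInference:
    def test_full_pipeline_flags_signal_regions(self, rng):
        X = rng.normal(size=(40, 6))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.5 * rng.normal(size=40)
        res = pls_inference(X, y, n_perm=200, n_boot=150, seed=0)
        assert res.p_permutation < 0.05
        assert res.roi_table["fdr_significant"].iloc[0]
        assert res.roi_table["fdr_significant"].iloc[1]
        assert res.roi_table.loc[res.roi_table["fdr_significant"], "p_fdr"].lt(0.05).all()
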