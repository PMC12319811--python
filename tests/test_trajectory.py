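"""Trajectory matrices, ISTS, random pairs, z-scoring, whole-brain means."""

import numpy as np
import pandas as pd
import pytest

from dyadsync import (
    ValidationError,
    build_trajectory_matrix,
    compute_ists,
    make_random_pairs,
    whole_brain_average,
    zscore_across_dyads,
)
from dyadsync.trajectory import IstsTable

from .conftest import make_ts
from .oracles import all_derangements, naive_ists, naive_trajectory_matrix, pearson


class TestBuildTrajectoryMatrix:
    def test_hand_computed_three_patterns(self):
        # MVPs (1,2,3), (3,2,1), (1,0,1): r12=-1, r13=0, r23=0
        data = np.array([[1, 3, 1], [2, 2, 0], [3, 1, 1]], dtype=float)
        m = build_trajectory_matrix(make_ts(data)).matrix
        expected = np.array([[1, -1, 0], [-1, 1, 0], [0, 0, 1]], dtype=float)
        np.testing.assert_allclose(m, expected, atol=1e-12)

    def test_constant_trajectory_all_ones(self):
        data = np.tile([[1.0], [2.0], [5.0]], (1, 6))
        m = build_trajectory_matrix(make_ts(data)).matrix
        np.testing.assert_allclose(m, 1.0)

    def test_matches_double_loop_pearson(self, rng):
        for _ in range(10):
            data = rng.normal(size=(7, 10))
            m = build_trajectory_matrix(make_ts(data)).matrix
            np.testing.assert_allclose(m, naive_trajectory_matrix(data), atol=1e-12)

    def test_invariants_symmetric_unit_diagonal_bounded(self, rng):
        m = build_trajectory_matrix(make_ts(rng.normal(size=(9, 14)))).matrix
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 1.0)
        assert np.all(m >= -1) and np.all(m <= 1)

    def test_zero_variance_tr_marked_missing(self, rng):
        data = rng.normal(size=(5, 8))
        data[:, 3] = 2.0
        m = build_trajectory_matrix(make_ts(data)).matrix
        assert np.isnan(m[3, :4]).all() and np.isnan(m[:3, 3]).all()
        assert np.isfinite(m[np.ix_([0, 1, 2, 4], [0, 1, 2, 4])]).all()

    def test_tr_mask_selects_columns(self, rng):
        data = rng.normal(size=(6, 12))
        idx = np.array([0, 3, 4, 9])
        m = build_trajectory_matrix(make_ts(data), tr_mask=idx).matrix
        np.testing.assert_allclose(m, naive_trajectory_matrix(data[:, idx]), atol=1e-12)

    def test_too_few_trs_after_masking_errors(self, rng):
        ts = make_ts(rng.normal(size=(5, 10)))
        with pytest.raises(ValidationError):
            build_trajectory_matrix(ts, tr_mask=np.array([1, 2]))


class TestComputeIsts:
    def test_identity_is_one(self, rng):
        m = build_trajectory_matrix(make_ts(rng.normal(size=(6, 8))))
        assert compute_ists(m, m) == pytest.approx(1.0)

    def test_linear_decreasing_transform_is_minus_one(self, rng):
        a = build_trajectory_matrix(make_ts(rng.normal(size=(6, 8))))
        b_mat = 0.5 - 0.25 * a.matrix
        np.fill_diagonal(b_mat, 1.0)
        from dyadsync.trajectory import PatternTrajectoryMatrix

        b = PatternTrajectoryMatrix("s2", 1, b_mat)
        assert compute_ists(a, b) == pytest.approx(-1.0)

    def test_matches_upper_triangle_correlation(self, rng):
        a = build_trajectory_matrix(make_ts(rng.normal(size=(7, 5))))
        b = build_trajectory_matrix(make_ts(rng.normal(size=(7, 5)), "s2"))
        assert compute_ists(a, b) == pytest.approx(
            naive_ists(a.matrix, b.matrix), abs=1e-12
        )

    def test_symmetric_in_arguments(self, rng):
        a = build_trajectory_matrix(make_ts(rng.normal(size=(6, 9))))
        b = build_trajectory_matrix(make_ts(rng.normal(size=(6, 9)), "s2"))
        assert compute_ists(a, b) == pytest.approx(compute_ists(b, a), abs=1e-15)

    def test_invariant_to_common_tr_reordering(self, rng):
        da, db = rng.normal(size=(6, 9)), rng.normal(size=(6, 9))
        perm = rng.permutation(9)
        before = compute_ists(
            build_trajectory_matrix(make_ts(da)),
            build_trajectory_matrix(make_ts(db, "s2")),
        )
        after = compute_ists(
            build_trajectory_matrix(make_ts(da[:, perm])),
            build_trajectory_matrix(make_ts(db[:, perm], "s2")),
        )
        assert after == pytest.approx(before, abs=1e-12)

    def test_invariant_to_per_tr_affine_rescaling(self, rng):
        da, db = rng.normal(size=(6, 9)), rng.normal(size=(6, 9))
        scale = rng.uniform(0.5, 3.0, size=9)
        shift = rng.normal(size=9)
        before = compute_ists(
            build_trajectory_matrix(make_ts(da)),
            build_trajectory_matrix(make_ts(db, "s2")),
        )
        after = compute_ists(
            build_trajectory_matrix(make_ts(da * scale + shift)),
            build_trajectory_matrix(make_ts(db, "s2")),
        )
        assert after == pytest.approx(before, abs=1e-12)

    def test_shape_mismatch_errors(self, rng):
        a = build_trajectory_matrix(make_ts(rng.normal(size=(5, 6))))
        b = build_trajectory_matrix(make_ts(rng.normal(size=(5, 7)), "s2"))
        with pytest.raises(ValidationError):
            compute_ists(a, b)

    def test_missing_entries_dropped_pairwise(self, rng):
        da, db = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
        da[:, 2] = 1.0  # zero-variance TR in both members
        db[:, 2] = 4.0
        a = build_trajectory_matrix(make_ts(da))
        b = build_trajectory_matrix(make_ts(db, "s2"))
        keep = [0, 1, 3, 4, 5, 6, 7]
        expected = naive_ists(a.matrix[np.ix_(keep, keep)], b.matrix[np.ix_(keep, keep)])
        assert compute_ists(a, b) == pytest.approx(expected, abs=1e-12)


class TestMakeRandomPairs:
    def test_two_couples_forced_swap(self, couple_table):
        pairs = make_random_pairs(couple_table.iloc[:2], seed=0)
        assert set(pairs["female_id"]) == {"f1", "f2"}
        assert pairs.loc[pairs["male_id"] == "m1", "female_id"].item() == "f2"
        assert pairs.loc[pairs["male_id"] == "m2", "female_id"].item() == "f1"

    def test_three_couples_yields_valid_derangement(self, couple_table):
        pairs = make_random_pairs(couple_table, seed=5)
        perm = tuple(
            int(pairs.loc[pairs["male_id"] == f"m{i+1}", "female_id"].item()[1:]) - 1
            for i in range(3)
        )
        assert perm in set(all_derangements(3))
        again = make_random_pairs(couple_table, seed=5)
        pd.testing.assert_frame_equal(pairs, again)

    @pytest.mark.parametrize("seed", range(12))
    def test_never_pairs_spouses_and_no_reuse(self, couple_table, seed):
        pairs = make_random_pairs(couple_table, seed=seed)
        spouse = dict(zip(couple_table["male_id"], couple_table["female_id"]))
        assert not any(spouse[m] == f for m, f in zip(pairs["male_id"], pairs["female_id"]))
        assert pairs["female_id"].is_unique and pairs["male_id"].is_unique

    def test_single_couple_errors(self, couple_table):
        with pytest.raises(ValidationError):
            make_random_pairs(couple_table.iloc[:1], seed=0)


def _table(values, classes, dyad_ids=None):
    dyad_ids = dyad_ids or [f"d{i}" for i in range(len(values))]
    dyads = pd.DataFrame(
        {
            "dyad_id": dyad_ids,
            "male_id": [f"m{i}" for i in range(len(values))],
            "female_id": [f"f{i}" for i in range(len(values))],
            "dyad_class": classes,
            "cmqi_score": np.nan,
            "marriage_duration": np.nan,
        }
    )
    vals = pd.DataFrame(values, index=pd.Index(dyad_ids, name="dyad_id"))
    return IstsTable(values=vals, dyads=dyads)


class TestZscoreAcrossDyads:
    def test_hand_example(self):
        tab = _table([[0.1], [0.2], [0.3]], ["random"] * 3)
        z = zscore_across_dyads(tab).zvalues[0].to_numpy()
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mean_zero_sd_one(self, rng):
        tab = _table(rng.normal(size=(9, 4)), ["random"] * 9)
        z = zscore_across_dyads(tab).zvalues
        assert z.mean(axis=0).abs().max() < 1e-10
        assert (z.std(axis=0, ddof=1) - 1).abs().max() < 1e-10

    def test_degenerate_roi_missing_with_warning(self, caplog):
        tab = _table([[0.5, 0.1], [0.5, 0.2], [0.5, 0.3]], ["random"] * 3)
        z = zscore_across_dyads(tab).zvalues
        assert z[0].isna().all() and z[1].notna().all()

    def test_class_restriction_excludes_other_rows(self):
        tab = _table([[0.1], [0.2], [0.3], [0.9]], ["random"] * 3 + ["couple_high"])
        z = zscore_across_dyads(tab, classes_included={"random"}).zvalues
        np.testing.assert_allclose(z[0].to_numpy()[:3], [-1, 0, 1], atol=1e-12)
        assert np.isnan(z[0].to_numpy()[3])


class TestWholeBrainAverage:
    def test_two_rois(self):
        tab = _table([[0.2, 0.4]], ["random"])
        out = whole_brain_average(tab)
        assert out["mean_ists"].item() == pytest.approx(0.3)
        assert out["n_rois"].item() == 2

    def test_missing_roi_skipped_and_counted(self):
        tab = _table([[0.1, np.nan, 0.5]], ["random"])
        out = whole_brain_average(tab)
        assert out["mean_ists"].item() == pytest.approx(0.3)
        assert out["n_rois"].item() == 2

    def test_matches_brute_force_mean(self, rng):
        vals = rng.normal(size=(6, 10))
        tab = _table(vals, ["random"] * 6)
        out = whole_brain_average(tab)
        np.testing.assert_allclose(out["mean_ists"], vals.mean(axis=1), atol=1e-12)
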