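import numpy as np
import pytest

import tfcircuit as tc
from tfcircuit.differential import FlaggedPair  # noqa: F401  (re-exported dataclass)


@pytest.fixture
def conn3x2():
    return tc.ConnectivityMatrix(
        gene_ids=["g1", "g2", "g3"],
        tf_ids=["f1", "f2"],
        entries=np.array([[1, 1], [1, 0], [0, 1]]),
    )


class TestNormalizedActivity:
    def test_ratio_and_absolute_value(self, conn3x2):
        W = np.array([[-3.0, 1.0], [2.0, 0.0], [0.0, 4.0]])
        act = tc.normalized_activity(W, np.array([2.0, 1.0]), conn3x2)
        assert act.A[0, 0] == pytest.approx(1.5)
        assert act.clamped_tfs == []

    def test_zero_concentration_clamped_to_floor(self, conn3x2):
        W = np.zeros((3, 2))
        W[0, 0] = 1.0
        act = tc.normalized_activity(W, np.array([0.0, 1.0]), conn3x2, epsilon=1e-6)
        assert act.A[0, 0] == pytest.approx(1e6)
        assert act.clamped_tfs == ["f1"]

    def test_off_support_zero_regardless_of_w(self, conn3x2):
        W = np.full((3, 2), 9.0)
        act = tc.normalized_activity(W, np.array([1.0, 1.0]), conn3x2)
        assert act.A[2, 0] == 0.0 and act.A[1, 1] == 0.0

    def test_nonpositive_epsilon_rejected(self, conn3x2):
        with pytest.raises(tc.ValidationError):
            tc.normalized_activity(np.zeros((3, 2)), np.ones(2), conn3x2, epsilon=0.0)


class TestActivityDifference:
    def test_identity_and_subtraction(self, conn3x2):
        a = tc.normalized_activity(np.ones((3, 2)) * 5, np.ones(2), conn3x2)
        b = tc.normalized_activity(np.ones((3, 2)) * 2, np.ones(2), conn3x2)
        D = tc.activity_difference(a, b)
        assert D[0, 0] == pytest.approx(3.0)
        assert np.all(tc.activity_difference(a, a) == 0)

    def test_antisymmetry(self, conn3x2):
        rng = np.random.default_rng(0)
        a = tc.normalized_activity(rng.standard_normal((3, 2)), np.ones(2), conn3x2)
        b = tc.normalized_activity(rng.standard_normal((3, 2)), np.ones(2), conn3x2)
        np.testing.assert_allclose(
            tc.activity_difference(a, b), -tc.activity_difference(b, a)
        )

    def test_mismatched_universes_rejected(self, conn3x2):
        a = tc.normalized_activity(np.zeros((3, 2)), np.ones(2), conn3x2)
        other = tc.ConnectivityMatrix(["gX"], ["f1"], np.array([[1]]))
        b = tc.normalized_activity(np.zeros((1, 1)), np.ones(1), other)
        with pytest.raises(tc.ValidationError):
            tc.activity_difference(a, b)


class TestSignificanceCutoff:
    def test_hand_computed_sample_sd(self):
        conn = tc.ConnectivityMatrix(["g1", "g2", "g3"], ["f1"], np.ones((3, 1), dtype=np.int8))
        D = np.array([[-1.0], [0.0], [1.0]])
        # sample SD of {-1, 0, 1} is exactly 1
        assert tc.significance_cutoff(D, conn, k=2.0) == pytest.approx(2.0)

    def test_zero_variance_and_homogeneity(self):
        conn = tc.ConnectivityMatrix(["g1", "g2"], ["f1"], np.ones((2, 1), dtype=np.int8))
        assert tc.significance_cutoff(np.array([[3.0], [3.0]]), conn) == 0.0
        D = np.array([[1.0], [-2.0]])
        assert tc.significance_cutoff(10 * D, conn) == pytest.approx(
            10 * tc.significance_cutoff(D, conn)
        )

    def test_off_support_zeros_excluded(self):
        conn = tc.ConnectivityMatrix(
            ["g1", "g2", "g3"], ["f1"], np.array([[1], [1], [0]], dtype=np.int8)
        )
        D = np.array([[-1.0], [1.0], [0.0]])
        # only the two support entries count: SD = sqrt(2), not the
        # deflated value over three entries
        assert tc.significance_cutoff(D, conn, k=1.0) == pytest.approx(np.sqrt(2.0))

    def test_too_few_support_entries_rejected(self):
        conn = tc.ConnectivityMatrix(["g1", "g2"], ["f1"], np.array([[1], [0]], dtype=np.int8))
        with pytest.raises(tc.ValidationError):
            tc.significance_cutoff(np.zeros((2, 1)), conn)


class TestFlagInteractions:
    def test_sign_rule(self):
        conn = tc.ConnectivityMatrix(["g1", "g2"], ["f1", "f2"], np.ones((2, 2), dtype=np.int8))
        D = np.array([[3.0, 0.0], [-3.0, 0.0]])
        pairs = {(p.gene_id, p.tf_id, p.regulation) for p in tc.flag_interactions(D, conn, 2.0)}
        assert pairs == {("g1", "f1", "Down"), ("g2", "f1", "Up")}

    def test_boundary_is_strict(self):
        conn = tc.ConnectivityMatrix(["g1"], ["f1"], np.array([[1]]))
        assert tc.flag_interactions(np.array([[2.0]]), conn, 2.0) == []
        assert len(tc.flag_interactions(np.array([[2.0]]), conn, 0.0)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        conn = tc.ConnectivityMatrix(
            [f"g{i}" for i in range(20)],
            [f"f{j}" for j in range(5)],
            (rng.random((20, 5)) < 0.5).astype(np.int8),
        )
        D = rng.standard_normal((20, 5)) * conn.entries
        cutoff = 1.0
        got = {(p.gene_id, p.tf_id, p.regulation) for p in tc.flag_interactions(D, conn, cutoff)}
        want = set()
        for i in range(20):
            for j in range(5):
                if conn.entries[i, j] and abs(D[i, j]) > cutoff:
                    want.add((f"g{i}", f"f{j}", "Down" if D[i, j] > 0 else "Up"))
        assert got == want


class TestAverageStrength:
    def test_mean_absolute_weight(self):
        conn = tc.ConnectivityMatrix(
            ["g1", "g2", "g3"], ["f1"], np.array([[1], [1], [0]], dtype=np.int8)
        )
        W = np.array([[2.0], [-4.0], [0.0]])
        assert tc.average_strength(W, conn)[0] == pytest.approx(3.0)
        assert tc.average_strength(np.zeros((3, 1)), conn)[0] == 0.0

    def test_tf_without_targets_rejected(self):
        conn = tc.ConnectivityMatrix(["g1"], ["f1", "f2"], np.array([[1, 0]], dtype=np.int8))
        with pytest.raises(tc.ValidationError):
            tc.average_strength(np.zeros((1, 2)), conn)


class TestFlagTfs:
    def test_single_outlier_detected(self):
        tf_ids = [f"f{i}" for i in range(5)]
        v_ref = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
        v_alt = np.zeros(5)
        # delta = [0,0,0,0,100]: median 0, sample SD = 44.72, band 89.4
        flags = tc.flag_tfs(tf_ids, v_ref, v_alt, k=2.0)
        assert flags == {"f4": "Down"}

    def test_no_dispersion_no_flags(self):
        assert tc.flag_tfs(["a", "b", "c"], np.ones(3), np.zeros(3)) == {}

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        v_ref = rng.standard_normal(8)
        v_alt = rng.standard_normal(8)
        ids = [f"f{i}" for i in range(8)]
        assert tc.flag_tfs(ids, v_ref, v_alt) == tc.flag_tfs(ids, v_ref + 5, v_alt + 5)

    def test_too_few_tfs_rejected(self):
        with pytest.raises(tc.ValidationError):
            tc.flag_tfs(["a", "b"], np.zeros(2), np.zeros(2))


class TestCompare:
    def test_swapping_conditions_negates_and_relabels(self, fitted_pair):
        ds, ref, alt, forward = fitted_pair
        backward = tc.compare(alt, ref, ds.conn)
        np.testing.assert_allclose(backward.D, -forward.D)
        assert backward.cutoff == pytest.approx(forward.cutoff)
        fwd = {(p.gene_id, p.tf_id): p.regulation for p in forward.flagged_pairs}
        bwd = {(p.gene_id, p.tf_id): p.regulation for p in backward.flagged_pairs}
        assert fwd.keys() == bwd.keys()
        assert all(fwd[k] != bwd[k] for k in fwd)

    def test_flagged_pairs_match_cutoff_definition(self, fitted_pair):
        ds, _, _, result = fitted_pair
        support = ds.conn.entries == 1
        n_above = int((np.abs(result.D) > result.cutoff)[support].sum())
        assert n_above == len(result.flagged_pairs)

    def test_planted_activity_tfs_flagged(self, fitted_pair):
        ds, _, _, result = fitted_pair
        assert ds.perturbed_tf_ids <= set(result.flagged_tfs_activity)
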