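"""Subject-wise permutation test, significance masks, ROI count maps,
and the head-motion synchronization check."""

import numpy as np
import pytest

from isfcpipe.inference import (
    InferenceError,
    SignificanceMask,
    intersubject_motion_coupling,
    pooled_pair_tensor,
    roi_count_map,
    subject_wise_permutation_test,
)
from isfcpipe.inference import _median_diff
from isfcpipe.isfc import group_pairwise_isfc
from isfcpipe.preprocess import CleanedSeries

from conftest import make_subjects


def two_group_subjects(rng, n_nt=5, n_aut=5, t=80, r=4):
    return make_subjects(n_nt, t, r, rng, group="NT") + make_subjects(
        n_aut, t, r, rng, group="AUT"
    )


class TestPooledPairTensor:
    def test_pooled_pair_count(self, rng):
        pool = pooled_pair_tensor(two_group_subjects(rng, 3, 2))
        assert pool.matrices.shape[0] == 10  # C(5, 2)

    def test_within_group_restriction_is_bit_exact(self, rng):
        subs = two_group_subjects(rng, 4, 3)
        pool = pooled_pair_tensor(subs)
        for g, members in (("NT", subs[:4]), ("AUT", subs[4:])):
            direct = group_pairwise_isfc(members)
            restricted = pool.restrict(g)
            assert restricted.pair_index == direct.pair_index
            assert np.array_equal(restricted.matrices, direct.matrices)

    def test_tensor_is_immutable(self, rng):
        pool = pooled_pair_tensor(two_group_subjects(rng))
        with pytest.raises(ValueError):
            pool.matrices[0, 0, 0] = 0.0

    def test_too_small_group_raises(self, rng):
        subs = make_subjects(4, 50, 3, rng, group="NT") + make_subjects(
            1, 50, 3, rng, group="AUT"
        )
        with pytest.raises(InferenceError):
            pooled_pair_tensor(subs)


class TestSubjectWisePermutationTest:
    def test_identity_shuffle_reproduces_observed(self, rng):
        subs = two_group_subjects(rng)
        pool = pooled_pair_tensor(subs)
        res = subject_wise_permutation_test(pool, n_permutations=100, seed=1)
        direct = _median_diff(
            pool.matrices, pool.pair_subjects, np.asarray(pool.labels), pool.groups
        )
        assert np.array_equal(res.observed_diff, direct)

    def test_duplicated_cohort_has_no_signal(self, rng):
        nt = make_subjects(4, 60, 3, rng, group="NT")
        aut = [
            CleanedSeries(s.data.copy(), s.subject_id.replace("NT", "AUT"), "AUT")
            for s in nt
        ]
        pool = pooled_pair_tensor(nt + aut)
        res = subject_wise_permutation_test(pool, n_permutations=200, seed=0)
        assert np.allclose(res.observed_diff, 0.0, atol=1e-12)
        for mask in res.masks.values():
            assert np.all(mask.values == 0)

    def test_label_swap_flips_sign(self, rng):
        subs = two_group_subjects(rng, 4, 4)
        pool_fwd = pooled_pair_tensor(subs, groups=("NT", "AUT"))
        pool_rev = pooled_pair_tensor(subs, groups=("AUT", "NT"))
        fwd = subject_wise_permutation_test(pool_fwd, n_permutations=300, seed=5)
        rev = subject_wise_permutation_test(pool_rev, n_permutations=300, seed=5)
        assert np.allclose(fwd.observed_diff, -rev.observed_diff)
        assert np.array_equal(
            fwd.masks[0.05].values, -rev.masks[0.05].values
        )

    def test_fixed_seed_is_reproducible(self, rng):
        pool = pooled_pair_tensor(two_group_subjects(rng))
        a = subject_wise_permutation_test(pool, n_permutations=150, seed=42)
        b = subject_wise_permutation_test(pool, n_permutations=150, seed=42)
        assert np.array_equal(a.p_values, b.p_values)
        assert np.array_equal(a.masks[0.05].values, b.masks[0.05].values)

    def test_exhaustive_enumeration_when_few_shuffles_exist(self, rng):
        subs = two_group_subjects(rng, 3, 3, t=40, r=3)
        pool = pooled_pair_tensor(subs)
        with pytest.warns(UserWarning, match="enumerat"):
            res = subject_wise_permutation_test(pool, n_permutations=100, seed=0)
        assert res.n_permutations == 20  # C(6, 3)

    def test_p_values_in_half_open_unit_interval(self, rng):
        pool = pooled_pair_tensor(two_group_subjects(rng))
        res = subject_wise_permutation_test(pool, n_permutations=120, seed=3)
        iu = np.triu_indices(res.p_values.shape[0], k=1)
        assert (res.p_values[iu] > 0).all() and (res.p_values[iu] <= 1).all()

    def test_masks_consistent_with_quantiles(self, rng):
        pool = pooled_pair_tensor(two_group_subjects(rng, 6, 6))
        res = subject_wise_permutation_test(pool, n_permutations=400, seed=9)
        obs = res.observed_diff
        hi, lo = res.null_quantiles[97.5], res.null_quantiles[2.5]
        expect = np.where(obs > hi, 1, np.where(obs < lo, -1, 0))
        np.fill_diagonal(expect, 0)
        assert np.array_equal(res.masks[0.05].values, expect)

    def test_too_few_permutations_rejected(self, rng):
        pool = pooled_pair_tensor(two_group_subjects(rng))
        with pytest.raises(InferenceError):
            subject_wise_permutation_test(pool, n_permutations=50)


class TestSignificanceMask:
    def test_rejects_asymmetric_or_offrange_values(self):
        with pytest.raises(InferenceError):
            SignificanceMask(np.array([[0, 1], [0, 0]]), alpha=0.05)
        with pytest.raises(InferenceError):
            SignificanceMask(np.full((2, 2), 3), alpha=0.05)

    def test_diagonal_forced_to_zero(self):
        m = SignificanceMask(np.eye(3, dtype=int), alpha=0.05)
        assert np.all(np.diag(m.values) == 0)


class TestRoiCountMap:
    def test_all_zero_mask(self):
        mask = SignificanceMask(np.zeros((4, 4), dtype=int), alpha=0.05)
        counts = roi_count_map(mask)
        assert (counts[["positive_count", "negative_count"]] == 0).all().all()

    def test_single_positive_pair(self):
        v = np.zeros((5, 5), dtype=int)
        v[1, 3] = v[3, 1] = 1
        counts = roi_count_map(SignificanceMask(v, alpha=0.05))
        assert counts["positive_count"].tolist() == [0, 1, 0, 1, 0]
        assert counts["negative_count"].sum() == 0

    def test_matches_exhaustive_enumeration(self, rng):
        r = 10
        v = np.zeros((r, r), dtype=int)
        iu = np.triu_indices(r, k=1)
        pick = rng.choice(iu[0].size, size=20, replace=False)
        signs = rng.choice([-1, 1], size=20)
        for k, s in zip(pick, signs):
            i, j = iu[0][k], iu[1][k]
            v[i, j] = v[j, i] = s
        counts = roi_count_map(SignificanceMask(v, alpha=0.05))
        for region in range(r):
            pos = sum(
                1 for jj in range(r) if jj != region and v[region, jj] == 1
            )
            neg = sum(
                1 for jj in range(r) if jj != region and v[region, jj] == -1
            )
            assert counts.loc[region, "positive_count"] == pos
            assert counts.loc[region, "negative_count"] == neg
        # each significant pair contributes to exactly two regions
        assert counts["positive_count"].sum() == 2 * (v[iu] == 1).sum()


class TestMotionCoupling:
    def test_identical_fd_series_fully_coupled(self, rng):
        fd = np.abs(rng.standard_normal(100))
        fd[0] = 0.0
        series = [fd.copy() for _ in range(4)]
        res = intersubject_motion_coupling(
            series, ["NT", "NT", "AUT", "AUT"], n_permutations=100, seed=0
        )
        assert np.allclose(res.pair_table["correlation"], 1.0)

    def test_independent_motion_has_null_coupling(self, rng):
        t = 300
        series = [np.r_[0.0, np.abs(rng.standard_normal(t - 1))] for _ in range(8)]
        res = intersubject_motion_coupling(
            series, ["NT"] * 4 + ["AUT"] * 4, n_permutations=100, seed=1
        )
        assert abs(res.pair_table["correlation"].median()) < 3 / np.sqrt(t)

    def test_null_group_comparison_is_calibrated(self):
        """Equal-distribution groups should rarely reach significance."""
        n_sig = 0
        n_sims = 100
        for k in range(n_sims):
            g = np.random.default_rng(1000 + k)
            series = [
                np.r_[0.0, np.abs(g.standard_normal(120))] for _ in range(8)
            ]
            res = intersubject_motion_coupling(
                series, ["NT"] * 4 + ["AUT"] * 4, n_permutations=100, seed=k
            )
            n_sig += res.p_value <= 0.05
        assert n_sig <= 10  # p > .05 in at least 90% of simulations

    def test_constant_fd_series_raises_naming_subject(self):
        flat = np.zeros(50)
        with pytest.raises(InferenceError, match="sub-02"):
            intersubject_motion_coupling(
                [np.r_[0.0, np.abs(np.random.default_rng(0).standard_normal(49))],
                 flat, flat, flat],
                ["NT", "NT", "AUT", "AUT"],
                subject_ids=["sub-01", "sub-02", "sub-03", "sub-04"],
            )
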