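"""Nonparametric inference: MW/HL, ROC sweep, ANOVA, permutation clustering."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from vocaldyad.core import InsufficientDataError, ParameterError, ZeroVarianceError
from vocaldyad.stats import (
    mw_hl,
    oneway_f,
    permutation_cluster,
    roc_auc,
)


def enumerate_mw_p(real, control):
    """Brute-force two-sided permutation p for U, by explicit pairwise counts."""
    real = np.asarray(real, float)
    control = np.asarray(control, float)
    pooled = np.concatenate([real, control])
    n, big_n = len(real), len(pooled)

    def u_stat(first_idx):
        first = pooled[list(first_idx)]
        rest = pooled[[i for i in range(big_n) if i not in first_idx]]
        wins = sum((a > b) + 0.5 * (a == b) for a in first for b in rest)
        return wins

    u_obs = u_stat(tuple(range(n)))
    us = [u_stat(c) for c in combinations(range(big_n), n)]
    total = comb(big_n, n)
    n_le = sum(u <= u_obs + 1e-9 for u in us)
    n_ge = sum(u >= u_obs - 1e-9 for u in us)
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


class TestMannWhitneyHL:
    def test_separated_samples_exact_p_and_hl(self):
        res = mw_hl([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1)
        assert res.hl == pytest.approx(-3.0)
        assert res.u == 0.0

    def test_identical_samples_are_null(self):
        res = mw_hl([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p == pytest.approx(1.0)
        assert res.hl == pytest.approx(0.0)

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_hl_shift_equivariance(self, control, c):
        shifted = [x + c for x in control]
        assert mw_hl(shifted, control).hl == pytest.approx(c, abs=1e-9)

    def test_exact_p_matches_bruteforce_enumeration_with_ties(self, rng):
        for _ in range(20):
            n, m = rng.integers(2, 6, size=2)
            real = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            control = rng.integers(0, 4, size=m).astype(float)
            assert mw_hl(real, control).p == pytest.approx(
                enumerate_mw_p(real, control), abs=1e-12
            )

    def test_exact_p_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(20):
            n, m = rng.integers(3, 8, size=2)
            real = rng.normal(size=n)
            control = rng.normal(size=m)
            expected = sps.mannwhitneyu(real, control, alternative="two-sided",
                                        method="exact").pvalue
            assert mw_hl(real, control).p == pytest.approx(expected, abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        real = rng.normal(0.3, 1, size=30)
        control = rng.normal(0, 1, size=30)
        expected = sps.mannwhitneyu(real, control, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert mw_hl(real, control).p == pytest.approx(expected, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mw_hl([], [1.0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], [True, True, False, False]) == 1.0

    def test_all_tied_values_are_chance(self):
        assert roc_auc([2.0] * 6, [True, False] * 3) == pytest.approx(0.5)

    def test_interleaved_example(self):
        assert roc_auc([1, 3, 2, 4], [True, True, False, False]) == pytest.approx(0.25)

    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=50),
        st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sweep_equals_rank_sum_formulation(self, values, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(values), max_size=len(values))
        )
        labels = np.asarray(labels)
        if labels.all() or not labels.any():
            return
        values = np.asarray(values, float)
        ranks = sps.rankdata(values)
        n_pos = labels.sum()
        n_neg = len(labels) - n_pos
        expected = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        assert roc_auc(values, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_auc([1.0, 2.0], [True, True])


class TestOnewayF:
    def test_identical_groups_give_zero_f(self):
        f, p = oneway_f([[1, 2], [1, 2], [1, 2], [1, 2]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_no_within_variance_gives_extreme_f(self):
        f, p = oneway_f([[0.0, 0.0], [10.0, 10.0]])
        assert f > 1e10 or np.isinf(f)
        assert p < 1e-10

    def test_hand_computed_f(self):
        f, p = oneway_f([[1, 2, 3], [2, 3, 4]])
        assert f == pytest.approx(1.5)
        assert p == pytest.approx(float(sps.f.sf(1.5, 1, 4)))

    def test_degenerate_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            oneway_f([[1.0], [2.0, 3.0]])
        with pytest.raises(ZeroVarianceError):
            oneway_f([[2.0, 2.0], [2.0, 2.0]])


class TestPermutationCluster:
    def test_null_data_without_exceedance_has_no_clusters(self, rng):
        x = rng.normal(size=(12, 10))
        res = permutation_cluster(x, x.copy(), n_perm=100, seed=0)
        assert np.allclose(res.stat[np.isfinite(res.stat)], 0.0)
        assert res.clusters == ()

    def test_injected_effect_detected_in_injected_bins(self, rng):
        real = rng.normal(size=(20, 15))
        control = rng.normal(size=(20, 15))
        real[:, 5:10] += 1.5
        res = permutation_cluster(real, control, n_perm=300, seed=1)
        sig = res.significant(0.05)
        assert sig
        covered = set()
        for c in sig:
            covered |= set(range(c.start, c.stop))
        assert covered & set(range(5, 10))
        assert all(c.sign == 1 for c in sig)

    def test_seed_reproducibility(self, rng):
        real = rng.normal(size=(10, 8))
        control = rng.normal(size=(10, 8))
        a = permutation_cluster(real, control, n_perm=200, seed=9)
        b = permutation_cluster(real, control, n_perm=200, seed=9)
        assert np.array_equal(a.null_max, b.null_max)
        assert a.clusters == b.clusters

    def test_cluster_p_values_lie_in_unit_interval(self, rng):
        real = rng.normal(size=(15, 12)) + 0.8
        control = rng.normal(size=(15, 12))
        res = permutation_cluster(real, control, n_perm=100, seed=3)
        for c in res.clusters:
            assert 0.0 < c.p <= 1.0

    def test_clear_decisions_stable_across_n_perm(self, rng):
        real = rng.normal(size=(20, 10))
        control = rng.normal(size=(20, 10))
        real[:, 3:7] += 2.0  # decisively significant
        decisions = []
        for n_perm in (200, 2000):
            res = permutation_cluster(real, control, n_perm=n_perm, seed=5)
            decisions.append(tuple((c.start, c.stop, c.p <= 0.05) for c in res.clusters))
        assert decisions[0] == decisions[1]

    def test_too_few_participants_rejected(self, rng):
        x = rng.normal(size=(5, 10))
        with pytest.raises(InsufficientDataError):
            permutation_cluster(x, x, n_perm=10, seed=0)

    def test_signflip_requires_zero_control(self, rng):
        real = rng.normal(size=(10, 5))
        with pytest.raises(ParameterError):
            permutation_cluster(real, real, mode="signflip", n_perm=10, seed=0)

    def test_signflip_detects_systematic_offset(self, rng):
        real = rng.normal(0.8, 1.0, size=(20, 9))
        zeros = np.zeros_like(real)
        res = permutation_cluster(real, zeros, n_perm=200, seed=2, mode="signflip")
        assert res.any_significant(0.05)

    def test_swap_and_observed_statistics_agree(self, rng):
        """The vectorised permutation path reuses the observed-rank machinery."""
        real = rng.normal(size=(12, 6)) + 0.5
        control = rng.normal(size=(12, 6))
        res = permutation_cluster(real, control, n_perm=50, seed=4)
        from vocaldyad.stats import _mw_z

        for b in range(6):
            assert res.stat[b] == pytest.approx(_mw_z(real[:, b], control[:, b]))
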