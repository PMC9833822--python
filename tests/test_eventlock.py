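"""Event-relative analyses: likelihood profiles, trajectories, peaks, quartiles."""

import numpy as np
import pytest

from vocaldyad.core import (
    BinGrid,
    InsufficientDataError,
    ParameterError,
)
from vocaldyad.eventlock import (
    detect_peaks,
    event_locked_arousal,
    likelihood_profile,
    partner_quartile_profiles,
    quartile_split,
)
from vocaldyad.stats import permutation_cluster_anova

from conftest import make_events, make_series

BINS = BinGrid(edges=(-3, -1, 1, 3))
FOLLOW = 2  # index of the [1,3) bin


class TestBinGrid:
    def test_default_grid_covers_both_directions_with_1_3_bin(self):
        g = BinGrid.default()
        assert (1.0, 3.0) in g.bins
        assert g.edges[0] == -g.edges[-1]
        assert np.allclose(np.diff(g.edges), 2.0)

    def test_asymmetric_edges_rejected(self):
        with pytest.raises(ParameterError):
            BinGrid(edges=(-3, -1, 1, 5))


class TestLikelihoodProfile:
    @pytest.mark.parametrize(
        "ref,target,expected",
        [
            ([10], [12], 1.0),          # event 2 min later falls in [1,3)
            ([10], [14], 0.0),          # 4 min later misses [1,3)
            ([10, 20], [11, 23], 0.5),  # indicators (1, 0)
        ],
    )
    def test_follow_bin_enumerated_examples(self, ref, target, expected):
        prof = likelihood_profile(make_events(40, ref), make_events(40, target), BINS)
        assert prof.likelihood[FOLLOW] == pytest.approx(expected)

    def test_empty_reference_rejected(self):
        with pytest.raises(InsufficientDataError):
            likelihood_profile(make_events(40, []), make_events(40, [3]), BINS)

    def test_unobservable_bin_excluded_per_event(self):
        # event at epoch 0: the [-3,-1) bin lies wholly before the session
        prof = likelihood_profile(make_events(40, [0]), make_events(40, [2]), BINS)
        assert np.isnan(prof.likelihood[0])
        assert prof.n_events[0] == 0
        assert prof.likelihood[FOLLOW] == 1.0

    def test_masked_region_does_not_count_targets(self):
        mask = np.ones(40, dtype=bool)
        mask[11:13] = False  # the whole [1,3) window of event 10 is unobservable
        prof = likelihood_profile(make_events(40, [10]), make_events(40, [12]), BINS, mask)
        assert prof.n_events[FOLLOW] == 0

    def test_self_contrast_excludes_the_reference_event_itself(self):
        ev = make_events(40, [10])
        with_self = likelihood_profile(ev, ev, BINS)
        without = likelihood_profile(ev, ev, BINS, exclude_ref_epoch=True)
        centre = 1  # [-1,1) bin contains lag 0
        assert with_self.likelihood[centre] == 1.0
        assert without.likelihood[centre] == 0.0


class TestEventLockedArousal:
    LAGS = np.arange(-2, 3)

    def test_zero_series_gives_zero_trajectory(self):
        s = make_series(np.zeros(50))
        traj = event_locked_arousal(s, make_events(50, [10, 20]), self.LAGS)
        assert np.allclose(traj.mean, 0.0)

    def test_single_event_reads_off_the_series(self):
        vals = np.zeros(50)
        vals[25] = 1.0
        traj = event_locked_arousal(make_series(vals), make_events(50, [25]), self.LAGS)
        assert np.allclose(traj.mean, [0, 0, 1, 0, 0])

    def test_lag_zero_mean_over_two_events(self):
        vals = np.zeros(50)
        vals[10], vals[30] = 0.2, 0.6
        traj = event_locked_arousal(make_series(vals), make_events(50, [10, 30]), self.LAGS)
        assert traj.mean[2] == pytest.approx(0.4)

    def test_edge_events_contribute_only_observable_lags(self):
        s = make_series(np.ones(50))
        traj = event_locked_arousal(s, make_events(50, [0]), self.LAGS)
        assert np.isnan(traj.mean[0]) and np.isnan(traj.mean[1])
        assert traj.counts[0] == 0
        assert traj.mean[2] == 1.0

    def test_no_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            event_locked_arousal(make_series(np.zeros(50)), make_events(50, []), self.LAGS)


class TestDetectPeaks:
    def test_top_decile_of_distinct_values(self):
        s = make_series(np.arange(1.0, 101.0))
        peaks = detect_peaks(s, pct=10)
        assert list(peaks.epochs()) == list(range(90, 100))  # values 91..100

    def test_constant_series_has_no_peaks(self):
        peaks = detect_peaks(make_series(np.full(30, 2.0)), pct=10)
        assert len(peaks) == 0

    def test_values_tied_at_threshold_excluded_by_strict_rule(self):
        s = make_series(np.arange(0.0, 101.0))  # 90th percentile is exactly 90
        peaks = detect_peaks(s, pct=10)
        flagged = set(peaks.epochs())
        assert 90 not in flagged
        assert flagged == set(range(91, 101))

    @pytest.mark.parametrize("pct", [5, 10, 20])
    def test_peak_count_consistent_with_percentile(self, pct, rng):
        vals = rng.permutation(np.linspace(-3, 3, 173))
        n_peaks = len(detect_peaks(make_series(vals), pct=pct))
        target = 173 * pct / 100
        assert n_peaks in (int(np.floor(target)), int(np.ceil(target)))

    def test_invalid_pct_rejected(self):
        with pytest.raises(ParameterError):
            detect_peaks(make_series(np.arange(30.0)), pct=60)

    def test_too_few_valid_epochs_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_peaks(make_series(np.arange(10.0)), pct=10)


class TestQuartiles:
    def test_eight_events_split_into_consecutive_pairs(self):
        groups = quartile_split(np.arange(1.0, 9.0), np.arange(8))
        assert list(groups) == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_ties_broken_stably_by_epoch(self):
        groups = quartile_split(np.zeros(8), np.arange(8))
        assert list(groups) == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_identical_group_trajectories_give_zero_f(self, rng):
        # constant partner arousal per participant: group means identical
        partner, events, own = [], [], []
        for i in range(10):
            c = float(rng.normal())
            partner.append(make_series(np.full(200, c), dyad_id=f"d{i}"))
            own.append(make_series(rng.normal(size=200), dyad_id=f"d{i}"))
            events.append(make_events(200, rng.choice(np.arange(50, 150), 12, replace=False)))
        qp = partner_quartile_profiles(partner, events, own, np.arange(-3, 4))
        assert np.allclose(qp.f[np.isfinite(qp.f)], 0.0, atol=1e-10)

    def test_participants_with_few_events_excluded_with_warning(self, rng):
        partner = [make_series(rng.normal(size=100), dyad_id=f"d{i}") for i in range(2)]
        own = [make_series(rng.normal(size=100), dyad_id=f"d{i}") for i in range(2)]
        events = [make_events(100, [10, 20, 30]),  # too few
                  make_events(100, list(range(20, 60, 4)))]
        with pytest.warns(UserWarning, match="excluded"):
            qp = partner_quartile_profiles(partner, events, own, np.arange(-2, 3))
        assert qp.group_means.shape[0] == 1

    def test_injected_top_quartile_offset_detected_by_cluster_anova(self, rng):
        """An offset confined to one group over contiguous bins forms a cluster."""
        detected = 0
        n_sim = 10
        for s in range(n_sim):
            g = np.random.default_rng(s).normal(0, 0.2, size=(20, 4, 21))
            g[:, 3, 11:15] += 0.5  # top quartile, bins 2-6 min after
            res = permutation_cluster_anova(g, n_perm=200, seed=s)
            detected += any(
                c.p <= 0.05 and set(range(c.start, c.stop)) & set(range(11, 15))
                for c in res.clusters
            )
        assert detected >= 8
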