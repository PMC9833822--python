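"""Simulator: determinism, stationarity checks, null calibration, sparse sampling."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from vocaldyad.core import INFANT, ParameterError
from vocaldyad.eventlock import event_locked_arousal
from vocaldyad.events import filter_events
from vocaldyad.stats import roc_auc_arousal
from vocaldyad.synthetic import (
    SimParams,
    duty_cycle_fraction,
    duty_cycle_percent,
    get_preset,
    preset_names,
    simulate_cohort,
    simulate_dyad,
    sparse_sample_events,
)

SPEECH = ("infant", "speech_like")


def test_fixed_seed_reproduces_dyad_bitwise():
    params = get_preset("paper_like", seed=7)
    d1 = simulate_dyad(params)
    d2 = simulate_dyad(params)
    assert np.array_equal(d1.infant.values, d2.infant.values, equal_nan=True)
    assert np.array_equal(d1.caregiver.values, d2.caregiver.values, equal_nan=True)
    assert d1.events.events == d2.events.events
    assert np.array_equal(d1.infant.valid, d2.infant.valid)


def test_output_is_zscored_and_events_on_valid_epochs():
    d = simulate_dyad(get_preset("paper_like", seed=3))
    for s in (d.infant, d.caregiver):
        v = s.valid_values
        assert abs(v.mean()) < 1e-9
        assert abs(v.std(ddof=1) - 1.0) < 1e-9
        assert np.all(np.isnan(s.values[~s.valid]))
    for e in d.events.events:
        assert d.infant.valid[e.epoch]


def test_nonstationary_parameters_rejected():
    bad = SimParams(phi_infant=0.8, phi_caregiver=0.8, kappa_i2c=0.5, kappa_c2i=0.5)
    with pytest.raises(ParameterError, match="spectral radius"):
        simulate_dyad(bad)
    with pytest.raises(ParameterError):
        SimParams(phi_infant=1.2).validate()
    with pytest.raises(ParameterError):
        SimParams(n_epochs=10).validate()
    with pytest.raises(ParameterError):
        SimParams(snapshot_s=90.0).validate()


def test_independence_null_gives_chance_auc():
    """No arousal-event dependence => per-dyad AUC centred on 0.5."""
    params = SimParams(n_epochs=240, beta0={SPEECH: -2.2}, seed=None)
    aucs = [
        roc_auc_arousal(d.infant, d.events, speaker=INFANT)
        for d in simulate_cohort(params, 50, seed=99)
    ]
    assert abs(np.mean(aucs) - 0.5) < 0.04


def test_self_arousal_dependence_elevates_event_locked_arousal():
    """beta_self > 0 => infant arousal at lag 0 exceeds far-lag arousal."""
    params = SimParams(
        n_epochs=240,
        beta0={SPEECH: -2.2},
        beta_self={SPEECH: 1.5},
    )
    lag0, far = [], []
    for d in simulate_cohort(params, 100, seed=5):
        ev = filter_events(d.events, INFANT, "speech_like")
        if len(ev) == 0:
            continue
        traj = event_locked_arousal(d.infant, ev, np.array([-20, 0, 20]))
        lag0.append(traj.mean[1])
        far.extend(traj.mean[[0, 2]])
    far = np.asarray(far)
    p = mannwhitneyu(lag0, far[np.isfinite(far)], alternative="greater").pvalue
    assert p < 0.01
    assert np.mean(lag0) > 0


def test_cross_coupling_induces_partner_correlation():
    coupled = SimParams(n_epochs=240, phi_infant=0.6, phi_caregiver=0.3,
                        kappa_i2c=0.6, beta0={SPEECH: -2.5}, seed=11)
    d = simulate_dyad(coupled)
    ok = d.valid
    r = np.corrcoef(d.infant.values[ok], d.caregiver.values[ok])[0, 1]
    assert r > 0.2


def test_validity_mask_is_blocky_and_near_target_fraction():
    params = SimParams(n_epochs=2000, mask_valid_frac=0.5, beta0={SPEECH: -2.5}, seed=21)
    d = simulate_dyad(params)
    frac = d.infant.valid.mean()
    assert 0.3 < frac < 0.7
    # contiguous blocks: far fewer state switches than i.i.d. masking would give
    switches = np.sum(d.infant.valid[1:] != d.infant.valid[:-1])
    assert switches < 400  # i.i.d. would give ~1000


class TestSparseSampling:
    def test_full_minute_vocalisation_always_detected(self):
        ev = sparse_sample_events([(60.0, 120.0, INFANT, "cry")], 5.0, 60.0)
        assert list(ev.epochs()) == [1]

    def test_interval_outside_snapshot_missed(self):
        ev = sparse_sample_events([(10.0, 20.0, INFANT, "cry")], 5.0, 60.0)
        assert len(ev) == 0

    def test_label_from_earliest_starting_interval(self):
        ev = sparse_sample_events(
            [(2.0, 4.0, INFANT, "speech_like"), (1.0, 3.0, INFANT, "cry")], 5.0, 60.0
        )
        assert len(ev) == 1
        assert ev.events[0].category == "cry"

    def test_snapshot_longer_than_period_rejected(self):
        with pytest.raises(ParameterError):
            sparse_sample_events([(0.0, 1.0, INFANT, "cry")], 90.0, 60.0)

    def test_poisson_detection_rate_matches_closed_form(self, rng):
        lam = 0.02  # events per second
        n_epochs = 10_000
        horizon = n_epochs * 60.0
        n_arrivals = rng.poisson(lam * horizon)
        times = np.sort(rng.uniform(0, horizon - 1.0, size=n_arrivals))
        intervals = [(t, t + 1e-3, INFANT, "cry") for t in times]
        from vocaldyad.core import EpochGrid

        ev = sparse_sample_events(intervals, 5.0, 60.0, grid=EpochGrid(n_epochs))
        detected_fraction = len(ev) / n_epochs
        expected = 1.0 - np.exp(-lam * 5.0)
        assert abs(detected_fraction - expected) < 0.01


def test_duty_cycle_percentage():
    assert duty_cycle_fraction(5.0, 60.0) == pytest.approx(1 / 12)
    assert duty_cycle_percent(5.0, 60.0) == 8


def test_presets_load_and_validate():
    names = preset_names()
    assert {"null", "paper_like", "cry_vs_speech"} <= set(names)
    for name in names:
        get_preset(name).validate()
    with pytest.raises(ParameterError):
        get_preset("no_such_scenario")
    # null preset carries no dependence structure
    null = get_preset("null")
    assert not null.beta_self and not null.beta_partner
    assert null.kappa_i2c == null.kappa_c2i == 0.0
    assert null.gamma_cluster == 0.0
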