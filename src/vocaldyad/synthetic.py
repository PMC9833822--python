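"""Forward simulator for dyadic arousal and vocal events.

The generator reproduces, in the simplest form, the three structures the
analyses are built to detect in day-long home recordings:

* autocorrelated arousal in both partners — a bivariate AR(1) with optional
  cross-coupling (each partner's lagged arousal feeding the other's);
* arousal-contingent vocalising — a per-epoch logistic event model whose
  log-odds depend on own and partner arousal (standardised to the process's
  stationary scale);
* temporal clustering of vocalisations — an additive self-excitation term
  active for ``k_excite`` epochs after a speaker's own event.

Cries and speech-like vocalisations can feed back onto infant arousal as
fixed-length additive boxcar inputs (cries downward, speech-like upward).
Validity masking uses contiguous blocks, mimicking nap/outdoor exclusions,
and a duty-cycled sparse-sampling operator emulates the 5 s-per-minute audio
snapshots, under which an event is detected only when it overlaps a
snapshot window.

With all dependence parameters at zero the generator is an exact
independence null: events are placed without regard to arousal, which every
downstream detector should then call unremarkable at its nominal rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy.linalg import solve_discrete_lyapunov
from scipy.special import expit

from .core import (
    CAREGIVER,
    CATEGORIES,
    CRY,
    INFANT,
    OTHER,
    ROLES,
    SPEECH_LIKE,
    ArousalSeries,
    Dyad,
    EpochGrid,
    EventSeries,
    ParameterError,
    VocalEvent,
    zscore_masked,
)

__all__ = [
    "SimParams",
    "simulate_dyad",
    "simulate_cohort",
    "sparse_sample_events",
    "events_to_intervals",
    "duty_cycle_fraction",
    "duty_cycle_percent",
    "get_preset",
    "preset_names",
]

#: epochs simulated before the session starts, to wash out initial conditions
_BURN_IN = 50

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}
_CAT_PRECEDENCE = (CRY, SPEECH_LIKE, OTHER)

Coef = dict[tuple[str, str], float]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the dyadic arousal + vocal-event forward model.

    Coefficient dictionaries are keyed by ``(speaker, category)``; a
    category without a ``beta0`` entry is never produced by that speaker.
    """

    n_epochs: int = 240
    phi_infant: float = 0.7
    phi_caregiver: float = 0.6
    kappa_i2c: float = 0.0
    kappa_c2i: float = 0.0
    noise_sd: float = 1.0
    beta0: Coef = field(default_factory=dict)
    beta_self: Coef = field(default_factory=dict)
    beta_partner: Coef = field(default_factory=dict)
    gamma_cluster: float = 0.0
    k_excite: int = 3
    post_cry_drop: float = 0.0
    post_speech_sustain: float = 0.0
    impulse_epochs: int = 5
    mask_valid_frac: float = 1.0
    snapshot_s: float = 5.0
    period_s: float = 60.0
    seed: int | None = None

    def lag_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.phi_infant, self.kappa_c2i],
                [self.kappa_i2c, self.phi_caregiver],
            ]
        )

    def validate(self) -> None:
        if self.n_epochs < 40:
            raise ParameterError("n_epochs must be >= 40")
        for name in ("phi_infant", "phi_caregiver"):
            phi = getattr(self, name)
            if not (0.0 <= phi < 1.0):
                raise ParameterError(f"{name} must lie in [0, 1), got {phi}")
        radius = float(np.max(np.abs(np.linalg.eigvals(self.lag_matrix()))))
        if radius >= 1.0:
            raise ParameterError(
                f"non-stationary arousal dynamics: spectral radius {radius:.3f} >= 1"
            )
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.k_excite < 1:
            raise ParameterError("k_excite must be >= 1")
        if self.impulse_epochs < 0:
            raise ParameterError("impulse_epochs must be >= 0")
        if not (0.0 < self.mask_valid_frac <= 1.0):
            raise ParameterError("mask_valid_frac must lie in (0, 1]")
        if self.snapshot_s > self.period_s:
            raise ParameterError("snapshot_s must not exceed period_s")
        for coef in (self.beta0, self.beta_self, self.beta_partner):
            for speaker, category in coef:
                if speaker not in ROLES or category not in CATEGORIES:
                    raise ParameterError(
                        f"unknown coefficient key ({speaker!r}, {category!r})"
                    )


def _block_mask(n: int, frac: float, rng: np.random.Generator,
                mean_valid_block: float = 30.0) -> np.ndarray:
    """Validity mask of random contiguous valid/invalid blocks."""
    if frac >= 1.0:
        return np.ones(n, dtype=bool)
    mean_invalid_block = mean_valid_block * (1.0 - frac) / frac
    mask = np.zeros(n, dtype=bool)
    pos = 0
    state = rng.random() < frac
    while pos < n:
        mean = mean_valid_block if state else mean_invalid_block
        length = int(rng.geometric(min(1.0, 1.0 / mean)))
        mask[pos : pos + length] = state
        pos += length
        state = not state
    if not mask.any():  # degenerate draw on short sessions
        start = int(rng.integers(0, max(1, n - 10)))
        mask[start : start + 10] = True
    return mask


def _stationary_sd(params: SimParams) -> np.ndarray:
    a = params.lag_matrix()
    q = np.eye(2) * params.noise_sd**2
    sigma = solve_discrete_lyapunov(a, q)
    return np.sqrt(np.diag(sigma))


def simulate_dyad(params: SimParams, dyad_id: str = "sim") -> Dyad:
    """Simulate one dyad: masked z-scored arousal plus vocal events.

    Identical ``params`` (including ``seed``) reproduce the output
    bit-for-bit.  Events occur only on valid epochs; arousal is z-scored
    over valid epochs and undefined elsewhere.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    mask_rng, arousal_rng, event_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    n = params.n_epochs
    total = _BURN_IN + n
    valid = _block_mask(n, params.mask_valid_frac, mask_rng)
    eps = arousal_rng.normal(0.0, params.noise_sd, size=(2, total))
    u = event_rng.random(size=(n, len(ROLES), len(CATEGORIES)))
    sd = _stationary_sd(params)

    a = np.zeros((2, total))
    impulse = np.zeros(total + params.impulse_epochs + 1)
    lag = params.lag_matrix()
    last_event: dict[str, int] = {}
    events: list[VocalEvent] = []

    a[:, 0] = eps[:, 0]
    for t in range(total):
        if t > 0:
            a[:, t] = lag @ a[:, t - 1] + eps[:, t]
            a[0, t] += impulse[t]
        e = t - _BURN_IN
        if e < 0 or not valid[e]:
            continue
        z = a[:, t] / sd
        for s_idx, speaker in enumerate(ROLES):
            z_own = z[s_idx]
            z_partner = z[1 - s_idx]
            prev = last_event.get(speaker)
            excited = prev is not None and 0 < e - prev <= params.k_excite
            fired: list[str] = []
            for category in CATEGORIES:
                key = (speaker, category)
                if key not in params.beta0:
                    continue
                logit = (
                    params.beta0[key]
                    + params.beta_self.get(key, 0.0) * z_own
                    + params.beta_partner.get(key, 0.0) * z_partner
                    + (params.gamma_cluster if excited else 0.0)
                )
                if u[e, s_idx, _CAT_INDEX[category]] < expit(logit):
                    fired.append(category)
            if not fired:
                continue
            category = min(fired, key=_CAT_PRECEDENCE.index)
            events.append(VocalEvent(epoch=e, speaker=speaker, category=category))
            last_event[speaker] = e
            if speaker == INFANT and params.impulse_epochs > 0:
                amp = {CRY: params.post_cry_drop, SPEECH_LIKE: params.post_speech_sustain}.get(
                    category, 0.0
                )
                if amp != 0.0:
                    impulse[t + 1 : t + 1 + params.impulse_epochs] += amp

    grid = EpochGrid(n_epochs=n, epoch_s=params.period_s)
    series = {}
    for s_idx, role in enumerate(ROLES):
        series[role] = ArousalSeries(
            dyad_id=dyad_id,
            role=role,
            grid=grid,
            values=zscore_masked(a[s_idx, _BURN_IN:], valid),
            valid=valid,
        )
    return Dyad(
        dyad_id=dyad_id,
        infant=series[INFANT],
        caregiver=series[CAREGIVER],
        events=EventSeries(grid, tuple(events)),
    )


def simulate_cohort(params: SimParams, n_dyads: int, seed: int | None = None) -> list[Dyad]:
    """Simulate ``n_dyads`` independent dyads with seeds derived from one seed."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_dyads) % (2**31 - 1)
    return [
        simulate_dyad(replace(params, seed=int(s)), dyad_id=f"sim{i:03d}")
        for i, s in enumerate(child_seeds)
    ]


# ---------------------------------------------------------------------------
# Duty-cycled (sparse) audio sampling
# ---------------------------------------------------------------------------

def duty_cycle_fraction(snapshot_s: float = 5.0, period_s: float = 60.0) -> float:
    """Fraction of each minute covered by the audio snapshot."""
    if snapshot_s > period_s:
        raise ParameterError("snapshot_s must not exceed period_s")
    if snapshot_s <= 0 or period_s <= 0:
        raise ParameterError("snapshot_s and period_s must be > 0")
    return snapshot_s / period_s


def duty_cycle_percent(snapshot_s: float = 5.0, period_s: float = 60.0) -> int:
    """Snapshot coverage as an integer percentage (5 s of 60 s -> 8)."""
    return int(round(100.0 * duty_cycle_fraction(snapshot_s, period_s)))


def sparse_sample_events(
    true_intervals,
    snapshot_s: float = 5.0,
    period_s: float = 60.0,
    grid: EpochGrid | None = None,
) -> EventSeries:
    """Detect vocal on-intervals through duty-cycled audio snapshots.

    ``true_intervals`` is a sequence of ``(start_s, end_s, speaker,
    category)`` tuples.  An event is emitted for epoch ``e`` iff an interval
    overlaps the snapshot window ``[e*period_s, e*period_s + snapshot_s)``;
    when several intervals from one speaker overlap the same snapshot, the
    earliest-starting interval provides the label.
    """
    duty_cycle_fraction(snapshot_s, period_s)  # validates the pair
    intervals = [(float(s0), float(s1), spk, cat) for s0, s1, spk, cat in true_intervals]
    for s0, s1, _, _ in intervals:
        if s0 < 0 or s1 < s0:
            raise ParameterError(f"bad interval [{s0}, {s1})")
    if grid is None:
        horizon = max((s1 for _, s1, _, _ in intervals), default=period_s)
        grid = EpochGrid(n_epochs=max(1, int(np.ceil(horizon / period_s))),
                         epoch_s=period_s)
    best: dict[tuple[int, str], tuple[float, str]] = {}
    for s0, s1, speaker, category in intervals:
        if s1 > grid.n_epochs * period_s:
            raise ParameterError(
                f"interval [{s0}, {s1}) extends past the session "
                f"({grid.n_epochs * period_s:g} s)"
            )
        e_lo = max(0, int(np.floor((s0 - snapshot_s) / period_s)))
        e_hi = min(grid.n_epochs - 1, int(np.floor(s1 / period_s)))
        for e in range(e_lo, e_hi + 1):
            w0 = e * period_s
            if s0 < w0 + snapshot_s and s1 > w0:
                key = (e, speaker)
                if key not in best or s0 < best[key][0]:
                    best[key] = (s0, category)
    events = tuple(
        VocalEvent(epoch=e, speaker=speaker, category=cat)
        for (e, speaker), (_, cat) in sorted(best.items())
    )
    return EventSeries(grid, events)


def events_to_intervals(
    events: EventSeries,
    rng: np.random.Generator,
    min_dur_s: float = 5.0,
    max_dur_s: float = 40.0,
) -> list[tuple[float, float, str, str]]:
    """Dress epoch-level events as continuous vocal bouts.

    Each event becomes one on-interval whose onset is uniform within its
    epoch and whose duration is uniform in ``[min_dur_s, max_dur_s]``;
    bouts may spill into following epochs (clipped at the session end), as
    real crying or babbling bouts do.  This is the ground truth a
    duty-cycled microphone subsamples; full-coverage detection of the same
    intervals is ``sparse_sample_events(..., snapshot_s=period_s)``.
    """
    period = events.grid.epoch_s
    session_end = events.grid.n_epochs * period
    if max_dur_s >= session_end:
        raise ParameterError("max_dur_s must be shorter than the session")
    out = []
    for ev in events.events:
        dur = float(rng.uniform(min_dur_s, max_dur_s))
        start = ev.epoch * period + float(rng.uniform(0.0, period))
        end = min(start + dur, session_end)
        if end > start:
            out.append((start, end, ev.speaker, ev.category))
    return out


# ---------------------------------------------------------------------------
# Named parameter scenarios
# ---------------------------------------------------------------------------

def _load_presets() -> dict:
    text = resources.files(__package__).joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_names() -> list[str]:
    return sorted(_load_presets())


def get_preset(name: str, **overrides) -> SimParams:
    """Named parameter scenario ("null", "paper_like", "cry_vs_speech")."""
    presets = _load_presets()
    if name not in presets:
        raise ParameterError(f"unknown preset {name!r}; known: {sorted(presets)}")
    raw = dict(presets[name])
    for coef in ("beta0", "beta_self", "beta_partner"):
        if coef in raw:
            raw[coef] = {
                (spk, cat): float(v)
                for key, v in raw[coef].items()
                for spk, cat in [key.split("/")]
            }
    raw.update(overrides)
    params = SimParams(**raw)
    params.validate()
    return params
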