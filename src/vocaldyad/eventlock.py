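"""Event-relative analyses on the epoch grid.

Everything here is computed per participant relative to a set of reference
events: the likelihood of (other) vocalisations in relative-time bins, mean
arousal trajectories at 1 min lags, arousal-peak detection, and
partner-arousal trajectories split by the vocaliser's arousal quartile.
Events near the session edges contribute only their observable lags; lags
or bins with no contributing observation are undefined (NaN), never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    PEAK,
    ArousalSeries,
    BinGrid,
    EventSeries,
    InsufficientDataError,
    ParameterError,
    VocaldyadError,
    VocalEvent,
)
from .stats import _anova_f_bins

__all__ = [
    "BinProfile",
    "Trajectory",
    "QuartileProfiles",
    "likelihood_profile",
    "event_locked_arousal",
    "detect_peaks",
    "quartile_split",
    "partner_quartile_profiles",
    "default_lags",
]


def default_lags(max_lag_min: int = 20) -> np.ndarray:
    """Relative lags in 1 min steps, -max..+max."""
    return np.arange(-max_lag_min, max_lag_min + 1)


@dataclass(frozen=True)
class BinProfile:
    """One participant's per-bin event likelihood (NaN where unobservable)."""

    bins: BinGrid
    likelihood: np.ndarray  # (n_bins,)
    n_events: np.ndarray    # contributing reference events per bin


@dataclass(frozen=True)
class Trajectory:
    """One participant's event-locked mean signal at 1 min lags."""

    lags: np.ndarray
    mean: np.ndarray    # (n_lags,), NaN where no observation
    counts: np.ndarray  # contributing events per lag


def likelihood_profile(
    ref: EventSeries,
    target: EventSeries,
    bins: BinGrid,
    mask=None,
    exclude_ref_epoch: bool = False,
) -> BinProfile:
    """Likelihood of >= 1 target event in each relative-time bin.

    For a reference event at epoch t and a bin [a, b) minutes, the
    indicator is whether any target event falls in epochs [t+a, t+b).  A
    bin counts for an event only when at least one of its epochs is
    observable (inside the session and inside ``mask``); the participant's
    likelihood is the mean indicator over contributing events.  With
    ``exclude_ref_epoch`` the reference epoch itself is ignored as a
    target, which is what a self-contrast ("another vocalisation") needs.
    """
    if len(ref) == 0:
        raise InsufficientDataError("reference event series is empty")
    n = ref.grid.n_epochs
    if target.grid.n_epochs != n:
        raise VocaldyadError("ref and target must share a grid")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise VocaldyadError("mask length does not match grid")

    occ = target.occupancy() & mask
    tcum = np.concatenate([[0], np.cumsum(occ)])
    ocum = np.concatenate([[0], np.cumsum(mask)])
    ref_epochs = ref.epochs()

    n_bins = bins.n_bins
    likelihood = np.full(n_bins, np.nan)
    n_events = np.zeros(n_bins, dtype=int)
    for bi, (a, b) in enumerate(bins.bins):
        lo = np.clip(ref_epochs + int(np.ceil(a)), 0, n)
        hi = np.clip(ref_epochs + int(np.ceil(b)), 0, n)
        observable = (ocum[hi] - ocum[lo]) > 0
        counts = tcum[hi] - tcum[lo]
        if exclude_ref_epoch:
            inside = (lo <= ref_epochs) & (ref_epochs < hi)
            counts = counts - (inside & occ[ref_epochs]).astype(int)
        usable = observable
        n_events[bi] = int(usable.sum())
        if n_events[bi] > 0:
            likelihood[bi] = float((counts[usable] > 0).mean())
    return BinProfile(bins=bins, likelihood=likelihood, n_events=n_events)


def event_locked_arousal(
    series: ArousalSeries,
    events: EventSeries,
    lags: np.ndarray | None = None,
) -> Trajectory:
    """Mean arousal at each 1 min lag relative to the given events.

    Per lag, the mean of the series value at epoch t+lag over events t for
    which that epoch is inside the session and valid.  Lags with no
    contributing observation are NaN.
    """
    if lags is None:
        lags = default_lags()
    lags = np.asarray(lags, dtype=int)
    if len(events) == 0:
        raise InsufficientDataError("no events to lock to")
    if events.grid.n_epochs != series.grid.n_epochs:
        raise VocaldyadError("series and events must share a grid")
    epochs = events.epochs()
    n = series.grid.n_epochs
    idx = epochs[:, None] + lags[None, :]
    inside = (idx >= 0) & (idx < n)
    vals = np.where(inside, series.values[np.clip(idx, 0, n - 1)], np.nan)
    counts = np.isfinite(vals).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
    mean = np.where(counts > 0, mean, np.nan)
    return Trajectory(lags=lags, mean=mean, counts=counts)


def detect_peaks(series: ArousalSeries, pct: float = 10.0) -> EventSeries:
    """Flag epochs whose arousal exceeds the participant's top ``pct`` cut.

    The threshold is the (100 - pct)th percentile (linear interpolation) of
    that participant's valid values; exceedance is strict, so values tied
    exactly at the threshold are not peaks.  Returns pseudo-events with
    category ``"arousal_peak"``.
    """
    if not (0.0 < pct <= 50.0):
        raise ParameterError(f"pct must lie in (0, 50], got {pct}")
    if series.n_valid < 20:
        raise InsufficientDataError(
            f"{series.n_valid} valid epochs; >= 20 required for peak detection"
        )
    threshold = float(np.percentile(series.valid_values, 100.0 - pct))
    flag = series.valid & (np.nan_to_num(series.values, nan=-np.inf) > threshold)
    return EventSeries(
        series.grid,
        tuple(
            VocalEvent(epoch=int(e), speaker=series.role, category=PEAK)
            for e in np.flatnonzero(flag)
        ),
    )


def quartile_split(values: np.ndarray, epochs: np.ndarray) -> np.ndarray:
    """Assign events to 4 rank-based groups by value (stable on epoch ties).

    Returns group indices 0..3 (0 = lowest quartile) aligned with the
    input order.  Group sizes differ by at most one; ties are broken by
    rank with stable ordering on epoch index.
    """
    values = np.asarray(values, dtype=float)
    epochs = np.asarray(epochs, dtype=int)
    n = values.size
    order = np.lexsort((epochs, values))
    groups = np.empty(n, dtype=int)
    groups[order] = (np.arange(n) * 4) // n
    return groups


@dataclass(frozen=True)
class QuartileProfiles:
    """Partner trajectories split by vocaliser-arousal quartile, cohort level."""

    lags: np.ndarray
    group_means: np.ndarray      # (participants, 4, n_lags)
    participant_ids: tuple[str, ...]
    f: np.ndarray                # per-lag one-way F across quartile groups
    p: np.ndarray


def partner_quartile_profiles(
    partner_series_list,
    events_list,
    own_series_list,
    lags: np.ndarray | None = None,
    min_events: int = 8,
) -> QuartileProfiles:
    """Partner-arousal trajectories split by the vocaliser's arousal quartile.

    Events are grouped per participant into quartiles of the vocaliser-side
    arousal at the event epoch; each group's partner-arousal trajectory is
    averaged per participant, and a one-way ANOVA across the 4 groups on
    participant-level means is computed per lag.  Participants with fewer
    than ``min_events`` events with defined vocaliser arousal are excluded
    with a warning.  Cluster correction is applied downstream
    (:func:`vocaldyad.stats.permutation_cluster_anova`).
    """
    if lags is None:
        lags = default_lags()
    lags = np.asarray(lags, dtype=int)
    rows = []
    ids = []
    for partner, events, own in zip(partner_series_list, events_list, own_series_list):
        epochs = events.epochs()
        own_vals = own.values[epochs] if epochs.size else np.array([])
        usable = np.isfinite(own_vals)
        if usable.sum() < min_events:
            warnings.warn(
                f"participant {own.dyad_id}: {int(usable.sum())} usable events "
                f"(< {min_events}); excluded from quartile analysis",
                stacklevel=2,
            )
            continue
        epochs_u = epochs[usable]
        groups = quartile_split(own_vals[usable], epochs_u)
        gm = np.full((4, lags.size), np.nan)
        for g in range(4):
            sub = EventSeries(
                events.grid,
                tuple(
                    VocalEvent(epoch=int(e), speaker="infant", category="other")
                    for e in epochs_u[groups == g]
                ),
            )
            gm[g] = event_locked_arousal(partner, sub, lags).mean
        rows.append(gm)
        ids.append(own.dyad_id)
    if not rows:
        raise InsufficientDataError("no participant has enough usable events")
    group_means = np.stack(rows)  # (P, 4, L)
    row_ok = np.isfinite(group_means).all(axis=1)
    f, p = _anova_f_bins(group_means, row_ok)
    return QuartileProfiles(
        lags=lags,
        group_means=group_means,
        participant_ids=tuple(ids),
        f=f,
        p=p,
    )
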