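"""Vocal-event filtering and matched control ("non-vocalisation") resampling.

The control analysis places as many pseudo-events as there are real events
uniformly at random on eligible epochs — epochs where the dyad was at home
and awake and *neither* partner vocalised — and repeats the draw many times;
downstream statistics are averaged over the repetitions.  Control sets never
intersect the epochs of the reference events.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CATEGORIES,
    PEAK,
    Dyad,
    EventSeries,
    InsufficientDataError,
    VocaldyadError,
    VocalEvent,
)

__all__ = [
    "filter_events",
    "eligible_control_epochs",
    "sample_controls_masked",
    "sample_control_events",
]

_KNOWN_CATEGORIES = set(CATEGORIES) | {PEAK}


def filter_events(series: EventSeries, speaker: str | None, category: str = "all") -> EventSeries:
    """Subset an event series by speaker and category, preserving order.

    ``category="all"`` keeps every category (including "other").
    """
    if category != "all" and category not in _KNOWN_CATEGORIES:
        raise VocaldyadError(
            f"unknown category {category!r}; expected one of "
            f"{sorted(_KNOWN_CATEGORIES)} or 'all'"
        )
    kept = tuple(
        e
        for e in series.events
        if (speaker is None or e.speaker == speaker)
        and (category == "all" or e.category == category)
    )
    return EventSeries(series.grid, kept)


def eligible_control_epochs(valid: np.ndarray, all_events: EventSeries,
                            exclude_epochs=()) -> np.ndarray:
    """Valid epochs with no vocalisation by either partner (nor exclusions)."""
    ok = np.asarray(valid, dtype=bool).copy()
    ok[all_events.epochs()] = False
    excl = np.asarray(list(exclude_epochs), dtype=int)
    if excl.size:
        ok[excl] = False
    return np.flatnonzero(ok)


def sample_controls_masked(
    valid: np.ndarray,
    all_events: EventSeries,
    reference: EventSeries,
    n_reps: int,
    seed=None,
) -> list[EventSeries]:
    """Matched control sets against an explicit validity mask.

    Reference events may be vocalisations or other point events (arousal
    peaks); eligibility always excludes every vocalisation epoch in
    ``all_events`` plus the reference epochs themselves.
    """
    if len(reference) == 0:
        raise InsufficientDataError("reference event set is empty")
    ref_epochs = reference.epochs()
    eligible = eligible_control_epochs(valid, all_events, exclude_epochs=ref_epochs)
    n_events = len(reference)
    if eligible.size < n_events:
        raise InsufficientDataError(
            f"only {eligible.size} eligible control epochs for {n_events} events"
        )
    rng = np.random.default_rng(seed)
    labels = [(e.speaker, e.category) for e in reference.events]
    out = []
    for _ in range(n_reps):
        drawn = np.sort(rng.choice(eligible, size=n_events, replace=False))
        out.append(
            EventSeries(
                all_events.grid,
                tuple(
                    VocalEvent(epoch=int(ep), speaker=spk, category=cat)
                    for ep, (spk, cat) in zip(drawn, labels)
                ),
            )
        )
    return out


def sample_control_events(
    dyad: Dyad,
    reference: EventSeries,
    n_reps: int,
    seed=None,
) -> list[EventSeries]:
    """Draw ``n_reps`` matched control event sets for a reference event set.

    Each control set holds exactly as many pseudo-events as ``reference``,
    drawn uniformly without replacement from eligible epochs (valid for the
    dyad, no vocalisation by either partner, and not a reference epoch).
    Pseudo-events inherit the speaker/category labels of the reference
    events so that per-contrast statistics are computed identically on
    both.  Draws are reproducible under a fixed seed.
    """
    return sample_controls_masked(dyad.valid, dyad.events, reference, n_reps, seed)
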