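"""Shared containers for epoch-gridded dyadic arousal and vocal-event data.

Everything downstream works on a uniform grid of 60 s epochs.  Arousal is a
per-role, per-epoch composite in within-person z-units with an explicit
validity mask (NaN exactly where invalid); vocal events are point events on
the same grid, tagged with speaker role and category.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

INFANT = "infant"
CAREGIVER = "caregiver"
ROLES = (INFANT, CAREGIVER)

CRY = "cry"
SPEECH_LIKE = "speech_like"
OTHER = "other"
PEAK = "arousal_peak"
CATEGORIES = (CRY, SPEECH_LIKE, OTHER)

#: precedence when several categories are coded within one epoch/speaker
_CATEGORY_PRECEDENCE = {CRY: 0, SPEECH_LIKE: 1, OTHER: 2, PEAK: 3}


class VocaldyadError(ValueError):
    """Base class for validation errors raised by this package."""


class ParameterError(VocaldyadError):
    """Invalid or non-stationary parameter set."""


class SchemaError(VocaldyadError):
    """Malformed input table."""


class EmptyDataError(VocaldyadError):
    """No valid epochs remain."""


class InsufficientDataError(VocaldyadError):
    """Too few valid epochs/pairs/events for the requested computation."""


class ZeroVarianceError(VocaldyadError):
    """A channel or sample is constant where variability is required."""


def partner_of(role: str) -> str:
    if role == INFANT:
        return CAREGIVER
    if role == CAREGIVER:
        return INFANT
    raise VocaldyadError(f"unknown role: {role!r}")


def zscore_masked(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Z-score ``values`` over the epochs flagged in ``valid`` (sample SD).

    Returns an array with NaN at invalid epochs.  Raises
    :class:`EmptyDataError` when no epoch is valid and
    :class:`ZeroVarianceError` when the valid values are constant.
    """
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    v = values[valid]
    if v.size == 0:
        raise EmptyDataError("no valid epochs to z-score over")
    if v.size < 2 or np.ptp(v) == 0.0:
        raise ZeroVarianceError("constant (or singleton) series cannot be z-scored")
    out = np.full(values.shape, np.nan)
    out[valid] = (v - v.mean()) / v.std(ddof=1)
    return out


@dataclass(frozen=True)
class EpochGrid:
    """Uniform epoch grid: ``n_epochs`` epochs of ``epoch_s`` seconds."""

    n_epochs: int
    epoch_s: float = 60.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ParameterError("n_epochs must be >= 1")
        if self.epoch_s <= 0:
            raise ParameterError("epoch_s must be > 0")

    @property
    def epochs(self) -> np.ndarray:
        return np.arange(self.n_epochs)

    def times_s(self) -> np.ndarray:
        """Epoch start times in seconds from session start."""
        return self.t0 + self.epochs * self.epoch_s


@dataclass
class ArousalSeries:
    """Per-epoch composite arousal (z-units) for one participant."""

    dyad_id: str
    role: str
    grid: EpochGrid
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise VocaldyadError(f"unknown role: {self.role!r}")
        self.values = np.asarray(self.values, dtype=float).copy()
        self.valid = np.asarray(self.valid, dtype=bool).copy()
        if self.values.shape != (self.grid.n_epochs,):
            raise VocaldyadError("values length does not match grid")
        if self.valid.shape != (self.grid.n_epochs,):
            raise VocaldyadError("valid mask length does not match grid")
        # values are undefined exactly where invalid (and NaN ⇒ invalid)
        self.valid &= np.isfinite(self.values)
        self.values[~self.valid] = np.nan

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def zscored(self) -> "ArousalSeries":
        return replace(self, values=zscore_masked(self.values, self.valid))


@dataclass(frozen=True)
class VocalEvent:
    """One coded vocalisation (or pseudo-event) at a single epoch."""

    epoch: int
    speaker: str
    category: str
    affect: str | None = None
    intensity: str | None = None


@dataclass
class EventSeries:
    """Vocal events on an epoch grid; at most one per (epoch, speaker)."""

    grid: EpochGrid
    events: tuple[VocalEvent, ...]

    def __post_init__(self) -> None:
        evs = tuple(sorted(self.events, key=lambda e: (e.epoch, e.speaker)))
        seen: set[tuple[int, str]] = set()
        for e in evs:
            if not (0 <= e.epoch < self.grid.n_epochs):
                raise VocaldyadError(f"event epoch {e.epoch} outside grid")
            key = (e.epoch, e.speaker)
            if key in seen:
                raise VocaldyadError(
                    f"duplicate event for (epoch={e.epoch}, speaker={e.speaker}); "
                    "collapse first with EventSeries.from_events"
                )
            seen.add(key)
        self.events = evs

    @classmethod
    def from_events(
        cls, grid: EpochGrid, events: Iterable[VocalEvent], collapse: bool = True
    ) -> "EventSeries":
        """Build a series, optionally collapsing within-epoch duplicates.

        When several vocalisations by the same speaker are coded within one
        epoch (one 5 s snapshot), they are merged into a single event; the
        surviving category is chosen by precedence cry > speech_like > other.
        """
        if not collapse:
            return cls(grid, tuple(events))
        best: dict[tuple[int, str], VocalEvent] = {}
        for e in events:
            key = (e.epoch, e.speaker)
            old = best.get(key)
            if old is None or (
                _CATEGORY_PRECEDENCE.get(e.category, 99)
                < _CATEGORY_PRECEDENCE.get(old.category, 99)
            ):
                best[key] = e
        return cls(grid, tuple(best.values()))

    def __len__(self) -> int:
        return len(self.events)

    def epochs(self, speaker: str | None = None, category: str | None = None) -> np.ndarray:
        """Sorted epoch indices of events matching the given filters."""
        eps = [
            e.epoch
            for e in self.events
            if (speaker is None or e.speaker == speaker)
            and (category is None or category == "all" or e.category == category)
        ]
        return np.asarray(sorted(eps), dtype=int)

    def occupancy(self, speaker: str | None = None, category: str | None = None) -> np.ndarray:
        """Boolean per-epoch indicator of event presence."""
        occ = np.zeros(self.grid.n_epochs, dtype=bool)
        occ[self.epochs(speaker, category)] = True
        return occ


@dataclass
class Dyad:
    """Paired infant/caregiver arousal plus the dyad's vocal events."""

    dyad_id: str
    infant: ArousalSeries
    caregiver: ArousalSeries
    events: EventSeries

    def __post_init__(self) -> None:
        if not (self.infant.grid == self.caregiver.grid == self.events.grid):
            raise VocaldyadError("infant, caregiver and events must share one grid")

    @property
    def grid(self) -> EpochGrid:
        return self.infant.grid

    @property
    def valid(self) -> np.ndarray:
        """Home-and-awake epochs usable for dyad-level analyses."""
        return self.infant.valid & self.caregiver.valid

    def arousal(self, role: str) -> ArousalSeries:
        if role == INFANT:
            return self.infant
        if role == CAREGIVER:
            return self.caregiver
        raise VocaldyadError(f"unknown role: {role!r}")


@dataclass(frozen=True)
class BinGrid:
    """Contiguous half-open relative-time bins in minutes, symmetric about 0.

    The default covers the 20 min before and after an event in 2 min bins
    with edges at odd minutes (…, [-3,-1), [-1,1), [1,3), …), so that the
    "1-3 min following" window is a bin in its own right.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ParameterError("bin edges must be strictly increasing, >= 2 of them")
        if not np.allclose(e, -e[::-1]):
            raise ParameterError("bin edges must be symmetric about 0")
        object.__setattr__(self, "edges", tuple(float(x) for x in e))

    @classmethod
    def default(cls, half_width_min: float = 21.0, width_min: float = 2.0) -> "BinGrid":
        edges = np.arange(-half_width_min, half_width_min + width_min / 2, width_min)
        return cls(tuple(edges))

    @property
    def bins(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    def labels(self) -> list[str]:
        return [f"[{lo:g},{hi:g})" for lo, hi in self.bins]
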