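"""Composite-arousal construction and prewhitening.

The composite arousal index collapses heart rate, heart-rate variability and
movement into a single within-person z-scored series: each channel is
sign-oriented so that higher means more aroused (faster heart, *lower*
variability, more movement), z-scored over its own valid epochs, averaged
across whatever channels are available at each epoch, and the average is
re-z-scored.  A first-order autoregressive residualisation is provided to
remove the strong lag-1 autocorrelation of arousal before event-locked
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ArousalSeries,
    EpochGrid,
    EmptyDataError,
    InsufficientDataError,
    VocaldyadError,
    ZeroVarianceError,
    zscore_masked,
)

__all__ = ["ChannelSet", "DEFAULT_ORIENTATION", "composite_arousal",
           "remove_autocorrelation", "apply_mask", "valid_lag_pairs"]

#: sign per channel mapping raw units onto "higher = more aroused"
DEFAULT_ORIENTATION = {"heart_rate": +1.0, "hrv": -1.0, "movement": +1.0}


@dataclass
class ChannelSet:
    """Raw per-epoch autonomic channels for one participant."""

    dyad_id: str
    role: str
    grid: EpochGrid
    channels: dict[str, np.ndarray]
    valid: np.ndarray
    orientation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise VocaldyadError("ChannelSet needs at least one channel")
        self.valid = np.asarray(self.valid, dtype=bool).copy()
        if self.valid.shape != (self.grid.n_epochs,):
            raise VocaldyadError("valid mask length does not match grid")
        self.channels = {
            name: np.asarray(vals, dtype=float).copy()
            for name, vals in self.channels.items()
        }
        for name, vals in self.channels.items():
            if vals.shape != (self.grid.n_epochs,):
                raise VocaldyadError(f"channel {name!r} length does not match grid")
        orient = dict(DEFAULT_ORIENTATION)
        orient.update(self.orientation)
        self.orientation = orient

    def channel_valid(self, name: str) -> np.ndarray:
        """Valid epochs for one channel: mask AND a finite reading."""
        return self.valid & np.isfinite(self.channels[name])


def composite_arousal(channels: ChannelSet, min_epochs: int = 10) -> ArousalSeries:
    """Collapse oriented, z-scored channels into one composite arousal series.

    Each channel is multiplied by its orientation sign, z-scored over its
    valid epochs, and the available channels are averaged per epoch (an
    epoch is valid when at least one channel is valid there).  The average
    is re-z-scored over its valid epochs, so the output is in within-person
    z-units with mean 0 and sample SD 1.
    """
    n = channels.grid.n_epochs
    zsum = np.zeros(n)
    zcnt = np.zeros(n)
    for name, vals in channels.channels.items():
        cv = channels.channel_valid(name)
        if cv.sum() < min_epochs:
            raise InsufficientDataError(
                f"channel {name!r} has {int(cv.sum())} valid epochs; >= {min_epochs} required"
            )
        if np.ptp(vals[cv]) == 0.0:
            raise ZeroVarianceError(f"channel {name!r} is constant over valid epochs")
        sign = channels.orientation.get(name, +1.0)
        z = zscore_masked(sign * vals, cv)
        zsum[cv] += z[cv]
        zcnt[cv] += 1
    valid = zcnt > 0
    if not valid.any():
        raise EmptyDataError("no epoch has any valid channel")
    avg = np.full(n, np.nan)
    avg[valid] = zsum[valid] / zcnt[valid]
    return ArousalSeries(
        dyad_id=channels.dyad_id,
        role=channels.role,
        grid=channels.grid,
        values=zscore_masked(avg, valid),
        valid=valid,
    )


def valid_lag_pairs(valid: np.ndarray) -> np.ndarray:
    """Indices t such that epochs t and t+1 are both valid."""
    valid = np.asarray(valid, dtype=bool)
    return np.flatnonzero(valid[:-1] & valid[1:])


def remove_autocorrelation(series: ArousalSeries, min_pairs: int = 20) -> ArousalSeries:
    """Residualise a first-order autoregression fit over valid lag-1 pairs.

    An OLS AR(1) fit x[t+1] = a + b x[t] is estimated from consecutive
    valid epoch pairs (gaps in the validity mask break pair formation).
    The output holds the re-z-scored residuals; epochs with no valid
    predecessor become invalid, since no residual is defined there.
    """
    pairs = valid_lag_pairs(series.valid)
    if pairs.size < min_pairs:
        raise InsufficientDataError(
            f"{pairs.size} valid lag-1 pairs; >= {min_pairs} required"
        )
    x = series.values[pairs]
    y = series.values[pairs + 1]
    if np.ptp(x) == 0.0:
        raise ZeroVarianceError("constant predecessor values; AR(1) fit undefined")
    b, a = np.polyfit(x, y, 1)
    resid = np.full(series.grid.n_epochs, np.nan)
    resid[pairs + 1] = y - (a + b * x)
    valid = np.isfinite(resid)
    return replace(series, values=zscore_masked(resid, valid), valid=valid)


def apply_mask(series: ArousalSeries, home_awake_mask) -> ArousalSeries:
    """Restrict a series to the given mask and re-z-score over survivors.

    Epochs outside the mask become invalid; z-scoring statistics (the
    "average arousal across the day" baseline) are recomputed on the epochs
    that remain, so 0 always means that participant's mean analysed arousal.
    Masking never resurrects previously invalid epochs.
    """
    mask = np.asarray(home_awake_mask, dtype=bool)
    if mask.shape != (series.grid.n_epochs,):
        raise VocaldyadError(
            f"mask length {mask.shape} does not match grid ({series.grid.n_epochs},)"
        )
    valid = series.valid & mask
    if not valid.any():
        raise EmptyDataError("mask leaves no valid epochs")
    return replace(series, values=zscore_masked(series.values, valid), valid=valid)
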