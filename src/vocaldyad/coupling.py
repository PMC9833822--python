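"""Moving-window arousal stability and interpersonal arousal coupling.

Stability is the lag-1 autocorrelation of one participant's arousal within
a moving window (higher = smoother, more persistent arousal); coupling is
the zero-lag Spearman correlation of the infant's and caregiver's
independently detrended arousal within the window (a synchrony index).
Windows are 10 epochs long and shift by 5 epochs by default; a window's
statistic is undefined (NaN, never 0) when fewer than ``min_valid`` usable
pairs/epochs remain.  Windowed statistics are then excerpted around events
by nearest-window-centre alignment and averaged across events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import (
    ArousalSeries,
    Dyad,
    EventSeries,
    InsufficientDataError,
    VocaldyadError,
)
from .eventlock import Trajectory, default_lags

__all__ = [
    "WindowedStatSeries",
    "lag1_autocorr",
    "zero_lag_coupling",
    "windowed_stability",
    "windowed_coupling",
    "windowed_series",
    "event_locked_stat",
]

DEFAULT_WINDOW = 10
DEFAULT_SHIFT = 5
DEFAULT_MIN_VALID = 5


@dataclass(frozen=True)
class WindowedStatSeries:
    """A statistic evaluated on shifted windows of the epoch grid."""

    centers: np.ndarray   # epoch index of each window centre
    values: np.ndarray    # statistic per window, NaN where undefined
    window: int
    shift: int
    kind: str             # "stability" | "coupling"

    def __len__(self) -> int:
        return len(self.centers)


def lag1_autocorr(window_values, window_mask=None, min_valid: int = DEFAULT_MIN_VALID) -> float:
    """Pearson correlation between x[t] and x[t+1] over valid pairs.

    Returns NaN (undefined, propagated rather than raised) when fewer than
    ``min_valid`` valid consecutive pairs exist or the pairs are degenerate.
    """
    x = np.asarray(window_values, dtype=float)
    if window_mask is None:
        mask = np.isfinite(x)
    else:
        mask = np.asarray(window_mask, dtype=bool) & np.isfinite(x)
    pair = mask[:-1] & mask[1:]
    if pair.sum() < min_valid:
        return np.nan
    a = x[:-1][pair]
    b = x[1:][pair]
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _detrend_valid(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """OLS-line detrend fitted on valid epochs; residuals NaN elsewhere."""
    t = np.flatnonzero(mask)
    out = np.full(x.shape, np.nan)
    if t.size < 2:
        return out
    slope, intercept = np.polyfit(t, x[t], 1)
    out[t] = x[t] - (intercept + slope * t)
    return out


def zero_lag_coupling(
    infant_window,
    caregiver_window,
    infant_mask=None,
    caregiver_mask=None,
    min_valid: int = DEFAULT_MIN_VALID,
) -> float:
    """Zero-lag Spearman correlation of independently detrended windows.

    Each side is detrended by an OLS line over its own valid epochs; the
    rank correlation (average ranks for ties) is computed over jointly
    valid epochs.  Undefined (NaN) when fewer than ``min_valid`` joint
    epochs remain or either residual is constant.
    """
    x = np.asarray(infant_window, dtype=float)
    y = np.asarray(caregiver_window, dtype=float)
    if x.shape != y.shape:
        raise VocaldyadError("windows must have equal length")
    mx = np.isfinite(x) if infant_mask is None else np.asarray(infant_mask, bool) & np.isfinite(x)
    my = np.isfinite(y) if caregiver_mask is None else np.asarray(caregiver_mask, bool) & np.isfinite(y)
    rx = _detrend_valid(x, mx)
    ry = _detrend_valid(y, my)
    joint = np.isfinite(rx) & np.isfinite(ry)
    if joint.sum() < min_valid:
        return np.nan
    a, b = rx[joint], ry[joint]
    if np.allclose(np.ptp(a), 0.0) or np.allclose(np.ptp(b), 0.0):
        return np.nan
    rho = sps.spearmanr(a, b).statistic
    return float(rho)


def _window_starts(n_epochs: int, window: int, shift: int) -> np.ndarray:
    if n_epochs < window:
        return np.array([], dtype=int)
    return np.arange(0, n_epochs - window + 1, shift)


def windowed_stability(
    series: ArousalSeries,
    window: int = DEFAULT_WINDOW,
    shift: int = DEFAULT_SHIFT,
    min_valid: int = DEFAULT_MIN_VALID,
) -> WindowedStatSeries:
    """Lag-1 autocorrelation of one participant's arousal per moving window."""
    starts = _window_starts(series.grid.n_epochs, window, shift)
    if starts.size == 0:
        warnings.warn("grid shorter than the window; empty windowed series", stacklevel=2)
    vals = np.array(
        [
            lag1_autocorr(series.values[i : i + window], series.valid[i : i + window], min_valid)
            for i in starts
        ]
    )
    return WindowedStatSeries(
        centers=starts + window // 2, values=vals, window=window, shift=shift, kind="stability"
    )


def windowed_coupling(
    dyad: Dyad,
    window: int = DEFAULT_WINDOW,
    shift: int = DEFAULT_SHIFT,
    min_valid: int = DEFAULT_MIN_VALID,
) -> WindowedStatSeries:
    """Detrended zero-lag rank correlation of the dyad's arousal per window."""
    starts = _window_starts(dyad.grid.n_epochs, window, shift)
    if starts.size == 0:
        warnings.warn("grid shorter than the window; empty windowed series", stacklevel=2)
    vals = np.array(
        [
            zero_lag_coupling(
                dyad.infant.values[i : i + window],
                dyad.caregiver.values[i : i + window],
                dyad.infant.valid[i : i + window],
                dyad.caregiver.valid[i : i + window],
                min_valid,
            )
            for i in starts
        ]
    )
    return WindowedStatSeries(
        centers=starts + window // 2, values=vals, window=window, shift=shift, kind="coupling"
    )


def windowed_series(
    dyad: Dyad,
    stat_kind: str,
    role: str | None = None,
    window: int = DEFAULT_WINDOW,
    shift: int = DEFAULT_SHIFT,
    min_valid: int = DEFAULT_MIN_VALID,
) -> WindowedStatSeries:
    """Dispatch to windowed stability (needs ``role``) or coupling."""
    if stat_kind == "stability":
        if role is None:
            raise VocaldyadError("stability requires a role")
        return windowed_stability(dyad.arousal(role), window, shift, min_valid)
    if stat_kind == "coupling":
        return windowed_coupling(dyad, window, shift, min_valid)
    raise VocaldyadError(f"unknown stat kind {stat_kind!r}")


def event_locked_stat(
    windowed: WindowedStatSeries,
    events: EventSeries,
    lags: np.ndarray | None = None,
) -> Trajectory:
    """Excerpt a windowed statistic around events and average across them.

    For each event and relative lag, the statistic of the window whose
    centre is nearest the lagged epoch is taken (ties resolved toward the
    earlier window); the per-lag mean over events ignores undefined
    windows, and a lag with no defined value anywhere stays NaN.
    """
    if lags is None:
        lags = default_lags()
    lags = np.asarray(lags, dtype=int)
    if len(events) == 0:
        raise InsufficientDataError("no events to lock to")
    if len(windowed) == 0:
        return Trajectory(lags=lags, mean=np.full(lags.size, np.nan),
                          counts=np.zeros(lags.size, dtype=int))
    centers = windowed.centers
    epochs = events.epochs()
    target = epochs[:, None] + lags[None, :]  # (E, L)
    # nearest centre, earlier window on ties: centres are sorted
    pos = np.searchsorted(centers, target)
    left = np.clip(pos - 1, 0, len(centers) - 1)
    right = np.clip(pos, 0, len(centers) - 1)
    use_right = np.abs(centers[right] - target) < np.abs(target - centers[left])
    nearest = np.where(use_right, right, left)
    vals = windowed.values[nearest]
    in_session = (target >= 0) & (target < int(centers[-1]) + windowed.window)
    vals = np.where(in_session, vals, np.nan)
    counts = np.isfinite(vals).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
    mean = np.where(counts > 0, mean, np.nan)
    return Trajectory(lags=lags, mean=mean, counts=counts)
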