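"""Delimited-text I/O for arousal and vocal-event tables.

Canonical schemas (TSV or CSV; the delimiter follows the file extension):

arousal table
    ``dyad_id, role, epoch, valid`` plus either a ``composite`` column
    (precomputed composite arousal) or any subset of the channel columns
    ``heart_rate, hrv, movement``.  One row per (dyad, role, epoch); epochs
    per participant must be contiguous from 0.

event table
    ``dyad_id, epoch, speaker, category`` plus optional ``affect`` and
    ``intensity``.  Categories may be the canonical labels (cry,
    speech_like, other) or raw morphological codes, which are collapsed:
    quasi-/fully-resonant vowels and marginal/canonical syllables map to
    speech_like; laughs, squeals and growls map to other (they are excluded
    from cry/speech contrasts).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CRY,
    OTHER,
    ROLES,
    SPEECH_LIKE,
    ArousalSeries,
    EpochGrid,
    EventSeries,
    SchemaError,
    VocalEvent,
)
from .preprocess import ChannelSet

__all__ = [
    "CATEGORY_MAP",
    "read_arousal_table",
    "read_event_table",
    "write_arousal_table",
    "write_event_table",
    "write_dyads",
]

CHANNEL_COLUMNS = ("heart_rate", "hrv", "movement")

#: raw vocal codes -> analysis categories
CATEGORY_MAP = {
    "cry": CRY,
    "speech_like": SPEECH_LIKE,
    "speech like": SPEECH_LIKE,
    "quasi-resonant vowel": SPEECH_LIKE,
    "quasi resonant vowel": SPEECH_LIKE,
    "fully-resonant vowel": SPEECH_LIKE,
    "fully resonant vowel": SPEECH_LIKE,
    "marginal syllable": SPEECH_LIKE,
    "canonical syllable": SPEECH_LIKE,
    "laugh": OTHER,
    "squeal": OTHER,
    "growl": OTHER,
    "other": OTHER,
}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    # +2: 1-based line numbers plus the header line
    df["_line"] = df.index + 2
    return df


def _normalise_category(raw: str) -> str | None:
    key = " ".join(str(raw).strip().lower().replace("_", " ").split())
    return CATEGORY_MAP.get(key)


def read_arousal_table(path) -> dict[tuple[str, str], ArousalSeries | ChannelSet]:
    """Read an arousal table into per-(dyad, role) series or channel sets.

    Rows with a ``composite`` column become :class:`ArousalSeries`
    directly (no compositing step needed); otherwise the channel columns
    present become a :class:`ChannelSet` for
    :func:`vocaldyad.preprocess.composite_arousal`.
    """
    df = _read(path, {"dyad_id", "role", "epoch", "valid"})
    has_composite = "composite" in df.columns
    channels = [c for c in CHANNEL_COLUMNS if c in df.columns]
    if not has_composite and not channels:
        raise SchemaError(
            f"{path}: need a 'composite' column or at least one of {CHANNEL_COLUMNS}"
        )
    out: dict[tuple[str, str], ArousalSeries | ChannelSet] = {}
    for (dyad_id, role), grp in df.groupby(["dyad_id", "role"], sort=True):
        dyad_id = str(dyad_id)
        if role not in ROLES:
            raise SchemaError(
                f"{path} line {int(grp['_line'].iloc[0])}: unknown role {role!r}"
            )
        dup = grp["epoch"].duplicated()
        if dup.any():
            line = int(grp.loc[dup, "_line"].iloc[0])
            raise SchemaError(
                f"{path} line {line}: duplicate epoch for ({dyad_id}, {role})"
            )
        grp = grp.sort_index()
        epochs = grp["epoch"].to_numpy()
        if np.any(np.diff(epochs) <= 0):
            bad = int(grp["_line"].to_numpy()[np.argmax(np.diff(epochs) <= 0) + 1])
            raise SchemaError(f"{path} line {bad}: non-monotone epoch order")
        if epochs[0] != 0 or not np.array_equal(epochs, np.arange(len(epochs))):
            raise SchemaError(
                f"{path}: epochs for ({dyad_id}, {role}) must be contiguous from 0"
            )
        grid = EpochGrid(n_epochs=len(epochs))
        valid = grp["valid"].to_numpy().astype(bool)
        if has_composite:
            out[(dyad_id, role)] = ArousalSeries(
                dyad_id=dyad_id,
                role=role,
                grid=grid,
                values=grp["composite"].to_numpy(dtype=float),
                valid=valid,
            )
        else:
            out[(dyad_id, role)] = ChannelSet(
                dyad_id=dyad_id,
                role=role,
                grid=grid,
                channels={c: grp[c].to_numpy(dtype=float) for c in channels},
                valid=valid,
            )
    return out


def read_event_table(path, grids: dict[str, EpochGrid] | None = None) -> dict[str, EventSeries]:
    """Read a vocal-event table into per-dyad event series.

    ``grids`` (dyad_id -> grid) pins the epoch grid; without it the grid
    extends to each dyad's largest event epoch.  Raw morphological codes
    are collapsed per :data:`CATEGORY_MAP`; unknown codes are an error.
    """
    df = _read(path, {"dyad_id", "epoch", "speaker", "category"})
    out: dict[str, EventSeries] = {}
    for dyad_id, grp in df.groupby("dyad_id", sort=True):
        dyad_id = str(dyad_id)
        events = []
        for _, row in grp.iterrows():
            if row["speaker"] not in ROLES:
                raise SchemaError(
                    f"{path} line {int(row['_line'])}: unknown speaker {row['speaker']!r}"
                )
            category = _normalise_category(row["category"])
            if category is None:
                raise SchemaError(
                    f"{path} line {int(row['_line'])}: unknown vocal code "
                    f"{row['category']!r}"
                )
            events.append(
                VocalEvent(
                    epoch=int(row["epoch"]),
                    speaker=str(row["speaker"]),
                    category=category,
                    affect=None if pd.isna(row.get("affect", np.nan)) else str(row["affect"]),
                    intensity=None if pd.isna(row.get("intensity", np.nan)) else str(row["intensity"]),
                )
            )
        if grids and dyad_id in grids:
            grid = grids[dyad_id]
        else:
            grid = EpochGrid(n_epochs=max(e.epoch for e in events) + 1)
        for e in events:
            if e.epoch < 0 or e.epoch >= grid.n_epochs:
                raise SchemaError(
                    f"{path}: event epoch {e.epoch} outside grid for dyad {dyad_id}"
                )
        out[dyad_id] = EventSeries.from_events(grid, events, collapse=True)
    return out


def write_arousal_table(series_list, path) -> None:
    """Write composite arousal series to a delimited table."""
    rows = []
    for s in series_list:
        for e in range(s.grid.n_epochs):
            rows.append(
                {
                    "dyad_id": s.dyad_id,
                    "role": s.role,
                    "epoch": e,
                    "composite": s.values[e],
                    "valid": int(s.valid[e]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False, float_format="%.6g")


def write_event_table(events_by_dyad: dict[str, EventSeries], path) -> None:
    rows = []
    for dyad_id, series in sorted(events_by_dyad.items()):
        for e in series.events:
            rows.append(
                {
                    "dyad_id": dyad_id,
                    "epoch": e.epoch,
                    "speaker": e.speaker,
                    "category": e.category,
                    "affect": e.affect or "",
                    "intensity": e.intensity or "",
                }
            )
    pd.DataFrame(
        rows, columns=["dyad_id", "epoch", "speaker", "category", "affect", "intensity"]
    ).to_csv(path, sep=_sep_for(path), index=False)


def write_dyads(dyads, arousal_path, event_path) -> None:
    """Write a cohort of dyads as one arousal table and one event table."""
    series = []
    events = {}
    for d in dyads:
        series.extend([d.infant, d.caregiver])
        events[d.dyad_id] = d.events
    write_arousal_table(series, arousal_path)
    write_event_table(events, event_path)
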