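import numpy as np
import pytest

from vocaldyad.core import (
    CAREGIVER,
    INFANT,
    ArousalSeries,
    Dyad,
    EpochGrid,
    EventSeries,
    VocalEvent,
)


def make_series(values, valid=None, role=INFANT, dyad_id="d0"):
    """ArousalSeries from raw values (no z-scoring applied)."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return ArousalSeries(
        dyad_id=dyad_id,
        role=role,
        grid=EpochGrid(n_epochs=len(values)),
        values=values,
        valid=np.asarray(valid, dtype=bool),
    )


def make_events(n_epochs, epochs, speaker=INFANT, category="cry"):
    grid = EpochGrid(n_epochs=n_epochs)
    return EventSeries(
        grid,
        tuple(VocalEvent(epoch=int(e), speaker=speaker, category=category) for e in epochs),
    )


def make_dyad(infant_values, caregiver_values, events=(), valid=None, dyad_id="d0"):
    inf = make_series(infant_values, valid, role=INFANT, dyad_id=dyad_id)
    cg = make_series(caregiver_values, valid, role=CAREGIVER, dyad_id=dyad_id)
    return Dyad(
        dyad_id=dyad_id,
        infant=inf,
        caregiver=cg,
        events=EventSeries(inf.grid, tuple(events)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
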