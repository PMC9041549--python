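"""Daily overheating-event counts per box.

An overheating event is a single hourly logger reading strictly above the
heat-stress threshold (40 °C by default): bats avoid such temperatures and
prolonged exposure can be lethal.  Counts run over recordings, not bats,
so days with incomplete grids are still counted among their available
readings; completeness is reported alongside.

Forest (fully shaded) placements log almost no events and make count
models rank-deficient, so the modelling table is filtered to exclude them.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microclimate import LEVELS, FACES, POSITIONS, RoostTemperatureGrid

__all__ = [
    "DEFAULT_THRESHOLD",
    "OverheatingDay",
    "count_daily_overheating",
    "overheating_table",
    "filter_for_overheating_model",
]

DEFAULT_THRESHOLD = 40.0
KNOWN_PLACEMENTS = ("open", "east", "west", "forest")


@dataclass(frozen=True)
class OverheatingDay:
    """Overheating summary for one box-day.

    ``per_position`` is a 12-vector of event counts in the fixed
    (level, face) position order; ``n_events`` is its sum and never
    exceeds ``n_readings`` (<= 144).
    """

    box_id: str
    date: dt.date
    n_events: int
    n_readings: int
    per_position: np.ndarray

    def by_level(self) -> dict[str, int]:
        counts = self.per_position.reshape(len(LEVELS), len(FACES))
        return {level: int(c) for level, c in zip(LEVELS, counts.sum(axis=1))}

    def by_face(self) -> dict[str, int]:
        counts = self.per_position.reshape(len(LEVELS), len(FACES))
        return {face: int(c) for face, c in zip(FACES, counts.sum(axis=0))}


def count_daily_overheating(
    grid: RoostTemperatureGrid, threshold: float = DEFAULT_THRESHOLD
) -> OverheatingDay:
    """Count readings strictly above ``threshold`` in one box-day grid.

    The comparison is strict (a reading of exactly 40.0 °C is not an
    event).  An empty grid yields zero events.
    """
    temps = np.asarray(grid.temps, dtype=float)
    hot = np.isfinite(temps) & (temps > threshold)
    per_position = hot.sum(axis=0).astype(int)
    return OverheatingDay(
        box_id=grid.box_id,
        date=grid.date,
        n_events=int(per_position.sum()),
        n_readings=int(np.isfinite(temps).sum()),
        per_position=per_position,
    )


def overheating_table(
    grids,
    threshold: float = DEFAULT_THRESHOLD,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-box-day overheating table.

    Columns: ``box_id, date, n_events, n_readings`` plus one
    ``events_<level>_<face>`` column per position; design/placement joined
    from ``metadata`` when provided.
    """
    pos_cols = [f"events_{level}_{face}" for level, face in POSITIONS]
    rows = []
    for grid in grids:
        day = count_daily_overheating(grid, threshold)
        row = {
            "box_id": day.box_id,
            "date": day.date,
            "n_events": day.n_events,
            "n_readings": day.n_readings,
        }
        row.update(dict(zip(pos_cols, day.per_position.tolist())))
        rows.append(row)
    table = pd.DataFrame(rows, columns=["box_id", "date", "n_events", "n_readings", *pos_cols])
    if metadata is not None and len(table):
        cols = [c for c in ("site", "design", "placement") if c in metadata.columns]
        table = table.merge(metadata[["box_id", *cols]], on="box_id", how="left")
    return table


def filter_for_overheating_model(
    box_days: pd.DataFrame, placements_to_drop: set[str] = frozenset({"forest"})
) -> pd.DataFrame:
    """Drop placements unusable in the count model (default: forest shade).

    Raises on placement labels outside the known set; warns when the
    filter empties the table.
    """
    labels = set(box_days["placement"].unique())
    unknown = labels - set(KNOWN_PLACEMENTS)
    if unknown:
        raise ValueError(f"unknown placement labels: {sorted(unknown)}")
    kept = box_days[~box_days["placement"].isin(placements_to_drop)].copy()
    if len(kept) == 0 and len(box_days) > 0:
        warnings.warn("all rows removed by placement filter", stacklevel=2)
    return kept
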