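"""Logger-record I/O and assembly into hourly box-day temperature grids.

A rocket box carries 12 temperature loggers: top, middle and bottom level
on each of the four faces (N, E, S, W).  To stretch logger memory over a
field season each logger records bi-hourly, on either even or odd hours;
parities alternate within each level so that every level contributes two
readings every hour.  A complete box-day therefore holds
12 loggers x 12 readings = 144 temperatures, six per hour.

The native CSV dialect has columns
``box_id, level, face, parity, timestamp, temp_c`` with an ISO
``YYYY-MM-DD HH:MM`` (or ``YYYY-MM-DDTHH:MM``) timestamp.  Hours are
integers 0-23 labelling the start of the recording hour; "even" parity
means hours {0, 2, ..., 22}.  Timestamps are taken as local logger time;
no timezone arithmetic is applied.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LEVELS",
    "FACES",
    "POSITIONS",
    "LoggerPosition",
    "TemperatureRecord",
    "RoostTemperatureGrid",
    "RowError",
    "ParseResult",
    "read_logger_csv",
    "write_logger_csv",
    "assemble_grids",
    "grid_to_records",
    "DuplicateRecordError",
]

LEVELS = ("top", "middle", "bottom")
FACES = ("N", "E", "S", "W")
#: Fixed position ordering: top-N, top-E, top-S, top-W, middle-N, ... bottom-W.
POSITIONS: tuple[tuple[str, str], ...] = tuple(
    (level, face) for level in LEVELS for face in FACES
)
POSITION_INDEX = {pos: i for i, pos in enumerate(POSITIONS)}

# sensor plausibility bounds, °C
_TEMP_MIN, _TEMP_MAX = -40.0, 85.0


class DuplicateRecordError(ValueError):
    """Two records share the same (box, position, timestamp)."""


@dataclass(frozen=True)
class LoggerPosition:
    """One of the 12 logger positions in a box, with its recording parity."""

    level: str
    face: str
    parity: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.face not in FACES:
            raise ValueError(f"unknown face {self.face!r}")
        if self.parity not in ("even", "odd"):
            raise ValueError(f"unknown parity {self.parity!r}")

    @property
    def index(self) -> int:
        """Column index in the fixed (level, face) ordering."""
        return POSITION_INDEX[(self.level, self.face)]

    def records_at(self, hour: int) -> bool:
        return hour % 2 == (0 if self.parity == "even" else 1)


@dataclass(frozen=True)
class TemperatureRecord:
    """A single logger reading: box, position, date, hour, temperature (°C)."""

    box_id: str
    position: LoggerPosition
    date: dt.date
    hour: int
    t_roost: float

    def __post_init__(self) -> None:
        if not 0 <= self.hour <= 23:
            raise ValueError(f"hour {self.hour} outside 0-23")
        if not self.position.records_at(self.hour):
            raise ValueError(
                f"hour {self.hour} does not match {self.position.parity} parity"
            )
        if not _TEMP_MIN < self.t_roost < _TEMP_MAX:
            raise ValueError(f"t_roost {self.t_roost} outside sensor bounds")


@dataclass
class RoostTemperatureGrid:
    """Hour x position roost-temperature matrix for one box-day.

    ``temps`` is a (24, 12) float array in the fixed :data:`POSITIONS`
    column order, NaN where the logger was not recording (off-parity hour
    or missing data).  The availability mask is simply ``isfinite(temps)``.
    """

    box_id: str
    date: dt.date
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps.shape != (24, len(POSITIONS)):
            raise ValueError(f"temps must be 24 x {len(POSITIONS)}")

    @property
    def available(self) -> np.ndarray:
        return np.isfinite(self.temps)

    @property
    def n_available(self) -> int:
        return int(self.available.sum())

    def readings_per_hour(self) -> np.ndarray:
        return self.available.sum(axis=1)


@dataclass(frozen=True)
class RowError:
    """A rejected CSV row with its 1-based line number and the reason."""

    line: int
    message: str


@dataclass
class ParseResult:
    records: list[TemperatureRecord]
    errors: list[RowError]


_REQUIRED_COLUMNS = ("box_id", "level", "face", "parity", "timestamp", "temp_c")


def _parse_timestamp(text: str) -> tuple[dt.date, int]:
    stamp = dt.datetime.fromisoformat(text.strip().replace("T", " "))
    return stamp.date(), stamp.hour


def read_logger_csv(path: str | Path, strict: bool = False) -> ParseResult:
    """Read logger records from the native CSV dialect.

    Malformed rows are rejected individually; diagnostics carry the
    1-based file line number.  Temperatures are passed through unmodified
    (no re-quantization).  With ``strict=True`` any rejected row raises.
    """
    records: list[TemperatureRecord] = []
    errors: list[RowError] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            line = reader.line_num
            try:
                position = LoggerPosition(
                    level=row["level"].strip(),
                    face=row["face"].strip(),
                    parity=row["parity"].strip(),
                )
                date, hour = _parse_timestamp(row["timestamp"])
                records.append(
                    TemperatureRecord(
                        box_id=row["box_id"].strip(),
                        position=position,
                        date=date,
                        hour=hour,
                        t_roost=float(row["temp_c"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line=line, message=str(exc)))
    if strict and errors:
        summary = "; ".join(f"line {e.line}: {e.message}" for e in errors[:5])
        raise ValueError(f"{path}: {len(errors)} invalid rows ({summary} ...)")
    return ParseResult(records=records, errors=errors)


def write_logger_csv(path: str | Path, records: Iterable[TemperatureRecord]) -> None:
    """Write records in the native CSV dialect (UTF-8, header row)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_REQUIRED_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.box_id,
                    rec.position.level,
                    rec.position.face,
                    rec.position.parity,
                    f"{rec.date.isoformat()} {rec.hour:02d}:00",
                    repr(rec.t_roost) if rec.t_roost % 1 else f"{rec.t_roost:.1f}",
                ]
            )


def assemble_grids(
    records: Iterable[TemperatureRecord],
) -> list[RoostTemperatureGrid]:
    """Assemble validated records into one grid per box-day present.

    Duplicate (box, position, timestamp) entries are a hard error — field
    data with genuine duplicates must be deduplicated explicitly upstream.
    Grids are returned sorted by (box_id, date).
    """
    grids: dict[tuple[str, dt.date], RoostTemperatureGrid] = {}
    for rec in records:
        key = (rec.box_id, rec.date)
        grid = grids.get(key)
        if grid is None:
            grid = RoostTemperatureGrid(
                box_id=rec.box_id,
                date=rec.date,
                temps=np.full((24, len(POSITIONS)), np.nan),
            )
            grids[key] = grid
        col = rec.position.index
        if np.isfinite(grid.temps[rec.hour, col]):
            raise DuplicateRecordError(
                f"duplicate reading for box {rec.box_id} "
                f"{rec.position.level}-{rec.position.face} at "
                f"{rec.date} hour {rec.hour}"
            )
        grid.temps[rec.hour, col] = rec.t_roost
    return [grids[key] for key in sorted(grids)]


def grid_to_records(
    grid: RoostTemperatureGrid, parity_by_position: Sequence[str] | None = None
) -> list[TemperatureRecord]:
    """Invert a grid back to individual records (round-trip support).

    Parities are inferred from which hours each position has data; a
    position with no readings needs ``parity_by_position`` to be named
    explicitly (12 entries in :data:`POSITIONS` order).
    """
    records = []
    for col, (level, face) in enumerate(POSITIONS):
        hours = np.flatnonzero(np.isfinite(grid.temps[:, col]))
        if parity_by_position is not None:
            parity = parity_by_position[col]
        elif hours.size:
            parity = "even" if hours[0] % 2 == 0 else "odd"
        else:
            continue
        position = LoggerPosition(level=level, face=face, parity=parity)
        for hour in hours:
            records.append(
                TemperatureRecord(
                    box_id=grid.box_id,
                    position=position,
                    date=grid.date,
                    hour=int(hour),
                    t_roost=float(grid.temps[hour, col]),
                )
            )
    return records
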