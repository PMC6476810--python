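"""Touch-event data model, validation, and readers/writers.

A smartphone trail-making game ("Jewels") produces one log row per screen
touch: who tapped, in which game, when (seconds since game start), what was
tapped, and whether the tap was correct.  The game *level* is the number of
jewels on screen, and hence the number of correct taps in a completed game.
Companion weekly streams (survey scores, step counts, weekly cognition
summaries) are kept in a simple long-format table.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AssessmentType",
    "MistakeCategory",
    "TouchEvent",
    "GameRecord",
    "WeeklyStream",
    "EventLogError",
    "SchemaError",
    "ParseError",
    "DataIntegrityError",
    "read_events",
    "write_events",
    "assemble_games",
    "mistake_category",
    "read_weekly_streams",
    "write_weekly_streams",
    "weekly_streams_to_frame",
]


class AssessmentType(str, Enum):
    """The two trail-making variants: numbered targets (A) or alternating
    number/letter targets requiring task switching (B)."""

    JEWELS_A = "JEWELS_A"
    JEWELS_B = "JEWELS_B"


class MistakeCategory(str, Enum):
    NONE = "NONE"
    ONE = "ONE"
    MORE_THAN_ONE = "MORE_THAN_ONE"


class EventLogError(ValueError):
    """Base class for event-log validation failures."""


class SchemaError(EventLogError):
    """The file does not carry the required columns/fields."""


class ParseError(EventLogError):
    """A row could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(f"row {row}: {message}" if row is not None else message)


class DataIntegrityError(EventLogError):
    """Events are individually well-formed but jointly inconsistent."""


# Epoch-millisecond timestamps are distinguished from seconds-from-start by
# magnitude: no single game lasts 10^8 seconds (~3 years).
_EPOCH_MS_THRESHOLD = 1e8


@dataclass(frozen=True, slots=True)
class TouchEvent:
    """One screen touch in one game."""

    subject_id: str
    game_id: str
    assessment_type: AssessmentType
    level: int
    t: float  # seconds since game start
    item: str
    correct: bool
    wall_time_start: datetime | None = None

    def __post_init__(self) -> None:
        if self.level < 1:
            raise EventLogError(f"level must be >= 1, got {self.level}")
        if not math.isfinite(self.t) or self.t < 0:
            raise EventLogError(f"touch time must be finite and >= 0, got {self.t}")


@dataclass(frozen=True, slots=True)
class GameRecord:
    """An ordered, validated tap sequence for one game.

    ``tap_times`` holds the times of the *correct* taps only;
    ``n_mistakes`` counts the incorrect touches.  A completed game has
    exactly ``level`` correct taps.
    """

    subject_id: str
    game_id: str
    assessment_type: AssessmentType
    level: int
    tap_times: tuple[float, ...]
    n_mistakes: int = 0
    completed: bool = True
    wall_time: datetime | None = None

    def __post_init__(self) -> None:
        if self.level < 1:
            raise EventLogError(f"level must be >= 1, got {self.level}")
        if self.n_mistakes < 0:
            raise EventLogError("n_mistakes must be >= 0")
        # ties are permitted (measure-zero for continuous tap times, but they
        # arise in constructed examples and are resolved by the Breslow
        # convention downstream); decreasing times are not
        if any(b < a for a, b in zip(self.tap_times, self.tap_times[1:])):
            raise EventLogError(
                f"tap_times must be non-decreasing, got {self.tap_times}"
            )
        if self.completed and len(self.tap_times) != self.level:
            raise EventLogError(
                f"completed game must have level={self.level} correct taps, "
                f"got {len(self.tap_times)}"
            )

    @property
    def completion_time(self) -> float:
        if not self.tap_times:
            raise EventLogError("game has no correct taps")
        return self.tap_times[-1]

    @property
    def mistake_cat(self) -> MistakeCategory:
        return mistake_category(self.n_mistakes)


@dataclass(slots=True)
class WeeklyStream:
    """Per-subject values of named data streams for one study week.

    ``values`` maps a stream name (``beta_A``, ``step_count``, survey score
    names, ...) to a float; missing entries are simply absent (or NaN).
    """

    subject_id: str
    week_index: int
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.week_index < 1:
            raise EventLogError(f"week_index must be >= 1, got {self.week_index}")


def mistake_category(n_mistakes: int) -> MistakeCategory:
    """Collapse a mistake count into the three-level category used for
    adjustment: 0, 1, or more than one.

    All counts >= 2 map to the same level, so games differing only in how
    far beyond one mistake they went are treated identically.
    """
    if n_mistakes < 0:
        raise EventLogError(f"mistake count must be >= 0, got {n_mistakes}")
    if n_mistakes == 0:
        return MistakeCategory.NONE
    if n_mistakes == 1:
        return MistakeCategory.ONE
    return MistakeCategory.MORE_THAN_ONE


# ---------------------------------------------------------------------------
# Readers / writers

EVENT_COLUMNS = [
    "subject_id",
    "game_id",
    "assessment_type",
    "level",
    "wall_time_start",
    "t_seconds",
    "item",
    "correct",
]

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_bool(raw: str, row: int) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"cannot parse correctness indicator {raw!r}", row)


def _parse_time(raw, row: int) -> float:
    try:
        t = float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"non-numeric timestamp {raw!r}", row) from None
    if not math.isfinite(t):
        raise ParseError(f"non-finite timestamp {raw!r}", row)
    # phone logs may carry epoch milliseconds; normalize to seconds later,
    # relative to the game's first event
    return t


def _parse_wall_time(raw, row: int) -> datetime | None:
    if raw is None or raw == "" or (isinstance(raw, float) and math.isnan(raw)):
        return None
    try:
        return datetime.fromisoformat(str(raw))
    except ValueError:
        raise ParseError(f"cannot parse wall_time_start {raw!r} as ISO-8601", row) from None


def _row_to_event(rec: Mapping, row: int) -> TouchEvent:
    try:
        atype = AssessmentType(str(rec["assessment_type"]).strip())
    except ValueError:
        raise ParseError(
            f"unknown assessment_type {rec['assessment_type']!r}", row
        ) from None
    try:
        level = int(rec["level"])
    except (TypeError, ValueError):
        raise ParseError(f"non-integer level {rec['level']!r}", row) from None
    try:
        return TouchEvent(
            subject_id=str(rec["subject_id"]),
            game_id=str(rec["game_id"]),
            assessment_type=atype,
            level=level,
            t=_parse_time(rec["t_seconds"], row),
            item=str(rec["item"]),
            correct=_parse_bool(rec["correct"], row),
            wall_time_start=_parse_wall_time(rec.get("wall_time_start"), row),
        )
    except EventLogError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(str(exc), row) from None


def _normalize_epoch_times(events: list[TouchEvent]) -> list[TouchEvent]:
    """Convert epoch-millisecond timestamps to seconds from game start.

    Applied per game: if a game's times look like epoch milliseconds, they
    are shifted to start at the first event and scaled to seconds.
    """
    by_game: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        by_game.setdefault(ev.game_id, []).append(i)
    out = list(events)
    for idx in by_game.values():
        times = [events[i].t for i in idx]
        if min(times) >= _EPOCH_MS_THRESHOLD:
            t0 = min(times)
            for i in idx:
                ev = events[i]
                out[i] = TouchEvent(
                    subject_id=ev.subject_id,
                    game_id=ev.game_id,
                    assessment_type=ev.assessment_type,
                    level=ev.level,
                    t=(ev.t - t0) / 1000.0,
                    item=ev.item,
                    correct=ev.correct,
                    wall_time_start=ev.wall_time_start,
                )
    return out


def read_events(path: str | Path, format: str | None = None) -> list[TouchEvent]:
    """Read a touch-event log (CSV or JSON-lines) into TouchEvents.

    The format is inferred from the suffix unless given explicitly
    (``"csv"`` or ``"jsonl"``).  Rows are returned in file order; a
    malformed row raises :class:`ParseError` naming its 1-based data-row
    number.  Epoch-millisecond timestamps are normalized to seconds from
    each game's first event.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"csv", "jsonl"}:
        raise SchemaError(f"unsupported event-log format {fmt!r}")

    events: list[TouchEvent] = []
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = set(EVENT_COLUMNS) - {"wall_time_start"} - set(reader.fieldnames)
            if missing:
                raise SchemaError(f"missing required columns: {sorted(missing)}")
            for row_no, rec in enumerate(reader, start=1):
                events.append(_row_to_event(rec, row_no))
    else:
        with open(path) as fh:
            for row_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError:
                    raise ParseError("invalid JSON", row_no) from None
                missing = set(EVENT_COLUMNS) - {"wall_time_start"} - set(rec)
                if missing:
                    raise SchemaError(
                        f"row {row_no}: missing required fields: {sorted(missing)}"
                    )
                events.append(_row_to_event(rec, row_no))
    return _normalize_epoch_times(events)


def write_events(events: Iterable[TouchEvent], path: str | Path, format: str | None = None) -> None:
    """Write touch events in the same schema :func:`read_events` accepts."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"csv", "jsonl"}:
        raise SchemaError(f"unsupported event-log format {fmt!r}")
    rows = [
        {
            "subject_id": ev.subject_id,
            "game_id": ev.game_id,
            "assessment_type": ev.assessment_type.value,
            "level": ev.level,
            "wall_time_start": ev.wall_time_start.isoformat() if ev.wall_time_start else "",
            "t_seconds": repr(ev.t),
            "item": ev.item,
            "correct": "true" if ev.correct else "false",
        }
        for ev in events
    ]
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=EVENT_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    else:
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def assemble_games(events: Sequence[TouchEvent]) -> list[GameRecord]:
    """Group touch events by game and build validated GameRecords.

    Correct-tap times become ``tap_times``; incorrect touches are counted
    into ``n_mistakes``.  A game is completed when its number of correct
    taps equals its level.  Incomplete games are returned with
    ``completed=False`` rather than dropped.

    Raises :class:`DataIntegrityError` when a game has more correct taps
    than its level or non-monotone times.
    """
    order: list[str] = []
    by_game: dict[str, list[TouchEvent]] = {}
    for ev in events:
        if ev.game_id not in by_game:
            order.append(ev.game_id)
            by_game[ev.game_id] = []
        by_game[ev.game_id].append(ev)

    games: list[GameRecord] = []
    for gid in order:
        evs = by_game[gid]
        meta = evs[0]
        if {e.subject_id for e in evs} != {meta.subject_id}:
            raise DataIntegrityError(f"game {gid}: multiple subject_ids")
        if len({e.level for e in evs}) != 1 or len({e.assessment_type for e in evs}) != 1:
            raise DataIntegrityError(f"game {gid}: inconsistent level or assessment_type")
        times = [e.t for e in evs]
        if any(b < a for a, b in zip(times, times[1:])):
            raise DataIntegrityError(f"game {gid}: touch times are not non-decreasing")
        tap_times = tuple(e.t for e in evs if e.correct)
        n_mistakes = sum(not e.correct for e in evs)
        if len(tap_times) > meta.level:
            raise DataIntegrityError(
                f"game {gid}: {len(tap_times)} correct taps exceeds level {meta.level}"
            )
        games.append(
            GameRecord(
                subject_id=meta.subject_id,
                game_id=gid,
                assessment_type=meta.assessment_type,
                level=meta.level,
                tap_times=tap_times,
                n_mistakes=n_mistakes,
                completed=len(tap_times) == meta.level,
                wall_time=meta.wall_time_start,
            )
        )
    return games


# ---------------------------------------------------------------------------
# Weekly streams (long-format CSV: subject_id, week_index, stream, value)


def weekly_streams_to_frame(streams: Iterable[WeeklyStream]) -> pd.DataFrame:
    rows = [
        {"subject_id": s.subject_id, "week_index": s.week_index, "stream": k, "value": v}
        for s in streams
        for k, v in s.values.items()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "week_index", "stream", "value"])


def write_weekly_streams(streams: Iterable[WeeklyStream], path: str | Path) -> None:
    weekly_streams_to_frame(streams).to_csv(path, index=False)


def read_weekly_streams(path: str | Path) -> list[WeeklyStream]:
    df = pd.read_csv(path)
    required = {"subject_id", "week_index", "stream", "value"}
    if not required <= set(df.columns):
        raise SchemaError(f"weekly-stream file missing columns: {sorted(required - set(df.columns))}")
    out: dict[tuple[str, int], WeeklyStream] = {}
    for rec in df.itertuples(index=False):
        key = (str(rec.subject_id), int(rec.week_index))
        ws = out.setdefault(key, WeeklyStream(subject_id=key[0], week_index=key[1]))
        ws.values[str(rec.stream)] = float(rec.value)
    return list(out.values())
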