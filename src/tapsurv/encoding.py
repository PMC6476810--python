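"""Survival encoding of tap sequences.

Each jewel on screen is treated as a subject at risk from game start; the
tap that clears it is the event, observed at the tap time.  A level-L game
is therefore L event times, and its empirical survival function is a
Kaplan-Meier curve stepping down by 1/L per tap.

Two games of different levels are made comparable by administrative
censoring tied to the level: the lower-level game contributes additional
*censored* pseudo-jewels at its completion time, so both games carry the
same number of at-risk units (the pairwise maximum level).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from lifelines import KaplanMeierFitter

from .events import GameRecord

__all__ = [
    "Unit",
    "Status",
    "SurvivalRecord",
    "SurvivalDataset",
    "KMCurve",
    "encode_pair",
    "km_curve",
]


class Unit(str, Enum):
    REFERENCE = "REFERENCE"
    ASSESSMENT = "ASSESSMENT"


class Status(str, Enum):
    EVENT = "EVENT"
    CENSORED = "CENSORED"


@dataclass(frozen=True, slots=True)
class SurvivalRecord:
    unit: Unit
    time: float
    status: Status
    tap_index: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"survival time must be finite and positive, got {self.time}")


@dataclass(frozen=True, slots=True)
class SurvivalDataset:
    """Encoded records for one assessment-vs-reference comparison.

    Each unit contributes exactly ``max_level`` records: its events plus
    any level-based censorings at its completion time.
    """

    records: tuple[SurvivalRecord, ...]
    max_level: int

    def __post_init__(self) -> None:
        for unit in Unit:
            n = sum(r.unit is unit for r in self.records)
            if n != self.max_level:
                raise ValueError(
                    f"{unit.value} carries {n} records, expected max_level={self.max_level}"
                )

    def arrays(self):
        """(times, is_event, is_assessment) as numpy arrays."""
        t = np.array([r.time for r in self.records])
        e = np.array([r.status is Status.EVENT for r in self.records])
        x = np.array([r.unit is Unit.ASSESSMENT for r in self.records])
        return t, e, x

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "unit": [r.unit.value for r in self.records],
                "time": [r.time for r in self.records],
                "status": [r.status.value for r in self.records],
                "tap_index": [r.tap_index for r in self.records],
            }
        )


@dataclass(frozen=True, slots=True)
class KMCurve:
    """A right-continuous step function S(t): times and the survival value
    just after each time.  S(0)=1; for a completed game with no censoring
    the curve reaches 0 at the last tap."""

    times: tuple[float, ...]
    survival: tuple[float, ...]

    def at(self, t: float) -> float:
        s = 1.0
        for tk, sk in zip(self.times, self.survival):
            if tk <= t:
                s = sk
            else:
                break
        return s


def _unit_records(game: GameRecord, unit: Unit, max_level: int,
                  censor_incomplete: bool) -> list[SurvivalRecord]:
    if not game.completed and not censor_incomplete:
        raise ValueError(
            f"game {game.game_id} is incomplete; pass censor_incomplete=True to "
            "censor its unobserved taps at the last observed tap time"
        )
    if not game.tap_times:
        raise ValueError(f"game {game.game_id} has no correct taps")
    recs = [
        SurvivalRecord(unit=unit, time=t, status=Status.EVENT, tap_index=k + 1)
        for k, t in enumerate(game.tap_times)
    ]
    n_censor = max_level - len(recs)
    end = game.tap_times[-1]
    for j in range(n_censor):
        recs.append(
            SurvivalRecord(unit=unit, time=end, status=Status.CENSORED,
                           tap_index=len(game.tap_times) + j + 1)
        )
    return recs


def encode_pair(assessment: GameRecord, reference: GameRecord,
                *, max_level: int | None = None,
                censor_incomplete: bool = False) -> SurvivalDataset:
    """Encode an assessment and a reference game as one survival dataset.

    Every correct tap becomes an EVENT at its tap time; all jewels enter
    the risk set at time 0.  If one game's level is below ``max_level``
    (by default the pairwise maximum), it additionally contributes
    (max_level - level) CENSORED records at its completion time, making
    the two units comparable despite different difficulty levels.

    ``max_level`` may be set higher (e.g. a study-wide maximum level) to
    censor against a global baseline instead of the pairwise maximum.
    """
    pairwise = max(assessment.level, reference.level)
    if max_level is None:
        max_level = pairwise
    elif max_level < pairwise:
        raise ValueError(f"max_level={max_level} below pairwise maximum {pairwise}")
    records = _unit_records(reference, Unit.REFERENCE, max_level, censor_incomplete)
    records += _unit_records(assessment, Unit.ASSESSMENT, max_level, censor_incomplete)
    return SurvivalDataset(records=tuple(records), max_level=max_level)


def km_curve(game: GameRecord) -> KMCurve:
    """Kaplan-Meier curve of one completed game.

    With L = level jewels at risk from time 0 and no censoring, the
    product-limit estimate steps down by 1/L at each tap time (by k/L at a
    k-fold tie).
    """
    if not game.tap_times:
        raise ValueError("cannot build a KM curve from a game with no taps")
    if not game.completed:
        raise ValueError("KM curve requires a completed game")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(game.tap_times), event_observed=np.ones(len(game.tap_times)))
    sf = kmf.survival_function_
    times = [float(t) for t in sf.index if t > 0]
    surv = [float(sf.loc[t].iloc[0]) for t in sf.index if t > 0]
    return KMCurve(times=tuple(times), survival=tuple(surv))
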