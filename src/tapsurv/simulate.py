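"""Synthetic smartphone-study generator.

Produces complete synthetic studies — per-touch game logs, weekly survey
and step-count streams, and a ground-truth table — with the statistical
structure the scoring pipeline assumes:

* two groups (controls and patients) whose per-tap hazard differs
  negligibly on the simple task (Jewels A) and substantially on the
  task-switching task (Jewels B);
* heterogeneous difficulty levels, occasional incorrect touches,
  between-subject heterogeneity, and optional week-to-week fluctuation
  of each subject's cognitive state;
* asymmetric adherence: patients complete roughly three times as many
  assessments per week as controls;
* companion weekly step counts and survey scores, optionally linearly
  coupled to the weekly cognitive state.

Inter-tap gaps are exponential, i.e. each jewel is cleared at a constant
hazard — the minimal process under which the Cox encoding of the scoring
stage is correctly specified; a Weibull shape parameter is available to
stress-test departures from proportional hazards.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .events import AssessmentType, GameRecord, TouchEvent, WeeklyStream

__all__ = [
    "SimulationConfig",
    "simulate_study",
    "fig2_fixture",
    "subject_group",
]


_LETTERS = string.ascii_uppercase


def _default_rates() -> dict[tuple[str, str], float]:
    # mean completed assessments over 12 weeks: controls 8 per task,
    # patients 24 (A) and 22 (B)
    return {
        ("control", "JEWELS_A"): 8 / 12,
        ("control", "JEWELS_B"): 8 / 12,
        ("patient", "JEWELS_A"): 24 / 12,
        ("patient", "JEWELS_B"): 22 / 12,
    }


def _default_levels() -> dict[int, float]:
    return {2: 0.25, 3: 0.35, 4: 0.25, 5: 0.15}


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Per-tap hazard for a subject's game is

        rate = base_tap_rate * exp(level_effect * level + group effect
                                   + subject effect + weekly state),

    where the group effect is ``group_effect_A`` or ``group_effect_B``
    for patients (0 for controls), the subject effect is N(0,
    subject_sd^2) and the weekly state is N(0, weekly_sd^2), redrawn each
    week and shared by that week's games and coupled streams.
    """

    seed: int = 0
    n_control: int = 17
    n_patient: int = 18
    weeks: int = 12
    games_per_week: dict[tuple[str, str], float] = field(default_factory=_default_rates)
    level_dist: dict[int, float] = field(default_factory=_default_levels)
    base_tap_rate: float = 0.5  # taps per second at level 0 covariates
    level_effect: float = -0.1  # per-level change in log tap rate
    group_effect_A: float = 0.0
    group_effect_B: float = -0.8
    subject_sd: float = 0.3
    weekly_sd: float = 0.0
    mistake_prob: float = 0.05  # per-tap probability of an incorrect touch
    weibull_shape: float = 1.0  # 1 = exponential gaps
    include_streams: bool = True
    step_mean: float = 6000.0
    step_sd: float = 1500.0
    step_coupling: float = 0.0  # steps added per unit weekly cognitive state
    survey_mean: float = 10.0
    survey_sd: float = 3.0
    survey_coupling: float = 0.0
    stream_missing_prob: float = 0.1
    start_date: datetime = datetime(2024, 1, 1)

    def validate(self) -> None:
        problems = []
        if self.seed < 0:
            problems.append("seed must be >= 0")
        if self.n_control < 0 or self.n_patient < 0:
            problems.append("group sizes must be >= 0")
        if self.weeks < 1:
            problems.append("weeks must be >= 1")
        if any(r < 0 for r in self.games_per_week.values()):
            problems.append("games_per_week rates must be >= 0")
        if self.base_tap_rate <= 0:
            problems.append("base_tap_rate must be > 0")
        if not self.level_dist or any(l < 1 for l in self.level_dist):
            problems.append("level_dist must map levels >= 1 to weights")
        if any(w < 0 for w in self.level_dist.values()) or sum(self.level_dist.values()) <= 0:
            problems.append("level_dist weights must be >= 0 and sum > 0")
        if not (0.0 <= self.mistake_prob <= 1.0):
            problems.append("mistake_prob must be in [0, 1]")
        if not (0.0 <= self.stream_missing_prob <= 1.0):
            problems.append("stream_missing_prob must be in [0, 1]")
        if self.subject_sd < 0 or self.weekly_sd < 0:
            problems.append("subject_sd and weekly_sd must be >= 0")
        if self.weibull_shape <= 0:
            problems.append("weibull_shape must be > 0")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


def subject_group(subject_id: str) -> str:
    """Group of a simulated subject, encoded in the id prefix."""
    if subject_id.startswith("C"):
        return "control"
    if subject_id.startswith("P"):
        return "patient"
    raise ValueError(f"cannot infer group from subject id {subject_id!r}")


def _item_sequence(atype: AssessmentType, level: int) -> list[str]:
    if atype is AssessmentType.JEWELS_A:
        return [str(k + 1) for k in range(level)]
    # task switching: 1 -> A -> 2 -> B -> ...
    items = []
    for k in range(level):
        items.append(str(k // 2 + 1) if k % 2 == 0 else _LETTERS[k // 2])
    return items


def _game_events(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    subject_id: str,
    game_id: str,
    atype: AssessmentType,
    level: int,
    log_rate: float,
    wall_time: datetime,
) -> list[TouchEvent]:
    rate = cfg.base_tap_rate * np.exp(log_rate + cfg.level_effect * level)
    if cfg.weibull_shape == 1.0:
        gaps = rng.exponential(1.0 / rate, size=level)
    else:
        gaps = rng.weibull(cfg.weibull_shape, size=level) / rate
    taps = np.cumsum(gaps)
    items = _item_sequence(atype, level)
    events: list[TouchEvent] = []
    prev = 0.0
    for k, (t, item) in enumerate(zip(taps, items)):
        if rng.random() < cfg.mistake_prob:
            tm = float(rng.uniform(prev, t))
            events.append(
                TouchEvent(subject_id, game_id, atype, level, tm, "WRONG",
                           correct=False, wall_time_start=wall_time)
            )
        events.append(
            TouchEvent(subject_id, game_id, atype, level, float(t), item,
                       correct=True, wall_time_start=wall_time)
        )
        prev = float(t)
    return events


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[TouchEvent], list[WeeklyStream], pd.DataFrame]:
    """Generate one synthetic study: (events, weekly streams, ground truth).

    Fully reproducible from ``config.seed``.  The ground-truth table has
    one row per subject with the group, the subject's log-hazard offset
    and the group effects in force for each task.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    subjects = [f"C{k + 1:02d}" for k in range(config.n_control)] + [
        f"P{k + 1:02d}" for k in range(config.n_patient)
    ]
    levels = sorted(config.level_dist)
    level_p = np.array([config.level_dist[l] for l in levels], dtype=float)
    level_p = level_p / level_p.sum()

    events: list[TouchEvent] = []
    streams: list[WeeklyStream] = []
    truth_rows = []
    game_counter = 0

    for sid in subjects:
        group = subject_group(sid)
        subj_eff = float(rng.normal(0.0, config.subject_sd))
        truth_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "subject_effect": subj_eff,
                "group_effect_A": config.group_effect_A if group == "patient" else 0.0,
                "group_effect_B": config.group_effect_B if group == "patient" else 0.0,
            }
        )
        for week in range(1, config.weeks + 1):
            week_state = float(rng.normal(0.0, config.weekly_sd)) if config.weekly_sd > 0 else 0.0
            for atype in AssessmentType:
                rate = config.games_per_week[(group, atype.value)]
                n_games = rng.poisson(rate)
                geff = (
                    (config.group_effect_A if atype is AssessmentType.JEWELS_A else config.group_effect_B)
                    if group == "patient"
                    else 0.0
                )
                for _ in range(n_games):
                    game_counter += 1
                    gid = f"g{game_counter:06d}"
                    level = int(rng.choice(levels, p=level_p))
                    wall = (
                        config.start_date
                        + timedelta(days=7 * (week - 1))
                        + timedelta(days=float(rng.uniform(0, 7)))
                    )
                    events.extend(
                        _game_events(
                            rng, config, sid, gid, atype, level,
                            geff + subj_eff + week_state, wall,
                        )
                    )
            if config.include_streams:
                ws = WeeklyStream(subject_id=sid, week_index=week)
                if rng.random() >= config.stream_missing_prob:
                    ws.values["step_count"] = float(
                        config.step_mean
                        + config.step_coupling * week_state
                        + rng.normal(0.0, config.step_sd)
                    )
                if rng.random() >= config.stream_missing_prob:
                    ws.values["survey_score"] = float(
                        config.survey_mean
                        + config.survey_coupling * week_state
                        + rng.normal(0.0, config.survey_sd)
                    )
                if ws.values:
                    streams.append(ws)

    truth = pd.DataFrame(truth_rows)
    return events, streams, truth


def fig2_fixture() -> tuple[GameRecord, GameRecord, GameRecord]:
    """Deterministic worked example: a reference and two assessments.

    Returns (reference, assessment_B, assessment_C):

    * the reference path has three jewels tapped at 1, 2 and 3 s;
    * assessment C also has three jewels but uniformly later taps
      (2, 4, 6 s) — slower on every tap, finishing later;
    * assessment B has only two jewels, each tapped more slowly
      (1.5 and 3.0 s), finishing exactly when the reference does.

    Scored against the reference, C's hazard ratio is the smallest and
    B's lies between C's and the reference's own ratio of 1 — level-based
    censoring is what makes the two-jewel game comparable at all.
    Bit-identical across calls.
    """
    ref = GameRecord(
        subject_id="ref", game_id="fig2_reference",
        assessment_type=AssessmentType.JEWELS_A, level=3,
        tap_times=(1.0, 2.0, 3.0),
    )
    b = GameRecord(
        subject_id="s1", game_id="fig2_assessment_B",
        assessment_type=AssessmentType.JEWELS_A, level=2,
        tap_times=(1.5, 3.0),
    )
    c = GameRecord(
        subject_id="s1", game_id="fig2_assessment_C",
        assessment_type=AssessmentType.JEWELS_A, level=3,
        tap_times=(2.0, 4.0, 6.0),
    )
    return ref, b, c
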