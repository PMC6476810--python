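"""Cox proportional-hazards scoring of games against a control reference.

The reference path for an (assessment type, level) pair is a pseudo-game
whose k-th tap time is the mean of the k-th correct-tap times across
completed control games.  Every game is then compared to its reference in
a two-unit Cox model with a single binary covariate (assessment = 1,
reference = 0); the fitted hazard ratio exp(log_hr) is the game's score.
HR = 1 means performance matching the control average, HR < 1 slower
tapping (lower measured cognition), HR > 1 faster.

The log partial likelihood uses the Breslow convention for tied event
times.  Because the model has a single scalar coefficient, the fit is an
analytic Newton maximization with closed-form score and information; a
grid-search oracle over the same likelihood is exposed for verification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .encoding import SurvivalDataset, Status, Unit, encode_pair
from .events import AssessmentType, GameRecord, MistakeCategory

__all__ = [
    "ReferencePath",
    "HazardRatioEstimate",
    "ScoringError",
    "build_reference",
    "build_reference_table",
    "partial_likelihood",
    "cox_fit",
    "grid_oracle",
    "score_all",
    "estimates_to_frame",
]

logger = logging.getLogger(__name__)

#: search interval for log hazard ratio; exiting it signals monotone likelihood
LOG_HR_BOUND = 10.0
#: ridge penalty applied on detected monotone likelihood
RIDGE_LAMBDA = 0.1


class ScoringError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class ReferencePath:
    """Control-derived expected tap times for one (assessment type, level)."""

    assessment_type: AssessmentType
    level: int
    tap_times: tuple[float, ...]
    n_source_games: int

    def __post_init__(self) -> None:
        if len(self.tap_times) != self.level:
            raise ScoringError(
                f"reference path must have level={self.level} tap times"
            )
        if any(b <= a for a, b in zip(self.tap_times, self.tap_times[1:])):
            raise ScoringError(
                f"reference tap times must be strictly increasing, got {self.tap_times}"
            )

    def as_game(self) -> GameRecord:
        return GameRecord(
            subject_id="__reference__",
            game_id=f"ref_{self.assessment_type.value}_L{self.level}",
            assessment_type=self.assessment_type,
            level=self.level,
            tap_times=self.tap_times,
        )


@dataclass(frozen=True, slots=True)
class HazardRatioEstimate:
    game_id: str
    subject_id: str
    assessment_type: AssessmentType
    log_hr: float
    se: float
    level: int
    mistake_cat: MistakeCategory
    wall_time: datetime | None = None
    week_index: int | None = None
    converged: bool = True
    penalized: bool = False

    def __post_init__(self) -> None:
        if self.converged and not (self.se > 0):
            raise ScoringError("converged estimate must carry a positive se")

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)


def build_reference(
    control_games: list[GameRecord],
    assessment_type: AssessmentType,
    level: int,
    *,
    exclude_subject: str | None = None,
) -> ReferencePath:
    """Average control games into the reference path for one type/level.

    The k-th reference tap time is the arithmetic mean of the k-th
    (cumulative) correct-tap time over completed control games of the
    given type and level; averaging cumulative times keeps the result
    monotone whenever every source game is.  ``exclude_subject`` supports
    leave-one-out references for scoring controls against the others.
    """
    src = [
        g
        for g in control_games
        if g.completed
        and g.assessment_type == assessment_type
        and g.level == level
        and g.subject_id != exclude_subject
    ]
    if not src:
        raise ScoringError(
            f"no completed control games for {assessment_type.value} level {level}; "
            "pool neighbouring levels or supply an explicit reference"
        )
    taps = np.mean([g.tap_times for g in src], axis=0)
    return ReferencePath(
        assessment_type=assessment_type,
        level=level,
        tap_times=tuple(float(t) for t in taps),
        n_source_games=len(src),
    )


def build_reference_table(
    control_games: list[GameRecord],
    *,
    exclude_subject: str | None = None,
) -> dict[tuple[AssessmentType, int], ReferencePath]:
    """References for every (type, level) present among the control games."""
    keys = {
        (g.assessment_type, g.level)
        for g in control_games
        if g.completed and g.subject_id != exclude_subject
    }
    return {
        key: build_reference(control_games, *key, exclude_subject=exclude_subject)
        for key in sorted(keys, key=lambda k: (k[0].value, k[1]))
    }


# ---------------------------------------------------------------------------
# Breslow partial likelihood for the two-unit binary-covariate model


def _event_counts(data: SurvivalDataset):
    """Per distinct event time: (#events with x=0, #events with x=1,
    #at-risk with x=0, #at-risk with x=1).

    At-risk counts follow the standard convention that units censored at
    an event time are still in the risk set at that time.
    """
    t, e, x = data.arrays()
    if not np.all(np.isfinite(t)):
        raise ScoringError("non-finite survival times")
    ev_times = np.unique(t[e])
    if ev_times.size == 0:
        raise ScoringError("dataset has no events")

    def _counts(unit_mask):
        tu = np.sort(t[unit_mask])
        te = np.sort(t[unit_mask & e])
        # events of this unit at each distinct event time
        d = np.searchsorted(te, ev_times, side="right") - np.searchsorted(
            te, ev_times, side="left"
        )
        # still at risk at each event time (censored at t counts as at risk)
        n = tu.size - np.searchsorted(tu, ev_times, side="left")
        return d.astype(float), n.astype(float)

    d0, n0 = _counts(~x)
    d1, n1 = _counts(x)
    # plain Python floats: the per-comparison arrays are tiny (<= 2 * level
    # entries) and the Newton loop evaluates these kernels thousands of
    # times across a study
    return d0.tolist(), d1.tolist(), n0.tolist(), n1.tolist()


def _logpl(beta: float, d0, d1, n0, n1) -> float:
    eb = math.exp(beta)
    out = 0.0
    for a0, a1, m0, m1 in zip(d0, d1, n0, n1):
        out += a1 * beta - (a0 + a1) * math.log(m0 + m1 * eb)
    return out


def _score_info(beta: float, d0, d1, n0, n1):
    eb = math.exp(beta)
    score = 0.0
    info = 0.0
    for a0, a1, m0, m1 in zip(d0, d1, n0, n1):
        p = m1 * eb / (m0 + m1 * eb)  # E[x | at risk] at this event time
        d = a0 + a1
        score += a1 - d * p
        info += d * p * (1.0 - p)
    return score, info


def partial_likelihood(data: SurvivalDataset, log_hr: float) -> float:
    """Breslow log partial likelihood of the two-unit comparison at a given
    log hazard ratio.

    Each event at time t contributes ``x*beta - log(sum over the risk set
    at t of exp(x*beta))``; tied events all use the full risk set at their
    common time.  Exposed publicly so brute-force oracles and unit tests
    can evaluate the objective the fitter maximizes.
    """
    if not np.isfinite(log_hr):
        raise ScoringError("log_hr must be finite")
    return _logpl(log_hr, *_event_counts(data))


def grid_oracle(data: SurvivalDataset, *, bound: float = LOG_HR_BOUND,
                coarse: int = 4001, refine_iters: int = 12) -> float:
    """Brute-force maximizer of the Breslow partial likelihood.

    A fine grid over [-bound, bound] followed by interval refinement
    around the best point; independent of the Newton path in
    :func:`cox_fit` and used to verify it.
    """
    counts = _event_counts(data)
    grid = np.linspace(-bound, bound, coarse)
    vals = [_logpl(b, *counts) for b in grid]
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, coarse - 1)]
    for _ in range(refine_iters):
        grid = np.linspace(lo, hi, 41)
        vals = [_logpl(b, *counts) for b in grid]
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, 40)]
    return float(grid[i])


def _newton(counts, ridge: float, tol: float = 1e-10, max_iter: int = 200):
    """Maximize logPL - ridge*beta^2 by damped Newton; returns (beta, info)."""
    beta = 0.0
    for _ in range(max_iter):
        score, info = _score_info(beta, *counts)
        score -= 2.0 * ridge * beta
        info_pen = info + 2.0 * ridge
        if info_pen <= 0:  # flat likelihood (e.g. single event in one unit)
            break
        step = score / info_pen
        # dampen huge steps so the iteration cannot overshoot into overflow
        step = max(min(step, 2.0), -2.0)
        beta += step
        if abs(step) < tol:
            break
        if abs(beta) > LOG_HR_BOUND and ridge == 0.0:
            return beta, info  # signal monotone likelihood to the caller
    _, info = _score_info(beta, *counts)
    return beta, info + 2.0 * ridge


def cox_fit_dataset(data: SurvivalDataset) -> tuple[float, float, bool, bool]:
    """Fit the two-unit Cox model; returns (log_hr, se, converged, penalized).

    Newton on the Breslow log partial likelihood; if the iteration exits
    [-LOG_HR_BOUND, LOG_HR_BOUND] the likelihood is monotone (the survival
    analogue of complete separation) and the model is refit with a weak
    ridge penalty on log_hr.
    """
    counts = _event_counts(data)
    d0, d1 = counts[0], counts[1]
    if sum(d1) == 0 or sum(d0) == 0:
        raise ScoringError("each unit must contribute at least one event")
    beta, info = _newton(counts, ridge=0.0)
    penalized = False
    if abs(beta) > LOG_HR_BOUND or info <= 0:
        beta, info = _newton(counts, ridge=RIDGE_LAMBDA)
        penalized = True
    converged = np.isfinite(beta) and info > 0
    se = float(1.0 / math.sqrt(info)) if converged else float("nan")
    return float(beta), se, converged, penalized


def cox_fit(
    data: SurvivalDataset,
    *,
    game: GameRecord | None = None,
    week_index: int | None = None,
) -> HazardRatioEstimate:
    """Estimate the hazard ratio of the assessment unit vs the reference.

    ``game`` supplies the identifying metadata carried on the estimate;
    when omitted, placeholder identifiers are used (handy in tests that
    work with raw datasets).
    """
    log_hr, se, converged, penalized = cox_fit_dataset(data)
    if game is None:
        level = max(
            sum(1 for r in data.records if r.unit is Unit.ASSESSMENT and r.status is Status.EVENT),
            1,
        )
        return HazardRatioEstimate(
            game_id="<dataset>",
            subject_id="<dataset>",
            assessment_type=AssessmentType.JEWELS_A,
            log_hr=log_hr,
            se=se,
            level=level,
            mistake_cat=MistakeCategory.NONE,
            week_index=week_index,
            converged=converged,
            penalized=penalized,
        )
    return HazardRatioEstimate(
        game_id=game.game_id,
        subject_id=game.subject_id,
        assessment_type=game.assessment_type,
        log_hr=log_hr,
        se=se,
        level=game.level,
        mistake_cat=game.mistake_cat,
        wall_time=game.wall_time,
        week_index=week_index,
        converged=converged,
        penalized=penalized,
    )


def score_all(
    games: list[GameRecord],
    references: dict[tuple[AssessmentType, int], ReferencePath],
    *,
    include_incomplete: bool = False,
    max_level: int | None = None,
) -> tuple[list[HazardRatioEstimate], list[str]]:
    """Score every completed game against its reference path.

    Returns (estimates, problems): games whose (type, level) has no
    reference, or whose fit fails, are reported in ``problems`` and never
    silently dropped.  Incomplete games are skipped unless
    ``include_incomplete`` (then censored at their last observed tap).
    """
    if not games:
        logger.warning("score_all called with no games")
    estimates: list[HazardRatioEstimate] = []
    problems: list[str] = []
    for g in games:
        if not g.completed and not include_incomplete:
            problems.append(f"{g.game_id}: incomplete game skipped")
            continue
        ref = references.get((g.assessment_type, g.level))
        if ref is None:
            problems.append(
                f"{g.game_id}: no reference for {g.assessment_type.value} level {g.level}"
            )
            continue
        try:
            data = encode_pair(
                g, ref.as_game(), max_level=max_level, censor_incomplete=include_incomplete
            )
            est = cox_fit(data, game=g)
        except (ScoringError, ValueError) as exc:
            problems.append(f"{g.game_id}: {exc}")
            continue
        logger.debug(
            "scored %s: log_hr=%.4f se=%.4f penalized=%s",
            g.game_id, est.log_hr, est.se, est.penalized,
        )
        estimates.append(est)
    return estimates, problems


def estimates_to_frame(estimates: list[HazardRatioEstimate]):
    import pandas as pd

    return pd.DataFrame(
        {
            "game_id": [e.game_id for e in estimates],
            "subject_id": [e.subject_id for e in estimates],
            "assessment_type": [e.assessment_type.value for e in estimates],
            "level": [e.level for e in estimates],
            "mistake_cat": [e.mistake_cat.value for e in estimates],
            "week_index": [e.week_index for e in estimates],
            "wall_time": [e.wall_time.isoformat() if e.wall_time else "" for e in estimates],
            "log_hr": [e.log_hr for e in estimates],
            "se": [e.se for e in estimates],
            "hr": [e.hr for e in estimates],
            "converged": [e.converged for e in estimates],
            "penalized": [e.penalized for e in estimates],
        }
    )
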