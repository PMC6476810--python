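"""End-to-end orchestration: events -> games -> references -> estimates
-> adjusted betas -> group comparison -> weekly correlations.

This is the glue the CLI, the examples and the simulation experiments
share; every step is a thin call into the stage modules.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import adjustment, analysis, scoring
from .adjustment import AdjustmentModel, BetaValue
from .analysis import GroupComparison
from .events import AssessmentType, GameRecord, TouchEvent, WeeklyStream, assemble_games
from .scoring import HazardRatioEstimate, ReferencePath
from .simulate import subject_group

__all__ = ["PipelineResult", "run_pipeline", "weekly_beta_streams"]

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class PipelineResult:
    games: list[GameRecord]
    references: dict[tuple[AssessmentType, int], ReferencePath]
    estimates: list[HazardRatioEstimate]
    problems: list[str]
    models: dict[AssessmentType, AdjustmentModel]
    study_betas: list[BetaValue]
    weekly_betas: list[BetaValue]
    comparisons: dict[AssessmentType, GroupComparison] = field(default_factory=dict)

    def study_beta_table(self) -> pd.DataFrame:
        return adjustment.betas_to_frame(self.study_betas)

    def weekly_beta_table(self) -> pd.DataFrame:
        return adjustment.betas_to_frame(self.weekly_betas)


def _modal_level(games: list[GameRecord], atype: AssessmentType) -> int | None:
    levels = [g.level for g in games if g.assessment_type is atype and g.completed]
    if not levels:
        return None
    return Counter(levels).most_common(1)[0][0]


def run_pipeline(
    events: list[TouchEvent],
    control_ids: set[str] | None = None,
    *,
    test: str = "welch",
    leave_one_out: bool = False,
    include_incomplete: bool = False,
) -> PipelineResult:
    """Run the full scoring pipeline on a touch-event log.

    ``control_ids`` names the control subjects whose games define the
    reference paths and the adjustment baseline level; when omitted it is
    inferred from the simulated id convention (C* control, P* patient).
    With ``leave_one_out`` each control is scored against references
    built from the other controls.
    """
    games = assemble_games(events)
    if control_ids is None:
        control_ids = {g.subject_id for g in games if subject_group(g.subject_id) == "control"}
    control_games = [g for g in games if g.subject_id in control_ids]

    references = scoring.build_reference_table(control_games)

    estimates: list[HazardRatioEstimate] = []
    problems: list[str] = []
    if leave_one_out:
        for sid in sorted({g.subject_id for g in games}):
            own = [g for g in games if g.subject_id == sid]
            refs = (
                scoring.build_reference_table(control_games, exclude_subject=sid)
                if sid in control_ids
                else references
            )
            est, prob = scoring.score_all(own, refs, include_incomplete=include_incomplete)
            estimates += est
            problems += prob
    else:
        estimates, problems = scoring.score_all(
            games, references, include_incomplete=include_incomplete
        )
    for p in problems:
        logger.warning("scoring: %s", p)

    estimates = adjustment.assign_week_indices(estimates)

    models: dict[AssessmentType, AdjustmentModel] = {}
    study_b: list[BetaValue] = []
    weekly_b: list[BetaValue] = []
    comparisons: dict[AssessmentType, GroupComparison] = {}
    for atype in AssessmentType:
        ests = [e for e in estimates if e.assessment_type is atype]
        if not ests:
            continue
        baseline = _modal_level(control_games, atype)
        model = adjustment.fit_adjustment(ests, baseline_level=baseline)
        models[atype] = model
        study_b += adjustment.study_betas(ests, model)
        weekly_b += adjustment.weekly_betas(ests, model)

        ctrl = [b.beta for b in study_b
                if b.assessment_type is atype and b.subject_id in control_ids]
        pat = [b.beta for b in study_b
               if b.assessment_type is atype and b.subject_id not in control_ids]
        if len(ctrl) >= 2 and len(pat) >= 2:
            comparisons[atype] = analysis.compare_groups(
                ctrl, pat, assessment_type=atype, test=test
            )

    return PipelineResult(
        games=games,
        references=references,
        estimates=estimates,
        problems=problems,
        models=models,
        study_betas=study_b,
        weekly_betas=weekly_b,
        comparisons=comparisons,
    )


def weekly_beta_streams(result: PipelineResult) -> list[WeeklyStream]:
    """Weekly betas reshaped as streams (beta_A / beta_B) so they can be
    correlated with step counts and survey scores."""
    by_key: dict[tuple[str, int], WeeklyStream] = {}
    name = {AssessmentType.JEWELS_A: "beta_A", AssessmentType.JEWELS_B: "beta_B"}
    for b in result.weekly_betas:
        if b.window.week is None:
            continue
        key = (b.subject_id, b.window.week)
        ws = by_key.setdefault(key, WeeklyStream(subject_id=key[0], week_index=key[1]))
        ws.values[name[b.assessment_type]] = b.beta
    return list(by_key.values())
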