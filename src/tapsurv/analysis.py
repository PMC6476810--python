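"""Group comparison of beta values and weekly cross-stream correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import AssessmentType, WeeklyStream

__all__ = [
    "GroupComparison",
    "CorrelationMatrix",
    "compare_groups",
    "weekly_correlations",
]

#: minimum number of jointly observed weeks for a correlation cell
MIN_OVERLAP = 3


@dataclass(frozen=True, slots=True)
class GroupComparison:
    """Two-sample comparison of study-wide betas between groups."""

    assessment_type: AssessmentType | None
    mean_control: float
    mean_patient: float
    statistic: float
    p_value: float
    n_control: int
    n_patient: int
    test: str = "welch"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations across weekly streams of one
    subject, with the per-cell number of jointly observed weeks.

    Cells with fewer than MIN_OVERLAP overlapping weeks are NaN (missing,
    not zero).
    """

    subject_id: str
    streams: tuple[str, ...]
    corr: pd.DataFrame
    n: pd.DataFrame


def compare_groups(
    betas_control: list[float],
    betas_patient: list[float],
    *,
    assessment_type: AssessmentType | None = None,
    test: str = "welch",
) -> GroupComparison:
    """Two-sided two-sample location test on study-wide beta values.

    Welch's unequal-variance t-test by default; ``test="ranksum"``
    switches to the Mann-Whitney U test.  Requires at least two betas per
    group.
    """
    a = np.asarray(betas_control, dtype=float)
    b = np.asarray(betas_patient, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two beta values in each group")
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        assessment_type=assessment_type,
        mean_control=float(a.mean()),
        mean_patient=float(b.mean()),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_control=int(a.size),
        n_patient=int(b.size),
        test=test,
    )


def weekly_correlations(
    streams: list[WeeklyStream],
    subject_id: str,
    *,
    min_overlap: int = MIN_OVERLAP,
) -> CorrelationMatrix:
    """Cross-stream correlation matrix over one subject's study weeks.

    Pearson correlation on weekly values, pairwise-complete: each cell
    uses the weeks where both streams are observed, and is missing (NaN)
    when fewer than ``min_overlap`` such weeks exist.  The matrix is
    symmetric with unit diagonal wherever a stream has enough data.
    """
    rows = [s for s in streams if s.subject_id == subject_id]
    if not rows:
        raise ValueError(f"no weekly streams for subject {subject_id!r}")
    # a week's streams may arrive in several records (e.g. sensor streams
    # and derived betas): merge them into one row per week
    by_week: dict[int, dict[str, float]] = {}
    for s in rows:
        week = by_week.setdefault(s.week_index, {})
        for name, value in s.values.items():
            if name in week and week[name] != value:
                raise ValueError(
                    f"conflicting values for stream {name!r} in week "
                    f"{s.week_index} of subject {subject_id!r}"
                )
            week[name] = value
    wide = (
        pd.DataFrame.from_dict(by_week, orient="index")
        .rename_axis("week_index")
        .sort_index()
    )
    names = tuple(wide.columns)
    if len(names) < 2:
        raise ValueError("need at least two streams to correlate")
    observed = wide.notna().astype(int)
    n = observed.T @ observed
    corr = wide.corr(method="pearson", min_periods=min_overlap)
    corr = corr.where(n >= min_overlap)
    # unit diagonal by construction wherever the stream has enough weeks
    # (pandas leaves NaN there for zero-variance streams)
    for name in names:
        if n.loc[name, name] >= min_overlap:
            corr.loc[name, name] = 1.0
    return CorrelationMatrix(subject_id=subject_id, streams=names, corr=corr, n=n)
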