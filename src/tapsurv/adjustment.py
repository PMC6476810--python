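"""Level adjustment and per-subject aggregation into beta values.

Raw log hazard ratios are not directly comparable across games played at
different difficulty levels (or with different mistake counts), so they
are first adjusted with a linear mixed model

    log_hr_ij = intercept + slope * level_ij + mistake effects
                + b_i + e_ij,      b_i ~ N(0, tau^2),
                e_ij ~ N(0, sigma^2 * se_ij^2),

with a random intercept per subject and residuals weighted by the Cox
standard errors (1/se^2 observation weights).  Each estimate is then
translated to a common baseline level and zero-mistake category, and a
subject's adjusted values within a window are pooled by inverse-variance
weighting into a single "beta value":

    beta = sum(w_i v_i) / sum(w_i),  w_i = 1/se_i^2,  Var(beta) = 1/sum(w_i).

Variance components are estimated by REML (profiled generalized least
squares for the fixed effects, 2-D optimization over the variance
parameters); when the random intercept is inestimable — e.g. all
estimates come from one subject — the fit falls back to weighted least
squares with tau = 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import optimize

from .events import AssessmentType, MistakeCategory
from .scoring import HazardRatioEstimate

__all__ = [
    "AdjustmentModel",
    "BetaValue",
    "Window",
    "fit_adjustment",
    "adjust",
    "beta_value",
    "weekly_betas",
    "study_betas",
    "assign_week_indices",
    "betas_to_frame",
]

logger = logging.getLogger(__name__)

STUDY_WIDE = "STUDY_WIDE"


@dataclass(frozen=True, slots=True)
class Window:
    """Aggregation window: the whole study or a single week."""

    kind: str  # STUDY_WIDE or WEEK
    week: int | None = None

    @classmethod
    def study_wide(cls) -> "Window":
        return cls(kind=STUDY_WIDE)

    @classmethod
    def week_of(cls, k: int) -> "Window":
        return cls(kind="WEEK", week=k)

    def __str__(self) -> str:
        return self.kind if self.kind == STUDY_WIDE else f"WEEK_{self.week}"


@dataclass(frozen=True, slots=True)
class AdjustmentModel:
    intercept: float
    level_slope: float
    mistake_effects: dict[MistakeCategory, float]
    random_intercept_sd: float
    residual_sd: float
    baseline_level: int
    n_obs: int = 0
    reml_converged: bool = True

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True, slots=True)
class BetaValue:
    subject_id: str
    assessment_type: AssessmentType
    window: Window
    beta: float
    variance: float
    n_games: int

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("beta variance must be positive")
        if self.n_games < 1:
            raise ValueError("beta must summarize at least one game")


def _design(estimates: list[HazardRatioEstimate], baseline_level: int):
    """Design matrix: intercept, centered level, mistake dummies."""
    lev = np.array([e.level - baseline_level for e in estimates], dtype=float)
    one = np.array([e.mistake_cat is MistakeCategory.ONE for e in estimates], dtype=float)
    more = np.array(
        [e.mistake_cat is MistakeCategory.MORE_THAN_ONE for e in estimates], dtype=float
    )
    X = np.column_stack([np.ones(len(estimates)), lev, one, more])
    # drop columns with no contrast so the GLS solve stays full-rank
    keep = [0] + [j for j in (1, 2, 3) if np.ptp(X[:, j]) > 0]
    return X[:, keep], keep


def _reml_fit(y, X, se2, groups):
    """REML for y = X b + Z u + e, Var(e)=sigma2*se2, Var(u)=tau2 I.

    Per-subject Woodbury identities (V_s^-1 = diag(a) - f a a' with
    a = 1/(sigma2 se2), f = tau2/(1 + tau2 sum(a))) keep every REML
    evaluation O(n).  Returns (coef, tau2, sigma2, converged).
    """
    n, p = X.shape
    codes = _group_codes(groups)
    k = codes.max() + 1

    def _bincount_cols(M, w):
        return np.column_stack([np.bincount(codes, w * M[:, j], minlength=k)
                                for j in range(M.shape[1])])

    def gls(tau2, sigma2):
        """Return (coef, XtViX, log|V|, resid' V^-1 resid)."""
        v = sigma2 * se2
        a = 1.0 / v
        c = np.bincount(codes, a, minlength=k)
        f = tau2 / (1.0 + tau2 * c)
        S = _bincount_cols(X, a)          # per-subject sums of a*X
        sy = np.bincount(codes, a * y, minlength=k)
        XtViX = (X.T * a) @ X - (S.T * f) @ S
        XtViy = X.T @ (a * y) - S.T @ (f * sy)
        coef = np.linalg.solve(XtViX, XtViy)
        r = y - X @ coef
        sr = np.bincount(codes, a * r, minlength=k)
        quad = float(r @ (a * r) - f @ sr**2)
        logdet = float(np.log(v).sum() + np.log1p(tau2 * c).sum())
        return coef, XtViX, logdet, quad

    def neg_reml(theta):
        tau2, sigma2 = np.exp(theta)
        try:
            coef, XtViX, logdet, quad = gls(tau2, sigma2)
        except np.linalg.LinAlgError:
            return 1e12
        sign, ld2 = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        return 0.5 * (logdet + ld2 + quad)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            neg_reml,
            x0=np.log([0.1, 1.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 600},
        )
    tau2, sigma2 = np.exp(res.x)
    coef, *_ = gls(tau2, sigma2)
    return coef, float(tau2), float(sigma2), bool(res.success)


def _group_codes(groups) -> np.ndarray:
    """Integer codes for group labels, first-appearance order."""
    uniq: dict = {}
    return np.array([uniq.setdefault(g, len(uniq)) for g in groups])


def fit_adjustment(
    estimates: list[HazardRatioEstimate],
    *,
    baseline_level: int | None = None,
) -> AdjustmentModel:
    """Fit the level/mistake adjustment mixed model to Cox estimates.

    ``baseline_level`` defaults to the modal level among the estimates;
    in the full pipeline the caller passes the modal level of the control
    games so all subjects are translated to the controls' most common
    difficulty.  With fewer than two distinct levels the slope is fixed
    at 0; with a single subject the random intercept is dropped and a
    weighted least-squares fit is used.
    """
    est = [e for e in estimates if e.converged and np.isfinite(e.log_hr)]
    if not est:
        raise ValueError("no converged estimates to fit the adjustment model")
    if baseline_level is None:
        baseline_level = Counter(e.level for e in est).most_common(1)[0][0]

    y = np.array([e.log_hr for e in est])
    se2 = np.array([e.se**2 for e in est])
    groups = [e.subject_id for e in est]
    n_levels = len({e.level for e in est})
    if n_levels < 2:
        logger.warning("single difficulty level present; level slope fixed to 0")

    X, keep = _design(est, baseline_level)
    n_subjects = len(set(groups))

    if n_subjects < 2:
        logger.warning("all estimates from one subject; falling back to WLS without random intercept")
        wls = sm.WLS(y, X, weights=1.0 / se2).fit()
        coef = wls.params
        sigma2 = float(wls.scale)
        tau2, converged = 0.0, True
    else:
        coef, tau2, sigma2, converged = _reml_fit(y, X, se2, groups)

    full = np.zeros(4)
    full[keep] = coef
    return AdjustmentModel(
        intercept=float(full[0]),
        level_slope=float(full[1]),
        mistake_effects={
            MistakeCategory.NONE: 0.0,
            MistakeCategory.ONE: float(full[2]),
            MistakeCategory.MORE_THAN_ONE: float(full[3]),
        },
        random_intercept_sd=float(math.sqrt(max(tau2, 0.0))),
        residual_sd=float(math.sqrt(max(sigma2, 0.0))),
        baseline_level=baseline_level,
        n_obs=len(est),
        reml_converged=converged,
    )


def adjust(estimate: HazardRatioEstimate, model: AdjustmentModel) -> float:
    """Translate a log HR to the baseline level and zero-mistake category."""
    return (
        estimate.log_hr
        - model.level_slope * (estimate.level - model.baseline_level)
        - model.mistake_effects.get(estimate.mistake_cat, 0.0)
    )


def beta_value(
    adjusted: list[tuple[float, float]],
    *,
    subject_id: str = "",
    assessment_type: AssessmentType = AssessmentType.JEWELS_A,
    window: Window | None = None,
) -> BetaValue | None:
    """Inverse-variance-weighted pooled value of (value, se) pairs.

    Returns None for an empty window — a missing value, never zero.
    """
    if not adjusted:
        return None
    vals = np.array([v for v, _ in adjusted], dtype=float)
    ses = np.array([s for _, s in adjusted], dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(~np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("beta_value requires finite values and positive finite ses")
    w = 1.0 / ses**2
    return BetaValue(
        subject_id=subject_id,
        assessment_type=assessment_type,
        window=window or Window.study_wide(),
        beta=float(np.sum(w * vals) / np.sum(w)),
        variance=float(1.0 / np.sum(w)),
        n_games=len(adjusted),
    )


def assign_week_indices(estimates: list[HazardRatioEstimate]) -> list[HazardRatioEstimate]:
    """Bin each subject's games into 7-day windows from their first game.

    Week 1 covers days [0, 7) after the subject's first observed game,
    week 2 days [7, 14), and so on — windows anchored at each subject's
    own baseline, not the calendar.  Estimates without a wall time keep
    ``week_index=None``.
    """
    first: dict[str, "object"] = {}
    for e in estimates:
        if e.wall_time is not None:
            t0 = first.get(e.subject_id)
            if t0 is None or e.wall_time < t0:
                first[e.subject_id] = e.wall_time
    out = []
    for e in estimates:
        if e.wall_time is None or e.subject_id not in first:
            out.append(e)
        else:
            days = (e.wall_time - first[e.subject_id]).total_seconds() / 86400.0
            out.append(replace(e, week_index=int(days // 7) + 1))
    return out


def _grouped_betas(
    estimates: list[HazardRatioEstimate],
    model: AdjustmentModel,
    key_fn,
    window_fn,
) -> list[BetaValue]:
    groups: dict = {}
    for e in estimates:
        if not e.converged:
            continue
        groups.setdefault(key_fn(e), []).append(e)
    betas = []
    for key in sorted(groups, key=str):
        ests = groups[key]
        pooled = beta_value(
            [(adjust(e, model), e.se) for e in ests],
            subject_id=ests[0].subject_id,
            assessment_type=ests[0].assessment_type,
            window=window_fn(key),
        )
        if pooled is not None:
            betas.append(pooled)
    return betas


def study_betas(
    estimates: list[HazardRatioEstimate], model: AdjustmentModel
) -> list[BetaValue]:
    """One study-wide beta per (subject, assessment type)."""
    return _grouped_betas(
        estimates,
        model,
        key_fn=lambda e: (e.subject_id, e.assessment_type),
        window_fn=lambda k: Window.study_wide(),
    )


def weekly_betas(
    estimates: list[HazardRatioEstimate], model: AdjustmentModel
) -> list[BetaValue]:
    """One beta per (subject, assessment type, week window).

    Estimates must carry week indices (see :func:`assign_week_indices`);
    the study-wide adjustment model is reused across weeks rather than
    refit per week.  Weeks with no games simply have no entry.
    """
    est = [e for e in estimates if e.week_index is not None]
    return _grouped_betas(
        est,
        model,
        key_fn=lambda e: (e.subject_id, e.assessment_type, e.week_index),
        window_fn=lambda k: Window.week_of(k[2]),
    )


def betas_to_frame(betas: list[BetaValue]):
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [b.subject_id for b in betas],
            "assessment_type": [b.assessment_type.value for b in betas],
            "window": [str(b.window) for b in betas],
            "beta": [b.beta for b in betas],
            "variance": [b.variance for b in betas],
            "n_games": [b.n_games for b in betas],
        }
    )
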