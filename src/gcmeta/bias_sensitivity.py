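"""Leave-one-out sensitivity analysis, funnel-plot data, and Egger's test.

Sensitivity: the pool is recomputed k times, each time omitting one study
and re-applying the full fixed/random selection rule to the remaining
k-1 studies, so an influential study shows up as a shifted pooled OR or a
CI that crosses 1.

Publication bias: the funnel plot scatters each study's OR against the
standard error of its log OR; Egger's regression makes the asymmetry check
formal by regressing the standardized effect z_i = theta_i / se_i on the
precision 1/se_i (unweighted OLS) and t-testing the intercept on k-2
degrees of freedom — small-study effects push the intercept away from 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import t as t_dist

from .dataset import StudyTable
from .effects import Correction, EffectEstimate, study_effects, Z_975
from .errors import InsufficientStudiesError, ValidationError
from .meta import PooledResult, pool_auto

__all__ = [
    "LeaveOneOutEntry",
    "FunnelPoint",
    "FunnelData",
    "EggerResult",
    "leave_one_out",
    "funnel_points",
    "egger_test",
]


@dataclass(frozen=True)
class LeaveOneOutEntry:
    omitted_study_id: str
    pooled: PooledResult


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    x: float   # OR or log OR, per scale
    y: float   # SE of log OR


@dataclass(frozen=True)
class FunnelData:
    """Plot-ready funnel content: points, pooled reference, 95% wedge."""

    points: tuple[FunnelPoint, ...]
    scale: Literal["or", "log_or"]
    reference: float                    # pooled effect on the chosen scale
    boundary_se: tuple[float, ...]      # grid of y values, 0 .. max se
    boundary_low: tuple[float, ...]     # reference -/+ 1.959964 * se, on scale
    boundary_high: tuple[float, ...]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    t: float
    df: int
    p: float
    slope: float
    significant: bool


def leave_one_out(
    table: StudyTable,
    correction: Correction = "add_half_if_zero",
    alpha: float = 0.05,
    p_threshold: float = 0.1,
    i2_threshold: float = 50.0,
) -> list[LeaveOneOutEntry]:
    """Re-pool k times, omitting each study in turn (input order kept)."""
    if table.k < 3:
        raise InsufficientStudiesError(f"leave-one-out needs at least 3 studies, got {table.k}")
    entries = []
    for study in table:
        reduced = table.drop(study.study_id)
        effects = study_effects(reduced, correction=correction, alpha=alpha)
        pooled = pool_auto(effects, alpha=alpha, p_threshold=p_threshold, i2_threshold=i2_threshold)
        entries.append(LeaveOneOutEntry(omitted_study_id=study.study_id, pooled=pooled))
    return entries


def funnel_points(
    effects: Sequence[EffectEstimate],
    scale: Literal["or", "log_or"] = "or",
    n_grid: int = 50,
) -> FunnelData:
    """Funnel coordinates plus the pooled reference line and pseudo-95%
    wedge (pooled log OR +/- 1.959964 * se over an se grid)."""
    if len(effects) < 1:
        raise InsufficientStudiesError("funnel_points needs at least one study")
    if scale not in ("or", "log_or"):
        raise ValidationError(f"unknown funnel scale {scale!r}")
    to_scale = math.exp if scale == "or" else (lambda v: v)
    points = tuple(
        FunnelPoint(study_id=e.study_id, x=to_scale(e.log_or), y=e.se) for e in effects
    )
    if len(effects) >= 2:
        pooled_log = pool_auto(effects).log_or
    else:
        pooled_log = effects[0].log_or
    se_grid = tuple(np.linspace(0.0, max(e.se for e in effects), n_grid).tolist())
    low = tuple(to_scale(pooled_log - Z_975 * s) for s in se_grid)
    high = tuple(to_scale(pooled_log + Z_975 * s) for s in se_grid)
    return FunnelData(
        points=points,
        scale=scale,
        reference=to_scale(pooled_log),
        boundary_se=se_grid,
        boundary_low=low,
        boundary_high=high,
    )


def egger_test(
    effects: Sequence[EffectEstimate],
    alpha: float = 0.01,
    weighted: bool = False,
) -> EggerResult:
    """Egger regression test for funnel asymmetry (precision form).

    Unweighted OLS of z_i = theta_i/se_i on x_i = 1/se_i; the intercept is
    the bias term, tested two-sided against Student t with k-2 df.  The
    ``weighted`` flag switches to WLS with weights 1/se_i^2, a common
    variant; the default reproduces the classic test.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"egger_test needs at least 3 studies, got {k}")
    se = np.array([e.se for e in effects])
    theta = np.array([e.log_or for e in effects])
    x = 1.0 / se
    z = theta / se
    w = x**2 if weighted else np.ones(k)
    # weighted least squares via the normal equations on sqrt(w)-scaled data
    sw = np.sqrt(w)
    design = np.column_stack([sw, sw * x])
    response = sw * z
    xtx = design.T @ design
    if np.linalg.matrix_rank(xtx) < 2:
        raise ValidationError("degenerate Egger regression: no spread in precision")
    beta = np.linalg.solve(xtx, design.T @ response)
    resid = response - design @ beta
    df = k - 2
    sigma2 = float(resid @ resid) / df
    # an exact linear fit leaves only rounding noise in the residuals
    scale = max(1.0, float(response @ response))
    if sigma2 < (1e-12) ** 2 * scale:
        sigma2 = 0.0
        beta = np.where(np.abs(beta) < 1e-10 * math.sqrt(scale), 0.0, beta)
    cov = sigma2 * np.linalg.inv(xtx)
    se_int = math.sqrt(max(cov[0, 0], 0.0))
    intercept = float(beta[0])
    if se_int == 0.0:
        # exact linear fit: no residual variance; a (numerically) zero
        # intercept is exactly unbiased, anything else is infinitely far
        t_stat = 0.0 if abs(intercept) < 1e-10 else math.copysign(math.inf, intercept)
        p = 1.0 if t_stat == 0.0 else 0.0
    else:
        t_stat = intercept / se_int
        p = float(2 * t_dist.sf(abs(t_stat), df=df))
    return EggerResult(
        intercept=intercept,
        se_intercept=se_int,
        t=t_stat,
        df=df,
        p=p,
        slope=float(beta[1]),
        significant=p < alpha,
    )
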