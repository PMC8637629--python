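"""Heterogeneity assessment, model selection, and inverse-variance pooling.

With per-study log odds ratios theta_i and Woolf standard errors se_i the
fixed-effect weights are w_i = 1/se_i^2 and

    theta_hat = sum(w_i theta_i) / sum(w_i),      SE = 1/sqrt(sum w_i)
    Q         = sum w_i (theta_i - theta_hat)^2   ~ chi2_{k-1} under
                                                    homogeneity
    I^2       = max(0, (Q - (k-1)) / Q) * 100
    tau^2_DL  = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i))

The random-effects (DerSimonian-Laird) pool replaces w_i with
1/(se_i^2 + tau^2).  The selection rule is the conjunction used in the
genetic-epidemiology literature this package serves: random effects if and
only if the Q-test p-value is below 0.1 AND I^2 exceeds 50%; otherwise
fixed effect.  The pooled association is judged with a two-sided Z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .dataset import StudyTable
from .effects import AlleleTable2x2, EffectEstimate, allele_table, z_quantile
from .errors import InsufficientStudiesError, ValidationError

Model = Literal["fixed", "random"]


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p_q: float
    i2: float          # percent, floored at 0
    tau2: float        # DerSimonian-Laird between-study variance


@dataclass(frozen=True)
class PooledResult:
    model: Model
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    weights: dict[str, float]          # normalized, sum to 1
    heterogeneity: HeterogeneityResult | None


def _check_effects(effects: Sequence[EffectEstimate], k_min: int, what: str) -> None:
    if len(effects) < k_min:
        raise InsufficientStudiesError(f"{what} needs at least {k_min} studies, got {len(effects)}")
    for e in effects:
        if e.se <= 0:
            raise ValidationError(f"study {e.study_id!r}: non-positive standard error")


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q, its chi-squared p-value, I2 (percent) and DL tau2."""
    _check_effects(effects, 2, "heterogeneity")
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(effects) - 1
    p_q = float(chi2_dist.sf(q, df=df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def _pool(
    effects: Sequence[EffectEstimate],
    weights: np.ndarray,
    model: Model,
    alpha: float,
    het: HeterogeneityResult | None,
) -> PooledResult:
    theta = np.array([e.log_or for e in effects])
    w_sum = float(np.sum(weights))
    log_or = float(np.sum(weights * theta) / w_sum)
    se = 1.0 / math.sqrt(w_sum)
    zc = z_quantile(alpha)
    z = log_or / se
    # two-sided normal tail via erfc for full precision in the far tail;
    # clamped to the smallest positive float so p stays strictly positive
    # when erfc underflows (|z| > ~38)
    p = math.erfc(abs(z) / math.sqrt(2)) or 5e-324
    return PooledResult(
        model=model,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - zc * se),
        ci_high=math.exp(log_or + zc * se),
        z=z,
        p=p,
        weights={e.study_id: float(wi / w_sum) for e, wi in zip(effects, weights)},
        heterogeneity=het,
    )


def pool_fixed(effects: Sequence[EffectEstimate], alpha: float = 0.05) -> PooledResult:
    """Fixed-effect inverse-variance pool of per-study log odds ratios."""
    _check_effects(effects, 1, "pool_fixed")
    het = heterogeneity(effects) if len(effects) >= 2 else None
    w = np.array([1.0 / e.se**2 for e in effects])
    return _pool(effects, w, "fixed", alpha, het)


def pool_random(effects: Sequence[EffectEstimate], alpha: float = 0.05) -> PooledResult:
    """DerSimonian-Laird random-effects pool.

    Collapses to the fixed-effect pool whenever tau2 = 0 (i.e. Q <= k-1).
    """
    _check_effects(effects, 2, "pool_random")
    het = heterogeneity(effects)
    w = np.array([1.0 / (e.se**2 + het.tau2) for e in effects])
    return _pool(effects, w, "random", alpha, het)


def select_model(
    het: HeterogeneityResult,
    p_threshold: float = 0.1,
    i2_threshold: float = 50.0,
) -> Model:
    """Random effects iff p_Q < 0.1 AND I2 > 50% (strict conjunction)."""
    return "random" if (het.p_q < p_threshold and het.i2 > i2_threshold) else "fixed"


def pool_auto(
    effects: Sequence[EffectEstimate],
    alpha: float = 0.05,
    p_threshold: float = 0.1,
    i2_threshold: float = 50.0,
) -> PooledResult:
    """Pool under the model picked by :func:`select_model`."""
    _check_effects(effects, 1, "pool_auto")
    if len(effects) == 1:
        return pool_fixed(effects, alpha=alpha)
    het = heterogeneity(effects)
    if select_model(het, p_threshold, i2_threshold) == "random":
        return pool_random(effects, alpha=alpha)
    return pool_fixed(effects, alpha=alpha)


def pool_mantel_haenszel(table: StudyTable, alpha: float = 0.05) -> PooledResult:
    """Mantel-Haenszel pooled allele-model OR (cross-check estimator).

    Stratum-summed MH point estimate with the Robins-Breslow-Greenland
    variance for log OR_MH.  Provided as an independent check on the
    inverse-variance pool; it is not the pipeline default.
    """
    tables = [allele_table(s) for s in table]
    return _mantel_haenszel(tables, alpha)


def _mantel_haenszel(tables: Sequence[AlleleTable2x2], alpha: float) -> PooledResult:
    r_sum = s_sum = 0.0
    p_r = p_s_plus_q_r = q_s = 0.0
    s_by_id: dict[str, float] = {}
    for t in tables:
        a, b, c, d = t.case_t, t.case_c, t.control_t, t.control_c
        n = a + b + c + d
        r, s = a * d / n, b * c / n
        p_, q_ = (a + d) / n, (b + c) / n
        r_sum += r
        s_sum += s
        s_by_id[t.study_id] = s
        p_r += p_ * r
        p_s_plus_q_r += p_ * s + q_ * r
        q_s += q_ * s
    if r_sum <= 0 or s_sum <= 0:
        raise ValidationError("Mantel-Haenszel estimator undefined: zero stratum sums")
    log_or = math.log(r_sum / s_sum)
    var = p_r / (2 * r_sum**2) + p_s_plus_q_r / (2 * r_sum * s_sum) + q_s / (2 * s_sum**2)
    se = math.sqrt(var)
    zc = z_quantile(alpha)
    z = log_or / se
    return PooledResult(
        model="fixed",
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - zc * se),
        ci_high=math.exp(log_or + zc * se),
        z=z,
        p=math.erfc(abs(z) / math.sqrt(2)) or 5e-324,
        # MH OR is the s_i-weighted mean of per-study ORs
        weights={sid: s / s_sum for sid, s in s_by_id.items()},
        heterogeneity=None,
    )
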