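"""Per-study allele-model odds ratios.

Under the additive (allele) genetic model each individual contributes two
alleles, so a study's genotype counts collapse to a 2x2 allele table:
effect (T) vs reference (C) allele counts in cases and controls.  The
log odds ratio and its Woolf standard error

    log OR = ln( (case_T * control_C) / (case_C * control_T) )
    SE     = sqrt( 1/case_T + 1/case_C + 1/control_T + 1/control_C )

are the per-study inputs to pooling.  A Haldane-Anscombe continuity
correction (add 0.5 to every cell if and only if any cell is zero) keeps
the estimate finite on sparse tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.stats import norm

from .dataset import StudyRecord, StudyTable
from .errors import DegenerateTableError, ValidationError

#: Normal 0.975 quantile, fixed for exact reproducibility of 95% intervals.
Z_975 = 1.959964

Correction = Literal["none", "add_half_if_zero"]


def z_quantile(alpha: float) -> float:
    """Two-sided normal critical value; hard-wired at the default level."""
    if alpha == 0.05:
        return Z_975
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    return float(norm.ppf(1 - alpha / 2))


@dataclass(frozen=True)
class AlleleTable2x2:
    """Allele counts for one study: T vs C in cases and controls."""

    study_id: str
    case_t: float
    case_c: float
    control_t: float
    control_c: float

    def cells(self) -> tuple[float, float, float, float]:
        return (self.case_t, self.case_c, self.control_t, self.control_c)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with Woolf standard error and CI."""

    study_id: str
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    corrected: bool = False


def allele_table(study: StudyRecord) -> AlleleTable2x2:
    """Collapse genotype counts to the T-vs-C allele 2x2 table."""
    return AlleleTable2x2(
        study_id=study.study_id,
        case_t=study.case.effect_allele_count,
        case_c=study.case.reference_allele_count,
        control_t=study.control.effect_allele_count,
        control_c=study.control.reference_allele_count,
    )


def odds_ratio(
    table: AlleleTable2x2,
    correction: Correction = "add_half_if_zero",
    alpha: float = 0.05,
) -> EffectEstimate:
    """Allele-model odds ratio with Woolf SE and (1-alpha) CI.

    With ``correction="add_half_if_zero"`` (the default used by the
    pipeline) 0.5 is added to *all four* cells if and only if at least one
    cell is zero; the estimate is then flagged ``corrected``.  With
    ``correction="none"`` a zero cell raises :class:`DegenerateTableError`.
    """
    a, b, c, d = table.cells()
    if a + b <= 0 or c + d <= 0:
        raise ValidationError(f"study {table.study_id!r}: an arm has zero alleles")
    corrected = False
    if min(a, b, c, d) == 0:
        if correction == "none":
            raise DegenerateTableError(
                f"study {table.study_id!r}: zero cell in allele table and no correction"
            )
        if correction != "add_half_if_zero":
            raise ValidationError(f"unknown correction {correction!r}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = z_quantile(alpha)
    return EffectEstimate(
        study_id=table.study_id,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        corrected=corrected,
    )


def study_effects(
    table: StudyTable,
    correction: Correction = "add_half_if_zero",
    alpha: float = 0.05,
) -> list[EffectEstimate]:
    """Per-study effect estimates for a whole table, in table order."""
    return [odds_ratio(allele_table(s), correction=correction, alpha=alpha) for s in table]
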