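"""Hardy-Weinberg equilibrium screening of control genotype counts.

Deviation from HWE in the control arm of a case-control study is a
standard genotyping-quality flag.  The default test is the plain Pearson
chi-squared goodness-of-fit on the three genotype classes against the
expected proportions ((1-q)^2, 2q(1-q), q^2) at the estimated effect-allele
frequency q, referred to a chi-squared distribution with 1 degree of
freedom (3 classes minus 1 minus 1 estimated parameter).  An exact
conditional test (enumeration of heterozygote counts given the allele
counts) is available as an alternative method for small or sparse arms.

Studies failing the screen are flagged, never dropped: the screen informs
the analyst, exclusion is an analyst decision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

from scipy.stats import chi2 as chi2_dist

from .dataset import GenotypeCounts, StudyTable

Method = Literal["pearson", "exact"]

#: Screen threshold: a control arm fails the screen when p < 0.001.
DEFAULT_THRESHOLD = 0.001


@dataclass(frozen=True)
class HweResult:
    study_id: str
    chi2: float
    p: float
    effect_allele_freq: float
    passes: bool
    method: Method = "pearson"


def _pearson(arm: GenotypeCounts) -> tuple[float, float, float]:
    n = arm.total
    q = arm.effect_allele_count / (2 * n)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q * q)
    observed = (arm.cc, arm.ct, arm.tt)
    chi2 = 0.0
    for obs, exp in zip(observed, expected):
        if exp == 0.0:
            # q = 0 or 1: the empty class is expected empty; observed is
            # forced to 0 too by the allele-frequency estimate.
            continue
        chi2 += (obs - exp) ** 2 / exp
    p = float(chi2_dist.sf(chi2, df=1))
    return chi2, p, q


def exact_hwe_p(arm: GenotypeCounts) -> float:
    """Exact conditional HWE p-value (sum of heterozygote-count
    probabilities no larger than the observed one, given allele counts)."""
    n = arm.total
    n_t = arm.effect_allele_count  # rarer-or-not, handled symmetrically below
    n_c = 2 * n - n_t
    rare = min(n_t, n_c)
    het_obs = arm.ct
    # log P(ct = h | allele counts) up to a shared constant
    def log_weight(h: int) -> float:
        tt = (rare - h) // 2
        cc = n - tt - h
        return (
            h * math.log(2)
            - math.lgamma(cc + 1)
            - math.lgamma(h + 1)
            - math.lgamma(tt + 1)
        )

    hets = [h for h in range(rare % 2, rare + 1, 2)]
    logs = [log_weight(h) for h in hets]
    m = max(logs)
    probs = [math.exp(lw - m) for lw in logs]
    total = sum(probs)
    p_obs = probs[hets.index(het_obs)]
    p = sum(pr for pr in probs if pr <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_chisq(
    arm: GenotypeCounts,
    threshold: float = DEFAULT_THRESHOLD,
    study_id: str = "",
    method: Method = "pearson",
) -> HweResult:
    """HWE test of one arm; ``passes`` is True when p >= threshold."""
    chi2, p, q = _pearson(arm)
    if method == "exact":
        p = exact_hwe_p(arm)
    elif method != "pearson":
        raise ValueError(f"unknown HWE method {method!r}")
    return HweResult(
        study_id=study_id,
        chi2=chi2,
        p=p,
        effect_allele_freq=q,
        passes=p >= threshold,
        method=method,
    )


def screen_controls(
    table: StudyTable,
    threshold: float = DEFAULT_THRESHOLD,
    method: Method = "pearson",
) -> list[HweResult]:
    """Screen every control arm; warn (never exclude) on failures."""
    results = [
        hwe_chisq(s.control, threshold=threshold, study_id=s.study_id, method=method)
        for s in table
    ]
    for r in results:
        if not r.passes:
            warnings.warn(
                f"study {r.study_id!r}: control arm deviates from "
                f"Hardy-Weinberg equilibrium (p = {r.p:.3g} < {threshold}); "
                "flagged, not excluded",
                UserWarning,
                stacklevel=2,
            )
    return results
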