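"""Case-control genotype-count simulator with known truth.

Controls are drawn multinomially from Hardy-Weinberg proportions at the
effect-allele frequency q; cases from the tilted distribution

    p_g  proportional to  HWE_g(q) * psi^g,   g in {0, 1, 2}

so psi is the true per-allele (additive) odds ratio: the allele-level
case/control odds ratio converges to psi as arm sizes grow.  Between-study
heterogeneity enters through a log-normal per-study effect,
log psi_i ~ Normal(log psi, tau^2), matching the DerSimonian-Laird model
the pooling stage assumes.

Every draw is driven by a single integer seed through per-study
``SeedSequence`` substreams keyed on (replicate, study index), so a study's
counts do not depend on how many other studies the table holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import GenotypeCounts, StudyRecord, StudyTable
from .effects import study_effects
from .errors import ValidationError
from .meta import pool_auto


@dataclass(frozen=True)
class SimStudySpec:
    """Design of one simulated study."""

    n_case: int
    n_control: int
    q: float      # control effect-allele frequency
    psi: float    # true per-allele odds ratio

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("arm sizes must be >= 1")
        if not 0.0 < self.q < 1.0:
            raise ValidationError(f"q must be in (0, 1), got {self.q}")
        if self.psi <= 0:
            raise ValidationError(f"psi must be > 0, got {self.psi}")


@dataclass(frozen=True)
class SimConfig:
    """A k-study design plus heterogeneity level and seed."""

    specs: tuple[SimStudySpec, ...]
    tau: float = 0.0    # between-study sd of log psi
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.specs) < 1:
            raise ValidationError("need at least one study spec")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Sidecar recording the generative parameters of a simulated table."""

    psi: tuple[float, ...]    # realized per-study odds ratios
    q: tuple[float, ...]
    tau: float
    seed: int


@dataclass(frozen=True)
class RejectionRate:
    rate: float
    ci_low: float
    ci_high: float
    rejections: int
    reps: int


def _hwe_probs(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def _case_probs(q: float, psi: float) -> np.ndarray:
    weights = _hwe_probs(q) * psi ** np.arange(3)
    return weights / weights.sum()


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _draw_arm(rng: np.random.Generator, n: int, probs: np.ndarray) -> GenotypeCounts:
    cc, ct, tt = (int(v) for v in rng.multinomial(n, probs))
    return GenotypeCounts(cc=cc, ct=ct, tt=tt)


def simulate_study(
    spec: SimStudySpec,
    rng: np.random.Generator,
    study_id: str = "sim",
    population: str = "simulated",
) -> StudyRecord:
    """Draw one study: HWE controls, odds-tilted cases."""
    control = _draw_arm(rng, spec.n_control, _hwe_probs(spec.q))
    case = _draw_arm(rng, spec.n_case, _case_probs(spec.q, spec.psi))
    return StudyRecord(study_id=study_id, population=population, case=case, control=control)


def simulate_table(config: SimConfig, replicate: int = 0) -> tuple[StudyTable, SimTruth]:
    """Draw a k-study table plus its truth sidecar, reproducibly.

    ``replicate`` offsets the substream key so repeated draws from one
    config (as in :func:`rejection_rate`) stay independent yet seeded.
    """
    studies = []
    psis = []
    for i, spec in enumerate(config.specs):
        rng = _rng(config.seed, replicate, i)
        if config.tau > 0:
            psi_i = float(np.exp(rng.normal(math.log(spec.psi), config.tau)))
        else:
            psi_i = spec.psi
        realized = SimStudySpec(spec.n_case, spec.n_control, spec.q, psi_i)
        studies.append(simulate_study(realized, rng, study_id=f"sim{i + 1:03d}"))
        psis.append(psi_i)
    truth = SimTruth(
        psi=tuple(psis),
        q=tuple(s.q for s in config.specs),
        tau=config.tau,
        seed=config.seed,
    )
    return StudyTable(tuple(studies)), truth


def rejection_rate(config: SimConfig, reps: int, alpha: float = 0.05) -> RejectionRate:
    """Fraction of replicates whose pooled Z-test rejects at ``alpha``.

    Each replicate simulates a fresh table, runs allele tables ->
    heterogeneity -> model selection -> pooling, and counts p < alpha.
    Returns the rate with its exact (Clopper-Pearson) binomial 95% CI.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rejections = 0
    for rep in range(reps):
        table, _ = simulate_table(config, replicate=rep)
        pooled = pool_auto(study_effects(table))
        if pooled.p < alpha:
            rejections += 1
    from scipy.stats import beta as beta_dist

    lo = 0.0 if rejections == 0 else float(beta_dist.ppf(0.025, rejections, reps - rejections + 1))
    hi = 1.0 if rejections == reps else float(beta_dist.ppf(0.975, rejections + 1, reps - rejections))
    return RejectionRate(
        rate=rejections / reps, ci_low=lo, ci_high=hi, rejections=rejections, reps=reps
    )


def table1_like_specs(psi: float = 1.0, q: float = 0.09) -> tuple[SimStudySpec, ...]:
    """Seven-study design with the bundled table's arm sizes.

    The default q of 0.09 is the pooled control effect-allele frequency of
    the bundled studies (rounded); psi = 1 gives the null design used for
    calibration experiments.
    """
    sizes = [(1019, 1030), (812, 762), (376, 277), (448, 452), (483, 495), (388, 389), (529, 421)]
    return tuple(SimStudySpec(n_case=a, n_control=b, q=q, psi=psi) for a, b in sizes)
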