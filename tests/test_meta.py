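"""Heterogeneity, model selection and inverse-variance pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcmeta import (
    EffectEstimate,
    heterogeneity,
    pool_auto,
    pool_fixed,
    pool_mantel_haenszel,
    pool_random,
    select_model,
)
from gcmeta.errors import InsufficientStudiesError, ValidationError
from gcmeta.meta import HeterogeneityResult


def _effect(study_id, log_or, se):
    z = 1.959964
    return EffectEstimate(
        study_id=study_id,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
    )


effects_strategy = st.lists(
    st.tuples(st.floats(-2, 2), st.floats(0.05, 1.0)),
    min_size=2,
    max_size=12,
).map(lambda pairs: [_effect(f"s{i}", lo, se) for i, (lo, se) in enumerate(pairs)])


# --- heterogeneity -----------------------------------------------------------


def test_table1_heterogeneity(effects1):
    het = heterogeneity(effects1)
    assert het.q == pytest.approx(5.95, abs=0.01)
    assert het.df == 6
    assert het.i2 == 0.0          # Q < df floors I2 at zero
    assert het.tau2 == 0.0
    assert 0.40 < het.p_q < 0.46  # printed as 0.44; direct computation ~0.43


def test_two_identical_studies_have_no_heterogeneity():
    het = heterogeneity([_effect("a", 0.3, 0.1), _effect("b", 0.3, 0.1)])
    assert het.q == pytest.approx(0.0, abs=1e-12)
    assert het.i2 == 0.0
    assert het.p_q == pytest.approx(1.0)


def test_heterogeneity_needs_two_studies():
    with pytest.raises(InsufficientStudiesError):
        heterogeneity([_effect("a", 0.3, 0.1)])
    with pytest.raises(ValidationError):
        heterogeneity([_effect("a", 0.3, 0.1), _effect("b", 0.1, 0.0)])


@settings(max_examples=100, deadline=None)
@given(effects=effects_strategy)
def test_q_matches_two_pass_oracle_and_is_order_invariant(effects):
    het = heterogeneity(effects)
    # brute-force two-pass recomputation
    w = [1 / e.se**2 for e in effects]
    pooled = sum(wi * e.log_or for wi, e in zip(w, effects)) / sum(w)
    q = sum(wi * (e.log_or - pooled) ** 2 for wi, e in zip(w, effects))
    assert het.q == pytest.approx(q, abs=1e-9)
    assert heterogeneity(effects[::-1]).q == pytest.approx(het.q, abs=1e-9)
    assert 0 <= het.i2 <= 100
    assert het.tau2 >= 0
    if het.q <= het.df:
        assert het.i2 == 0.0 and het.tau2 == 0.0


# --- fixed-effect pooling ----------------------------------------------------


def test_table1_pooled_fixed_headline(effects1):
    pooled = pool_fixed(effects1)
    assert round(pooled.or_, 2) == 1.28
    assert round(pooled.ci_low, 2) == 1.16
    assert round(pooled.ci_high, 2) == 1.42
    assert pooled.p <= 1e-4
    assert pooled.model == "fixed"
    assert sum(pooled.weights.values()) == pytest.approx(1.0, abs=1e-12)


def test_single_study_pool_is_identity():
    e = _effect("only", 0.25, 0.1)
    pooled = pool_fixed([e])
    assert pooled.log_or == pytest.approx(e.log_or)
    assert pooled.se == pytest.approx(e.se)
    assert pooled.ci_low == pytest.approx(e.ci_low)


def test_equal_se_pool_is_plain_average():
    pooled = pool_fixed([_effect("a", 0.1, 0.2), _effect("b", 0.5, 0.2)])
    assert pooled.log_or == pytest.approx(0.3)


@settings(max_examples=100, deadline=None)
@given(effects=effects_strategy)
def test_pooled_estimate_properties(effects):
    pooled = pool_fixed(effects)
    los = [e.log_or for e in effects]
    assert min(los) - 1e-12 <= pooled.log_or <= max(los) + 1e-12
    assert pooled.se < min(e.se for e in effects) + 1e-12
    assert all(w > 0 for w in pooled.weights.values())
    assert sum(pooled.weights.values()) == pytest.approx(1.0, abs=1e-12)
    assert pooled.z == pytest.approx(pooled.log_or / pooled.se)
    assert 0 < pooled.p <= 1
    # two-sided normal tail against an independent high-precision evaluation
    # (skip comparison where erfc underflows and the clamp kicks in)
    tail = math.erfc(abs(pooled.z) / math.sqrt(2))
    if tail > 0:
        assert pooled.p == pytest.approx(tail, abs=1e-12)


# --- random effects ----------------------------------------------------------


def test_random_collapses_to_fixed_when_tau2_zero(effects1):
    fixed, random = pool_fixed(effects1), pool_random(effects1)
    assert heterogeneity(effects1).tau2 == 0.0
    assert random.log_or == pytest.approx(fixed.log_or, abs=1e-12)
    assert random.se == pytest.approx(fixed.se, abs=1e-12)


def test_random_ci_wider_under_dispersion():
    rng = np.random.default_rng(11)
    # log ORs scattered far beyond their nominal SEs (tau ~ 0.4)
    effects = [_effect(f"s{i}", float(rng.normal(0.3, 0.4)), 0.08) for i in range(10)]
    het = heterogeneity(effects)
    assert het.tau2 > 0
    fixed, random = pool_fixed(effects), pool_random(effects)
    assert (random.ci_high - random.ci_low) > (fixed.ci_high - fixed.ci_low)


# --- model selection ---------------------------------------------------------


@pytest.mark.parametrize(
    "p_q, i2, expected",
    [
        (0.05, 80.0, "random"),
        (0.05, 30.0, "fixed"),   # conjunction: high I2 required too
        (0.50, 80.0, "fixed"),   # and low Q-test p required
        (0.10, 51.0, "fixed"),   # threshold is strict: p < 0.1
        (0.09, 50.0, "fixed"),   # I2 must exceed 50
    ],
)
def test_select_model_conjunction(p_q, i2, expected):
    het = HeterogeneityResult(q=1.0, df=1, p_q=p_q, i2=i2, tau2=0.1)
    assert select_model(het) == expected


def test_table1_selects_fixed(effects1):
    assert select_model(heterogeneity(effects1)) == "fixed"
    assert pool_auto(effects1).model == "fixed"


# --- independent oracles -----------------------------------------------------


def test_against_statsmodels_combine_effects(effects1):
    """Q, tau2, I2 and the fixed-effect pool agree with statsmodels
    (statsmodels reports unfloored tau2/I2; floors applied for comparison)."""
    from statsmodels.stats.meta_analysis import combine_effects

    eff = np.array([e.log_or for e in effects1])
    var = np.array([e.se**2 for e in effects1])
    res = combine_effects(eff, var, method_re="dl")
    het = heterogeneity(effects1)
    assert het.q == pytest.approx(float(res.q), abs=1e-9)
    assert het.tau2 == pytest.approx(max(float(res.tau2), 0.0), abs=1e-9)
    assert het.i2 == pytest.approx(max(float(res.i2), 0.0) * 100, abs=1e-6)
    assert pool_fixed(effects1).log_or == pytest.approx(float(res.mean_effect_fe), abs=1e-9)
    assert pool_fixed(effects1).se == pytest.approx(float(res.sd_eff_w_fe), abs=1e-9)


def test_random_effects_against_statsmodels_on_heterogeneous_data():
    from statsmodels.stats.meta_analysis import combine_effects

    rng = np.random.default_rng(5)
    effects = [_effect(f"s{i}", float(rng.normal(0.2, 0.5)), 0.1) for i in range(8)]
    res = combine_effects(
        np.array([e.log_or for e in effects]),
        np.array([e.se**2 for e in effects]),
        method_re="dl",
    )
    het = heterogeneity(effects)
    assert het.tau2 > 0  # ensures no floor discrepancy with statsmodels
    assert het.tau2 == pytest.approx(float(res.tau2), abs=1e-9)
    pooled = pool_random(effects)
    assert pooled.log_or == pytest.approx(float(res.mean_effect_re), abs=1e-9)
    assert pooled.se == pytest.approx(float(res.sd_eff_w_re), abs=1e-9)


def test_mantel_haenszel_cross_check(table1, effects1):
    """The MH pooled allele OR agrees with the IV pool at 2 dp on the
    bundled homogeneous table."""
    mh = pool_mantel_haenszel(table1)
    iv = pool_fixed(effects1)
    assert round(mh.or_, 2) == round(iv.or_, 2) == 1.28
    assert sum(mh.weights.values()) == pytest.approx(1.0, abs=1e-12)
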