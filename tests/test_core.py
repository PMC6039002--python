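"""Unit and property tests for the per-division operators."""

import math

import pytest
from hypothesis import given, strategies as st

from mztsim.core import (
    EmbryoState,
    GrowthConfig,
    InvalidParameterError,
    InvalidStateError,
    MethylState,
    RateSet,
    SexConfig,
    active_demethylate,
    decay_repressor,
    division_step,
    nucleocytoplasmic_ratio,
    realized_division_rate,
    repair,
    replicate,
    repressor_effect,
    transition_rate,
    update_cell_count,
)

# -- strategies --------------------------------------------------------------

unit = st.floats(0.0, 1.0, allow_nan=False)


@st.composite
def methyl_states(draw):
    x = draw(unit)
    y = draw(st.floats(0.0, 1.0 - x))
    return MethylState(x, y, 1.0 - x - y)


@st.composite
def rate_sets(draw):
    a = draw(unit)
    d = draw(st.floats(0.0, 1.0 - a))
    return RateSet(alpha=a, beta=draw(unit), delta=d, zeta=draw(unit))


# -- domain types ------------------------------------------------------------

def test_methyl_state_rejects_invalid_proportions():
    with pytest.raises(InvalidParameterError):
        MethylState(0.5, 0.5, 0.5)
    with pytest.raises(InvalidParameterError):
        MethylState(-0.2, 0.6, 0.6)


def test_rate_set_rejects_alpha_delta_over_one():
    with pytest.raises(InvalidParameterError):
        RateSet(alpha=0.6, beta=0.0, delta=0.5)


def test_sex_config_rejects_unknown_label():
    with pytest.raises(InvalidParameterError):
        SexConfig("other", post_zga=RateSet(0.99, 0.04, 0.01))


def test_embryo_state_nu_is_reciprocal_cell_count():
    e = EmbryoState(N=100.0, rho=0.5, rho0=1.0)
    assert e.nu == pytest.approx(0.01, abs=1e-12)


# -- growth / repressor ------------------------------------------------------

@pytest.mark.parametrize(
    "N, mu, K, expected",
    [
        (1024.0, 0.1, 1024.0, 1024.0),      # logistic fixed point
        (1.0, 0.2, 1024.0, 1.199804688),    # single-cell zygote, doubled rate
        (512.0, 0.1, 1024.0, 537.6),        # inflection point
    ],
)
def test_update_cell_count_examples(N, mu, K, expected):
    assert update_cell_count(N, mu, K) == pytest.approx(expected, abs=1e-6)


def test_update_cell_count_rejects_invalid():
    with pytest.raises(InvalidParameterError):
        update_cell_count(2000.0, 0.1, 1024.0)
    with pytest.raises(InvalidParameterError):
        update_cell_count(10.0, 0.0, 1024.0)


@given(st.floats(1.0, 1024.0), st.floats(0.001, 1.0))
def test_growth_is_monotone_and_bounded(N, mu):
    out = update_cell_count(N, mu, 1024.0)
    assert N <= out <= 1024.0


@pytest.mark.parametrize(
    "rho, r, expected", [(1.0, 0.1, 0.2), (0.0, 0.1, 0.1), (0.5, 0.1, 0.15)]
)
def test_realized_division_rate(rho, r, expected):
    assert realized_division_rate(rho, r) == pytest.approx(expected)


def test_repressor_decay_is_geometric():
    rho = 1.0
    for _ in range(44):
        rho = decay_repressor(rho, 0.1)
    assert rho == pytest.approx(0.9**44)
    assert rho <= 0.01  # first division at which rho drops below 1%
    assert 0.9**43 > 0.01
    assert decay_repressor(0.0, 0.1) == 0.0


def test_repressor_effect_examples():
    assert repressor_effect(1.0, 1.0) == 0.0
    assert repressor_effect(0.0, 1.0) == 1.0
    assert repressor_effect(0.0, 0.0) == 1.0  # defined as 1 when rho0 = 0
    with pytest.raises(InvalidStateError):
        repressor_effect(2.0, 1.0)


@pytest.mark.parametrize("N, expected", [(1.0, 1.0), (100.0, 0.01), (1024.0, 0.0009765625)])
def test_nucleocytoplasmic_ratio(N, expected):
    assert nucleocytoplasmic_ratio(N) == pytest.approx(expected, abs=1e-15)


# -- rate transition ---------------------------------------------------------

TR = dict(Q=100.0, rho_power=1.0, rho0=1.0, nu_t=0.01)


def test_transition_rate_saturates_exactly():
    # start of a generation: argument is hugely positive, rate == pre exactly
    assert transition_rate(1.0, 0.99, rho=1.0, **TR) == 1.0
    # deeply post-ZGA: rate == post exactly
    assert transition_rate(1.0, 0.99, rho=0.0001, **TR) == 0.99


def test_transition_rate_midpoint():
    # rho0/rho == 1/nu_t puts the logistic at its midpoint
    assert transition_rate(1.0, 0.99, rho=0.01, **TR) == pytest.approx(0.995)


def test_transition_rate_rho_zero_is_invalid_state():
    with pytest.raises(InvalidStateError):
        transition_rate(1.0, 0.99, rho=0.0, **TR)


def test_transition_rate_step_function_when_no_repressor():
    kw = dict(Q=100.0, rho_power=1.0, rho0=0.0, rho=0.0, nu_t=0.01)
    assert transition_rate(1.0, 0.99, nu=0.5, **kw) == 1.0
    assert transition_rate(1.0, 0.99, nu=0.01, **kw) == 0.99
    with pytest.raises(InvalidParameterError):
        transition_rate(1.0, 0.99, **kw)  # nu required


@given(st.floats(1e-6, 1.0))
def test_transition_rate_bounded_and_monotone_in_rho(rho):
    lo, hi = sorted((0.99, 1.0))
    v = transition_rate(1.0, 0.99, rho=rho, **TR)
    assert lo <= v <= hi
    # decreasing rho moves the rate toward the post value
    v2 = transition_rate(1.0, 0.99, rho=rho * 0.9, **TR)
    assert v2 <= v + 1e-15


# -- methylation sub-steps ---------------------------------------------------

@pytest.mark.parametrize(
    "state, expected",
    [
        ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
        ((0.0, 0.0, 1.0), (0.0, 0.0, 1.0)),
        ((0.5, 0.2, 0.3), (0.0, 0.6, 0.4)),
    ],
)
def test_replicate_examples(state, expected):
    out = replicate(MethylState(*state))
    assert out.as_tuple() == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize(
    "state, rates, expected",
    [
        ((0.0, 1.0, 0.0), dict(alpha=1.0, beta=0.0, delta=0.0, rho_c=0.3), (1.0, 0.0, 0.0)),
        ((0.0, 1.0, 0.0), dict(alpha=0.0, beta=0.0, delta=1.0, rho_c=1.0), (0.0, 0.0, 1.0)),
        ((0.0, 0.6, 0.4), dict(alpha=0.99, beta=0.04, delta=0.01, rho_c=1.0), (0.61, 0.0, 0.39)),
    ],
)
def test_repair_examples(state, rates, expected):
    out = repair(MethylState(*state), **rates)
    assert out.as_tuple() == pytest.approx(expected, abs=1e-12)


def test_repair_requires_post_replication_state():
    with pytest.raises(InvalidStateError):
        repair(MethylState(0.5, 0.0, 0.5), alpha=0.5, beta=0.0, delta=0.0, rho_c=1.0)


def test_repair_rejects_overdrawn_hemimethylated_pool():
    with pytest.raises(InvalidParameterError):
        repair(MethylState(0.0, 1.0, 0.0), alpha=0.8, beta=0.0, delta=0.5, rho_c=1.0)


@pytest.mark.parametrize(
    "state, zeta, expected",
    [
        ((0.61, 0.0, 0.39), 0.0, (0.61, 0.0, 0.39)),
        ((1.0, 0.0, 0.0), 1.0, (0.0, 0.0, 1.0)),
        ((0.5, 0.1, 0.4), 0.2, (0.4, 0.1, 0.5)),
    ],
)
def test_active_demethylate_examples(state, zeta, expected):
    out = active_demethylate(MethylState(*state), zeta)
    assert out.as_tuple() == pytest.approx(expected, abs=1e-12)


@given(methyl_states(), rate_sets(), unit)
def test_sub_steps_conserve_total_proportion(state, rates, rho_c):
    """X + Y + Z stays 1 (to 1e-12) after every sub-step."""
    rep = replicate(state)
    assert abs(rep.X + rep.Y + rep.Z - 1.0) <= 1e-12
    fixed = repair(rep, rates.alpha, rates.beta, rates.delta, rho_c)
    assert abs(fixed.X + fixed.Y + fixed.Z - 1.0) <= 1e-12
    act = active_demethylate(fixed, rates.zeta)
    assert abs(act.X + act.Y + act.Z - 1.0) <= 1e-12


@given(methyl_states(), unit, unit)
def test_full_repair_resolution_empties_hemimethylated_pool(state, alpha, beta):
    """When alpha + rho_c*delta = 1 no hemimethylated sites survive repair."""
    delta = 1.0 - alpha
    out = repair(replicate(state), alpha, beta, delta, rho_c=1.0)
    assert out.Y == pytest.approx(0.0, abs=1e-12)


# -- composed division step --------------------------------------------------

def _default_sex():
    return SexConfig("male", post_zga=RateSet(0.99, 0.04, 0.01, 0.0))


def test_division_step_preserves_state_before_zga():
    """Pre-ZGA, perfect maintenance exactly undoes replication for Y = 0 states."""
    cfg = GrowthConfig()
    state = MethylState(0.7, 0.0, 0.3)
    embryo = EmbryoState.initial(cfg)
    for _ in range(40):  # well before the transition midpoint at division 45
        state, embryo, rates = division_step(state, embryo, cfg, _default_sex())
        assert rates.alpha == 1.0 and rates.beta == 0.0
    assert state.as_tuple() == (0.7, 0.0, 0.3)


def test_division_step_advances_growth_and_repressor():
    cfg = GrowthConfig()
    embryo = EmbryoState.initial(cfg)
    state = MethylState(1.0, 0.0, 0.0)
    _, nxt, _ = division_step(state, embryo, cfg, _default_sex())
    assert nxt.mu == pytest.approx(0.2)          # (1 + rho0) * r
    assert nxt.rho == pytest.approx(0.9)         # one decay step
    assert nxt.N == pytest.approx(1.199804688, abs=1e-6)


def test_division_step_converges_to_post_zga_fixed_point():
    cfg = GrowthConfig()
    state = MethylState(1.0, 0.0, 0.0)
    embryo = EmbryoState.initial(cfg)
    sex = _default_sex()
    for _ in range(250):
        state, embryo, _ = division_step(state, embryo, cfg, sex)
    assert state.X == pytest.approx(0.04 / 0.05, abs=1e-5)
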