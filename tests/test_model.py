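"""Core model: uptake functions, derivative, closed-patch equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.optimize import brentq

import metaecosim as me
from metaecosim._kernels import pack_params, rhs
from metaecosim.model import _SCALAR_FIELDS


@pytest.mark.parametrize(
    "func,stock,expected",
    [
        (me.uptake_producer, 10.0, 0.5),  # half-saturation point
        (me.uptake_producer, 0.0, 0.0),
        (me.uptake_producer, 0.5842, 0.5842 / 10.5842),
        (me.uptake_consumer, 6.0, 0.3),  # half-saturation point
        (me.uptake_consumer, 0.0, 0.0),
        (me.uptake_consumer, 4.0, 0.24),  # equals m_C: consumer equilibrium
    ],
)
def test_uptake_known_values(baseline, func, stock, expected):
    assert func(stock, baseline) == pytest.approx(expected, abs=1e-12)


def test_uptake_monotone_and_bounded(baseline):
    N = np.linspace(0, 1e6, 101)
    f = me.uptake_producer(N, baseline)
    assert np.all(np.diff(f) > 0)
    assert np.all(f < baseline.a_P)


@pytest.mark.parametrize("func", [me.uptake_producer, me.uptake_consumer])
def test_uptake_rejects_negative_stock(baseline, func):
    with pytest.raises(ValueError):
        func(-0.1, baseline)


def test_derivative_hand_value_uncoupled(nested):
    """All stocks 1, no spatial flows: rates match direct evaluation."""
    p = me.ModelParams.with_dispersal(0.0, 0.0)
    d = me.derivative(me.MetaState.uniform(1, 1, 1, 4), p, nested)
    assert d.N == pytest.approx([0.181091] * 4, abs=1e-6)
    assert d.P == pytest.approx([-0.044805] * 4, abs=1e-6)
    assert d.C == pytest.approx([-0.154286] * 4, abs=1e-6)


@pytest.mark.parametrize("topo_name", ["nested", "fully_connected"])
def test_spatial_terms_vanish_for_uniform_state(request, topo_name):
    """Conservative topologies move no mass between identical patches."""
    topo = request.getfixturevalue(topo_name)
    p_coupled = me.ModelParams.with_dispersal(3.0, 0.7, 0.2)
    p_alone = me.ModelParams.with_dispersal(0.0, 0.0)
    state = me.MetaState.uniform(0.3, 2.1, 0.05, 4)
    d1 = me.derivative(state, p_coupled, topo)
    d2 = me.derivative(state, p_alone, topo)
    for a, b in [(d1.N, d2.N), (d1.P, d2.P), (d1.C, d2.C)]:
        np.testing.assert_allclose(a, b, atol=1e-14)


def test_closed_equilibrium_producer_stock_exact(baseline, closed_eq):
    # grazing balances consumer loss: P* = b_C m_C / (a_C - m_C)
    assert closed_eq[1] == 4.0


def test_closed_equilibrium_matches_bruteforce_oracle(baseline, closed_eq):
    """Independent root-find of the scalar equilibrium condition."""
    p = baseline
    P_star = p.b_C * p.m_C / (p.a_C - p.m_C)

    def mismatch(C):
        # N* from nutrient balance vs N* required by producer balance
        N_balance = (
            p.I_N
            - (1 - p.r_P) * p.m_P * P_star
            - (1 - p.r_C) * p.m_C * C
        ) / p.e_N
        u = p.m_P + p.m_C * C / P_star  # required f_P(N*)
        N_uptake = p.b_P * u / (p.a_P - u)
        return N_balance - N_uptake

    C_star = brentq(mismatch, 1e-9, 1.0, xtol=1e-14)
    N_star = (
        p.I_N - (1 - p.r_P) * p.m_P * P_star - (1 - p.r_C) * p.m_C * C_star
    ) / p.e_N
    assert closed_eq[2] == pytest.approx(C_star, abs=1e-10)
    assert closed_eq[0] == pytest.approx(N_star, abs=1e-10)
    assert closed_eq[2] == pytest.approx(0.0866, abs=5e-4)
    assert closed_eq[0] == pytest.approx(0.584, abs=5e-4)


def test_equilibrium_is_fixed_point_of_derivative(nested, closed_eq):
    p = me.ModelParams.with_dispersal(0.0, 0.0)
    state = me.MetaState.uniform(*closed_eq, 4)
    d = me.derivative(state, p, nested)
    assert max(np.abs(d.to_vector())) < 1e-12


def test_no_equilibrium_without_consumer_persistence():
    with pytest.warns(UserWarning):
        p = me.ModelParams(a_C=0.2, m_C=0.24)
    with pytest.raises(me.EquilibriumError):
        me.closed_ecosystem_equilibrium(p)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st_.integers(0, 2**31 - 1), st_.booleans())
def test_mass_bookkeeping_under_spatial_exchange(seed, use_full):
    """Spatial flows redistribute mass; only local terms change the total.

    d/dt sum(N+P+C) must equal n I_N - sum(e_N N + (1-r_P) m_P P +
    (1-r_C) m_C C) for any nonnegative state and conservative topology.
    """
    topo = (
        me.fully_connected_resource_topology()
        if use_full
        else me.nested_topology()
    )
    rng = np.random.default_rng(seed)
    p = me.ModelParams.with_dispersal(
        rng.uniform(0, 6), rng.uniform(0, 1), rng.uniform(0, 1)
    )
    state = me.MetaState(*rng.uniform(0, 10, (3, 4)))
    d = me.derivative(state, p, topo)
    total_rate = d.N.sum() + d.P.sum() + d.C.sum()
    local = (
        4 * p.I_N
        - (
            p.e_N * state.N
            + (1 - p.r_P) * p.m_P * state.P
            + (1 - p.r_C) * p.m_C * state.C
        ).sum()
    )
    assert total_rate == pytest.approx(local, abs=1e-10)


def test_permutation_equivariance_under_location_swap(nested):
    """Relabelling locations commutes with the derivative."""
    perm = nested.location_swap_permutation()
    p = me.ModelParams.with_dispersal(4.0, 0.4)
    rng = np.random.default_rng(3)
    state = me.MetaState(*rng.uniform(0, 5, (3, 4)))
    d = me.derivative(state, p, nested)
    swapped = me.MetaState(state.N[perm], state.P[perm], state.C[perm])
    d_swapped = me.derivative(swapped, p, nested)
    np.testing.assert_allclose(d_swapped.N, d.N[perm], atol=1e-14)
    np.testing.assert_allclose(d_swapped.P, d.P[perm], atol=1e-14)
    np.testing.assert_allclose(d_swapped.C, d.C[perm], atol=1e-14)


def test_zero_compartments_never_pushed_negative(nested):
    """Rates at the orthant boundary point inward (or along it)."""
    p = me.ModelParams.with_dispersal(5.0, 0.4)
    rng = np.random.default_rng(7)
    other = rng.uniform(0, 5, (3, 4))
    for comp in range(3):
        vals = other.copy()
        vals[comp] = 0.0
        d = me.derivative(me.MetaState(*vals), p, nested)
        assert [d.N, d.P, d.C][comp].min() >= 0.0


def test_compiled_kernel_matches_reference_derivative(nested, fully_connected):
    rng = np.random.default_rng(11)
    for topo in (nested, fully_connected):
        p = me.ModelParams.with_dispersal(
            rng.uniform(0, 6), rng.uniform(0, 1), rng.uniform(0, 1)
        )
        y = rng.uniform(0, 8, 12)
        ref = me.derivative(me.MetaState.from_vector(y, 4), p, topo).to_vector()
        fast = rhs(
            0.0, y, pack_params(p), topo.S_N, topo.S_C, topo.S_P, p.d_C
        )
        np.testing.assert_allclose(fast, ref, rtol=1e-13, atol=1e-15)


def test_params_config_roundtrip_and_unknown_key():
    p = me.ModelParams.with_dispersal(2.5, 0.3, 0.1)
    q = me.ModelParams.from_dict(p.to_dict())
    assert q.to_dict() == p.to_dict()
    with pytest.raises(KeyError, match="unknown parameter"):
        me.ModelParams.from_dict({"I_n": 0.05})  # typo must not pass silently


def test_params_validation():
    with pytest.raises(ValueError):
        me.ModelParams(r_P=1.2)
    with pytest.raises(ValueError):
        me.ModelParams(I_N=-0.1)
    assert set(_SCALAR_FIELDS) <= set(me.ModelParams().to_dict())
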