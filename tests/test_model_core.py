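"""QIF-constant transform, analytic rates and the mean-field right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from colgamma import (
    ConfigurationError,
    PopulationState,
    derive_qif_constants,
    mean_field_rhs,
    qif_tonic_rate,
    subthreshold_fixed_point,
    uncoupled_steady_state,
)
from colgamma.fixtures import ei_pair
from colgamma.model_core import rhs_arrays


@pytest.mark.parametrize(
    "g_L, expected",
    [
        (0.08, (0.0114286, 1.33714, 38.9714)),   # excitatory leak conductance
        (0.10, (0.0142857, 1.67143, 48.7143)),   # inhibitory leak conductance
    ],
)
def test_qif_constants_match_direct_arithmetic(g_L, expected):
    zeta, eta, kappa = derive_qif_constants(g_L=g_L, C=1.0, V_R=-62.0, V_T=-55.0)
    assert zeta == pytest.approx(expected[0], rel=1e-5)
    assert eta == pytest.approx(expected[1], rel=1e-5)
    assert kappa == pytest.approx(expected[2], rel=1e-5)


@given(
    g_L=st.floats(0.01, 1.0),
    C=st.floats(0.1, 10.0),
    V_R=st.floats(-90.0, -50.0),
    dV=st.floats(1.0, 40.0),
)
@settings(max_examples=50, deadline=None)
def test_quadratic_roots_are_rest_and_threshold(g_L, C, V_R, dV):
    """zeta*v^2 + eta*v + kappa factorizes as zeta*(v-V_R)*(v-V_T)."""
    V_T = V_R + dV
    zeta, eta, kappa = derive_qif_constants(g_L, C, V_R, V_T)
    assert zeta > 0
    roots = sorted(np.roots([zeta, eta, kappa]).real)
    assert roots[0] == pytest.approx(V_R, rel=1e-9, abs=1e-9)
    assert roots[1] == pytest.approx(V_T, rel=1e-9, abs=1e-9)


def test_degenerate_thresholds_rejected():
    with pytest.raises(ConfigurationError):
        derive_qif_constants(0.08, 1.0, -55.0, -55.0)


@pytest.mark.parametrize("v_fixed", [-62.0, -55.0])
def test_isolated_population_fixed_points(v_fixed):
    """r=0 with v at rest or threshold is a fixed point without heterogeneity."""
    zeta, eta, kappa = derive_qif_constants(0.08, 1.0, -62.0, -55.0)
    one = np.ones(1)
    dr, dv, dge, dgi = rhs_arrays(
        r=np.zeros(1), v=np.array([v_fixed]),
        g_exc=np.zeros(1), g_inh=np.zeros(1),
        zeta=zeta * one, eta=eta * one, kappa=kappa * one, C=one,
        delta_back=np.zeros(1),
        A_exc=np.zeros((1, 1)), A_inh=np.zeros((1, 1)), I_ext=np.zeros(1),
    )
    assert dr[0] == 0.0
    assert dv[0] == pytest.approx(0.0, abs=1e-12)
    assert dge[0] == 0.0 and dgi[0] == 0.0


def test_heterogeneity_source_repels_rate_from_zero():
    """At r=0 the rate derivative equals zeta*Delta/pi > 0."""
    zeta, eta, kappa = derive_qif_constants(0.08, 1.0, -62.0, -55.0)
    one = np.ones(1)
    dr, *_ = rhs_arrays(
        r=np.zeros(1), v=np.array([-60.0]),
        g_exc=np.zeros(1), g_inh=np.zeros(1),
        zeta=zeta * one, eta=eta * one, kappa=kappa * one, C=one,
        delta_back=np.array([0.3]),
        A_exc=np.zeros((1, 1)), A_inh=np.zeros((1, 1)), I_ext=np.zeros(1),
    )
    assert dr[0] == pytest.approx(zeta * 0.3 / np.pi, rel=1e-12)
    assert dr[0] == pytest.approx(1.0914e-3, rel=1e-3)


def test_tonic_rate_matches_period_quadrature():
    """Closed-form suprathreshold rate equals 1/∮ dV/(zeta V^2+eta V+kappa+I)."""
    zeta, eta, kappa = derive_qif_constants(0.08, 1.0, -62.0, -55.0)
    for I in (0.2, 0.5, 2.0):
        period, _ = quad(
            lambda V: 1.0 / (zeta * V ** 2 + eta * V + kappa + I),
            -np.inf, np.inf,
        )
        assert qif_tonic_rate(zeta, eta, kappa, I) == pytest.approx(
            1.0 / period, rel=1e-8
        )
    assert qif_tonic_rate(zeta, eta, kappa, 0.0) == 0.0


def test_subthreshold_fixed_point_is_quadratic_root():
    zeta, eta, kappa = derive_qif_constants(0.08, 1.0, -62.0, -55.0)
    I = 0.05
    v = subthreshold_fixed_point(zeta, eta, kappa, I)
    assert zeta * v * v + eta * v + kappa + I == pytest.approx(0.0, abs=1e-10)
    # smaller (stable) root: below the vertex of the parabola
    assert v < -eta / (2 * zeta)
    with pytest.raises(ConfigurationError):
        subthreshold_fixed_point(zeta, eta, kappa, 10.0)


def test_uncoupled_steady_state_zeroes_the_rhs():
    zeta, eta, kappa = derive_qif_constants(0.08, 1.0, -62.0, -55.0)
    r, v = uncoupled_steady_state(zeta, eta, kappa, 1.0, 0.10667, 0.3)
    one = np.ones(1)
    dr, dv, *_ = rhs_arrays(
        r=np.array([r]), v=np.array([v]),
        g_exc=np.zeros(1), g_inh=np.zeros(1),
        zeta=zeta * one, eta=eta * one, kappa=kappa * one, C=one,
        delta_back=np.array([0.3]),
        A_exc=np.zeros((1, 1)), A_inh=np.zeros((1, 1)),
        I_ext=np.array([0.10667]),
    )
    assert abs(dr[0]) < 1e-10 and abs(dv[0]) < 1e-8


def test_mean_field_rhs_dict_api_and_nan_guard():
    spec = ei_pair()
    states = {
        "E": PopulationState(r=0.01, v=-60.0, g_exc_in=0.0, g_inh_in=0.0),
        "I": PopulationState(r=0.01, v=-60.0, g_exc_in=0.0, g_inh_in=0.0),
    }
    inputs = {"E": (0.0, 0.0), "I": (0.0, 0.0)}
    d1 = mean_field_rhs(states, spec, inputs)
    d2 = mean_field_rhs(states, spec, inputs)
    assert d1["E"].r == d2["E"].r and d1["I"].v == d2["I"].v  # pure function
    assert d1["E"].g_exc_in > 0  # excitatory drive from both populations firing
    states["I"].v = float("nan")
    with pytest.raises(FloatingPointError, match="population I"):
        mean_field_rhs(states, spec, inputs)
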