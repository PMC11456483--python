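"""Integration, determinism, positivity, convergence and settle times."""

import numpy as np
import pytest

from colgamma import (
    ConfigurationError,
    SimulationConfig,
    StimulusCondition,
    build_network,
    network_fixed_point,
    settle_time,
    simulate,
    subthreshold_fixed_point,
)
from colgamma.fixtures import ei_pair
from colgamma.model_core import (
    TAU_D_EXC,
    TAU_D_INH,
    PopulationParams,
    rhs_arrays,
)
from colgamma.network_builder import NetworkSpec
from colgamma.analysis import oscillation_amplitude


def _single_population(delta=1e-6, I_back=0.05):
    pop = PopulationParams(
        name="E", cell_class="excitatory", layer="L4", column=1,
        C=1.0, g_L=0.08, V_R=-62.0, V_T=-55.0, N=1000,
        I_back_center=I_back, I_back_width=delta,
    )
    return NetworkSpec(populations=[pop], pathways=[], P_inter=0.0)


def test_determinism_bitwise():
    spec = build_network(delta_E=0.3, delta_I=0.02)
    sim = SimulationConfig(t_total=1500.0, t_onset=1000.0)
    cond = StimulusCondition(name="S1", onset=1000.0)
    a = simulate(spec, cond, sim)
    b = simulate(spec, cond, sim)
    assert a.content_hash() == b.content_hash()


def test_positivity_along_trajectory(ref_traces):
    for trace in ref_traces.values():
        assert (trace.r >= 0.0).all()


def test_isolated_population_converges_to_quadratic_root():
    """With vanishing heterogeneity and subthreshold drive, v settles on the
    smaller root of zeta*v^2 + eta*v + kappa + I = 0 and the rate dies."""
    spec = _single_population(delta=1e-6, I_back=0.05)
    sim = SimulationConfig(t_total=3000.0, t_onset=2900.0,
                           initial_state_policy="uncoupled")
    trace = simulate(spec, StimulusCondition(name="none", onset=2900.0), sim)
    p = spec.populations[0]
    v_expected = subthreshold_fixed_point(p.zeta, p.eta, p.kappa, p.I_back_center)
    v_final = trace.voltage("E")[-1]
    assert v_final == pytest.approx(v_expected, rel=1e-6)
    assert trace.rate("E")[-1] < 1e-3   # Hz


def test_aggregated_conductances_equal_per_pathway_reference():
    """One conductance per source class is exactly equivalent to one per
    pathway (linear ODE, class-wise decay): step-for-step Euler comparison
    against an independent per-pathway integrator."""
    spec = ei_pair()
    arrs = spec.const_arrays()
    A_exc, A_inh = spec.coupling_matrices()
    r_fp, v_fp, _, _ = network_fixed_point(spec)
    r0 = r_fp * 1.01
    v0 = v_fp.copy()

    dt, n_steps = 0.01, 20000   # 200 ms
    # reference: one conductance variable per pathway
    n = spec.n_populations
    paths = spec.pathways
    g_path = np.array([
        (TAU_D_EXC if spec.population(p.source).is_excitatory else TAU_D_INH)
        * p.g_peak * p.P * spec.population(p.source).N * r0[spec.index(p.source)]
        for p in paths
    ])
    src = np.array([spec.index(p.source) for p in paths])
    tgt = np.array([spec.index(p.target) for p in paths])
    exc_path = np.array([spec.population(p.source).is_excitatory for p in paths])
    tau_path = np.where(exc_path, TAU_D_EXC, TAU_D_INH)
    w_path = np.array([
        p.g_peak * p.P * spec.population(p.source).N for p in paths
    ])
    r, v = r0.copy(), v0.copy()
    for _ in range(n_steps):
        ge = np.bincount(tgt[exc_path], weights=g_path[exc_path], minlength=n)
        gi = np.bincount(tgt[~exc_path], weights=g_path[~exc_path], minlength=n)
        dr, dv, _, _ = rhs_arrays(
            r, v, ge, gi, arrs["zeta"], arrs["eta"], arrs["kappa"], arrs["C"],
            arrs["I_back_width"], A_exc * 0, A_inh * 0, arrs["I_back_center"],
        )
        dg = -g_path / tau_path + w_path * r[src]
        r = r + dt * dr
        v = v + dt * dv
        g_path = g_path + dt * dg

    # aggregated path through the production integrator
    ge0 = TAU_D_EXC * (A_exc @ r0)
    gi0 = TAU_D_INH * (A_inh @ r0)
    sim = SimulationConfig(
        t_total=200.0, t_onset=199.0, record_stride=1,
        initial_state_policy="custom",
        initial_state={"r": r0, "v": v0, "ge": ge0, "gi": gi0},
        substep_dv_max=float("inf"),   # plain fixed-step Euler, as the oracle
    )
    trace = simulate(spec, StimulusCondition(name="none", onset=199.0), sim)
    np.testing.assert_allclose(trace.r[-1] / 1000.0, r, rtol=1e-9)
    np.testing.assert_allclose(trace.v[-1], v, rtol=1e-9)


def test_dt_refinement_changes_amplitude_below_one_percent():
    spec = ei_pair()
    cond = StimulusCondition(name="none", onset=2000.0)
    amps = []
    for dt in (0.01, 0.005):
        sim = SimulationConfig(dt=dt, t_total=2500.0, t_onset=2000.0,
                               record_stride=int(round(0.1 / dt)))
        trace = simulate(spec, cond, sim)
        amps.append(oscillation_amplitude(trace, "E"))
    assert abs(amps[1] - amps[0]) / amps[0] < 0.01


def test_settle_time_reference_point(ref_traces_all):
    """At the ordered-pattern point the new steady amplitude is reached well
    inside the stated 2 s bound; an unstimulated run is settled within one
    oscillation cycle."""
    for name in ("S1", "S1S2", "S1S2_A1"):
        assert settle_time(ref_traces_all[name], "1L5E") <= 2000.0
    assert settle_time(ref_traces_all["none"], "1L5E") <= 40.0  # one 30 Hz cycle


def test_settle_time_requires_long_trace():
    spec = ei_pair()
    sim = SimulationConfig(t_total=2000.0, t_onset=1000.0)
    trace = simulate(spec, StimulusCondition(name="none", onset=1000.0), sim)
    with pytest.raises(ValueError, match="3 s past onset"):
        settle_time(trace, "E")


def test_blowup_guard_names_population_and_time():
    spec = ei_pair()
    sim = SimulationConfig(
        t_total=50.0, t_onset=40.0, rate_ceiling=1.0,
        initial_state_policy="custom",
        initial_state={"r": [2.0, 2.0], "v": [-60.0, -60.0]},
    )
    with pytest.raises(RuntimeError, match=r"population [EI] at t="):
        simulate(spec, StimulusCondition(name="none", onset=40.0), sim)


def test_invalid_simulation_config_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(dt=-0.01)
    with pytest.raises(ConfigurationError):
        SimulationConfig(t_total=100.0, t_onset=100.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(record_stride=0)
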