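"""Synthetic fixtures with analytically known properties.

Three kinds are provided: a pure sinusoid trace (closed-form envelope and
spectrum), a minimal two-population E-I pair (closed-form uncoupled fixed
point; a PING-type oscillator used to cross-validate the mean-field
reduction against the spiking network), and the full table-driven
two-column network.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model_core import Pathway, PopulationParams, uncoupled_steady_state
from .network_builder import NetworkSpec, build_network, load_default_config
from .simulator import TraceSet

FIXTURE_KINDS = ("sinusoid", "ei_pair", "table_network")


def sinusoid_trace(
    freq_hz: float = 30.0,
    amplitude: float = 1.0,
    offset: float = 10.0,
    t_total: float = 2000.0,
    dt: float = 0.1,
    t_onset: float = 1000.0,
) -> TraceSet:
    """Single-population trace ``offset + amplitude*sin(2*pi*f*t)`` (Hz)."""
    time = np.arange(0.0, t_total + dt / 2, dt)
    y = offset + amplitude * np.sin(2 * np.pi * freq_hz * time / 1000.0)
    return TraceSet(
        time=time,
        r=y[:, None],
        v=None,
        labels=["SYN"],
        condition="none",
        t_onset=t_onset,
        fingerprint="sinusoid-fixture",
        dt=dt,
    )


def ei_pair(
    delta_E: float = 0.3,
    delta_I: float = 0.02,
    I_back_E: float = 0.32,
    N_E: int = 3200,
    N_I: int = 800,
) -> NetworkSpec:
    """Minimal excitatory-inhibitory pair in a PING-oscillatory regime.

    The default drive is strongly suprathreshold and the connectivity
    sparse over a few thousand neurons: this puts the pair deep inside its
    oscillatory regime, where the collective rhythm is only weakly
    advanced by finite-size fluctuations, so down-scaled spiking
    simulations track the mean-field frequency closely.
    """
    cfg = load_default_config()
    pops_cfg = cfg["populations"]
    I_back_I = I_back_E * float(cfg["background"]["inhibitory_factor"])
    g_peak = cfg["pathways"]["g_peak"]

    common = dict(
        layer="L4", column=1,
        C=float(pops_cfg["C"]),
        V_R=float(pops_cfg["V_R"]), V_T=float(pops_cfg["V_T"]),
    )
    pops = [
        PopulationParams(
            name="E", cell_class="excitatory",
            g_L=float(pops_cfg["g_L"]["excitatory"]), N=N_E,
            I_back_center=I_back_E, I_back_width=delta_E, **common,
        ),
        PopulationParams(
            name="I", cell_class="inhibitory",
            g_L=float(pops_cfg["g_L"]["inhibitory"]), N=N_I,
            I_back_center=I_back_I, I_back_width=delta_I, **common,
        ),
    ]
    pathways = [
        Pathway("E", "E", 0.050, float(g_peak["excitatory"]["excitatory"])),
        Pathway("E", "I", 0.050, float(g_peak["excitatory"]["inhibitory"])),
        Pathway("I", "E", 0.075, float(g_peak["inhibitory"]["excitatory"])),
        Pathway("I", "I", 0.075, float(g_peak["inhibitory"]["inhibitory"])),
    ]
    return NetworkSpec(populations=pops, pathways=pathways, P_inter=0.0,
                       perturbation="none", config=cfg)


def make_fixture(kind: str) -> dict:
    """Fixture bundle: the object plus its analytically expected values."""
    if kind == "sinusoid":
        trace = sinusoid_trace()
        return {
            "kind": kind,
            "trace": trace,
            "expected": {
                "peak_freq_hz": 30.0,
                "upper_envelope": 11.0,
                "lower_envelope": 9.0,
                "cycle_amplitude": 1.0,
            },
        }
    if kind == "ei_pair":
        spec = ei_pair()
        expected = {}
        for p in spec.populations:
            r, v = uncoupled_steady_state(
                p.zeta, p.eta, p.kappa, p.C, p.I_back_center, p.I_back_width
            )
            expected[p.name] = {"uncoupled_r_hz": r * 1000.0, "uncoupled_v_mv": v}
        return {"kind": kind, "spec": spec, "expected": expected}
    if kind == "table_network":
        spec = build_network()
        return {
            "kind": kind,
            "spec": spec,
            "config": spec.to_config(),
            "expected": {"n_populations": 16, "n_pathways": len(spec.pathways)},
        }
    raise ValueError(f"unknown fixture kind {kind!r}; valid: {FIXTURE_KINDS}")
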