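"""Shared fixtures: cached condition sets at the reference parameter point.

Full-length (10 s, dt = 0.01 ms) runs are expensive, so traces are computed
once per (delta_E, delta_I, perturbation, condition) and shared across
tests through a module-level cache.
"""

from __future__ import annotations

import warnings

import pytest

from colgamma import (
    SimulationConfig,
    StimulusCondition,
    build_network,
    simulate,
)

_TRACE_CACHE: dict = {}

#: the reference gamma point of the two-column model
REF_POINT = (0.3, 0.02)

STIMULUS_CONDITIONS = ("S1", "S2", "S1S2", "S1S2_A1", "S1S2_A2")


def condition_set(delta_E, delta_I, perturbation=None,
                  conditions=STIMULUS_CONDITIONS):
    """Simulate (or fetch cached) full-length traces for several conditions."""
    out = {}
    spec = None
    for name in conditions:
        key = (round(delta_E, 6), round(delta_I, 6), perturbation or "none", name)
        if key not in _TRACE_CACHE:
            if spec is None:
                spec = build_network(delta_E=delta_E, delta_I=delta_I,
                                     perturbation=perturbation)
            sim = SimulationConfig.from_config(spec.config)
            cond = StimulusCondition.from_config(name, spec.config)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                _TRACE_CACHE[key] = simulate(spec, cond, sim)
        out[name] = _TRACE_CACHE[key]
    return out


@pytest.fixture(scope="session")
def ref_traces():
    """Traces for the five stimulus conditions at the reference point."""
    return condition_set(*REF_POINT)


@pytest.fixture(scope="session")
def ref_traces_all():
    """Reference-point traces including the no-stimulus baseline."""
    return condition_set(*REF_POINT, conditions=("none",) + STIMULUS_CONDITIONS)
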