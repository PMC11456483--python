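"""Forward-Euler integration of the full mean-field system and trace records.

The reference integrator is fixed-step forward Euler with dt = 0.01 ms,
integrating 10 s of activity with stimulus onset at 5 s (the first 5 s wash
out the arbitrary initial condition).  Traces are recorded at a configurable
stride (default 10, i.e. 0.1 ms sampling, Nyquist 5 kHz — far above the
gamma band).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .model_core import (
    ConfigurationError,
    TAU_D_EXC,
    TAU_D_INH,
    V_SYN_EXC,
    V_SYN_INH,
    rhs_arrays,
    uncoupled_steady_state,
)
from .network_builder import NetworkSpec
from .stimuli import StimulusCondition, steady_currents


@dataclass
class SimulationConfig:
    """Integration settings for one run."""

    dt: float = 0.01             # ms
    t_total: float = 10000.0     # ms
    t_onset: float = 5000.0      # ms
    record_stride: int = 10      # record every N steps
    rate_ceiling: float = 1000.0  # ms^-1; divergence guard (synchronous
                                  # inhibitory volleys legitimately reach ~10 ms^-1)
    initial_state_policy: str = "fixed_point"   # "fixed_point" | "uncoupled" | "custom"
    fp_perturbation: float = 1e-3   # relative nudge off the fixed point
    initial_state: Optional[dict] = None    # {"r":..., "v":..., "ge":..., "gi":...}
    # local substep guard: a grid step may move no voltage by more than
    # substep_dv_max (mV) nor remove more than substep_dr_rel_max of a
    # population's remaining rate; set dv_max to inf for plain fixed-step
    # Euler (the guard only ever engages inside near-singular gamma spikes)
    substep_dv_max: float = 0.5
    substep_dr_rel_max: float = 0.2
    substep_h_min_frac: float = 1e-7

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not self.t_onset < self.t_total:
            raise ConfigurationError("t_onset must be smaller than t_total")
        if self.record_stride < 1:
            raise ConfigurationError("record_stride must be >= 1")

    @classmethod
    def from_config(cls, config: dict, **overrides) -> "SimulationConfig":
        sim = config.get("simulation", {})
        kwargs = dict(
            dt=float(sim.get("dt", 0.01)),
            t_total=float(sim.get("t_total", 10000.0)),
            t_onset=float(sim.get("t_onset", 5000.0)),
            record_stride=int(sim.get("record_stride", 10)),
            rate_ceiling=float(sim.get("rate_ceiling", 1000.0)),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TraceSet:
    """Recorded firing-rate (Hz) and mean-voltage (mV) series per population."""

    time: np.ndarray               # ms, uniform grid
    r: np.ndarray                  # Hz, shape (n_samples, n_populations)
    v: Optional[np.ndarray]        # mV, same shape, or None
    labels: list
    condition: str
    t_onset: float
    fingerprint: str = ""
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.r.shape != (len(self.time), len(self.labels)):
            raise ValueError("trace shape inconsistent with time grid / labels")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no trace for population {label!r}") from None

    def rate(self, label: str) -> np.ndarray:
        """Firing-rate series of one population, Hz."""
        return self.r[:, self.index(label)]

    def voltage(self, label: str) -> np.ndarray:
        if self.v is None:
            raise ValueError("voltage traces were not recorded")
        return self.v[:, self.index(label)]

    def window(self, t0: float, t1: float) -> slice:
        """Index slice covering times in [t0, t1] (both edges inclusive)."""
        i0 = np.searchsorted(self.time, t0, side="left")
        i1 = np.searchsorted(self.time, t1, side="right")
        return slice(int(i0), int(i1))

    @property
    def t_end(self) -> float:
        return float(self.time[-1])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.time.tobytes())
        h.update(self.r.tobytes())
        if self.v is not None:
            h.update(self.v.tobytes())
        return h.hexdigest()


def uncoupled_initial_state(spec: NetworkSpec):
    """Per-population steady states with all coupling conductances at zero."""
    n = spec.n_populations
    r = np.empty(n)
    v = np.empty(n)
    for i, p in enumerate(spec.populations):
        r[i], v[i] = uncoupled_steady_state(
            p.zeta, p.eta, p.kappa, p.C, p.I_back_center, p.I_back_width
        )
    return r, v, np.zeros(n), np.zeros(n)


_FP_CACHE: dict = {}


def network_fixed_point(
    spec: NetworkSpec,
    I_extra: Optional[np.ndarray] = None,
    tol: float = 1e-9,
):
    """Steady state of the fully coupled network without stimulus.

    Solves the 4N-dimensional root problem with bounded least squares,
    seeded from the uncoupled steady states.  Used as the default initial
    condition: starting on (a nudge off) the fixed point avoids the
    near-singular synchronous transient that a cold start far from balance
    produces, and the pre-stimulus settling window then grows the
    oscillatory instability to its attractor.  Falls back to the uncoupled
    steady state if the residual does not converge.
    """
    from scipy.optimize import least_squares

    key = (spec.fingerprint(), None if I_extra is None else tuple(I_extra))
    if key in _FP_CACHE:
        return tuple(a.copy() for a in _FP_CACHE[key])

    arrs = spec.const_arrays()
    A_exc, A_inh = spec.coupling_matrices()
    n = spec.n_populations
    I_ext = arrs["I_back_center"].copy()
    if I_extra is not None:
        I_ext = I_ext + I_extra

    def resid(x):
        r, v, ge, gi = x[:n], x[n:2 * n], x[2 * n:3 * n], x[3 * n:]
        return np.concatenate(rhs_arrays(
            r, v, ge, gi,
            arrs["zeta"], arrs["eta"], arrs["kappa"], arrs["C"],
            arrs["I_back_width"], A_exc, A_inh, I_ext,
        ))

    r0, v0, _, _ = uncoupled_initial_state(spec)
    x0 = np.concatenate([r0, v0, TAU_D_EXC * (A_exc @ r0), TAU_D_INH * (A_inh @ r0)])
    lb = np.concatenate([np.full(n, 1e-14), np.full(n, -500.0),
                         np.zeros(n), np.zeros(n)])
    ub = np.concatenate([np.full(n, 10.0), np.full(n, 200.0),
                         np.full(n, 1e5), np.full(n, 1e5)])
    sol = least_squares(resid, np.clip(x0, lb, ub), bounds=(lb, ub),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.abs(sol.fun).max() > tol:
        warnings.warn(
            "coupled fixed point did not converge; falling back to the "
            "uncoupled steady state", RuntimeWarning, stacklevel=2,
        )
        return r0, v0, np.zeros(n), np.zeros(n)
    x = sol.x
    result = (x[:n].copy(), x[n:2 * n].copy(),
              x[2 * n:3 * n].copy(), x[3 * n:].copy())
    _FP_CACHE[key] = tuple(a.copy() for a in result)
    return result


def simulate(
    spec: NetworkSpec,
    cond: StimulusCondition,
    sim: Optional[SimulationConfig] = None,
    record_v: bool = True,
) -> TraceSet:
    """Integrate the network under one stimulus condition.

    Deterministic: identical inputs give bit-identical traces on the same
    platform.  Raises ``RuntimeError`` naming the population and time on
    numerical blow-up or positivity violation.
    """
    sim = sim or SimulationConfig()
    arrs = spec.const_arrays()
    A_exc, A_inh = spec.coupling_matrices()
    n = spec.n_populations

    I_sens, I_attn = steady_currents(cond, spec)
    I_pre = np.ascontiguousarray(arrs["I_back_center"])
    I_post = np.ascontiguousarray(arrs["I_back_center"] + I_sens + I_attn)

    if sim.initial_state_policy == "custom":
        init = sim.initial_state or {}
        r = np.array(init["r"], dtype=float).copy()
        v = np.array(init["v"], dtype=float).copy()
        ge = np.array(init.get("ge", np.zeros(n)), dtype=float).copy()
        gi = np.array(init.get("gi", np.zeros(n)), dtype=float).copy()
    elif sim.initial_state_policy == "uncoupled":
        r, v, ge, gi = uncoupled_initial_state(spec)
    elif sim.initial_state_policy == "fixed_point":
        r, v, ge, gi = network_fixed_point(spec)
        # deterministic nudge off the (possibly unstable) fixed point so
        # the oscillatory instability can grow during the settling window
        r = r * (1.0 + sim.fp_perturbation)
        v = v * (1.0 + sim.fp_perturbation)
    else:
        raise ConfigurationError(
            f"unknown initial_state_policy {sim.initial_state_policy!r}"
        )

    n_steps = int(round(sim.t_total / sim.dt))
    onset_step = int(round(cond.onset / sim.dt))
    r_rec, v_rec, status, bad_pop, bad_step = _kernels.euler_mean_field(
        r, v, ge, gi,
        np.ascontiguousarray(arrs["zeta"]), np.ascontiguousarray(arrs["eta"]),
        np.ascontiguousarray(arrs["kappa"]), np.ascontiguousarray(arrs["C"]),
        np.ascontiguousarray(arrs["I_back_width"]),
        np.ascontiguousarray(A_exc), np.ascontiguousarray(A_inh),
        I_pre, I_post,
        sim.dt, n_steps, onset_step, sim.record_stride,
        sim.rate_ceiling, TAU_D_EXC, TAU_D_INH, V_SYN_EXC, V_SYN_INH,
        sim.substep_dv_max, sim.substep_dr_rel_max, sim.substep_h_min_frac,
    )
    if status in (_kernels.NONFINITE, _kernels.NEGATIVE):
        label = spec.labels[bad_pop]
        t_bad = bad_step * sim.dt
        kind = "non-finite/runaway state" if status == _kernels.NONFINITE \
            else "positivity violation"
        raise RuntimeError(
            f"numerical blow-up ({kind}) in population {label} at t={t_bad:.2f} ms"
        )
    if status == _kernels.STEP_WARNING:
        warnings.warn(
            "substep guard hit its cap: a synchronous spike was under-resolved",
            RuntimeWarning, stacklevel=2,
        )

    time = np.arange(r_rec.shape[0]) * sim.record_stride * sim.dt
    return TraceSet(
        time=time,
        r=r_rec * 1000.0,   # ms^-1 -> Hz
        v=v_rec if record_v else None,
        labels=list(spec.labels),
        condition=cond.name,
        t_onset=cond.onset,
        fingerprint=spec.fingerprint(),
        dt=sim.dt,
    )


def settle_time(
    trace: TraceSet,
    population: str,
    rel_tol: float = 0.05,
    amp_floor_hz: float = 1e-3,
) -> float:
    """Time (ms past onset) for the oscillation-cycle amplitude to settle.

    The cycle amplitude is the half-range between the upper and lower
    envelopes, sampled at oscillation peaks.  The settle time is the first
    time after onset at which the amplitude enters and stays within
    ``rel_tol`` (relative) of its final-second mean; ``inf`` if it never
    does.  Non-oscillating traces are judged on the rate itself against its
    final-second mean.
    """
    from .analysis import envelope_series

    if trace.t_end - trace.t_onset < 3000.0:
        raise ValueError("trace must extend at least 3 s past onset")
    sl = trace.window(trace.t_onset, trace.t_end)
    t = trace.time[sl]
    y = trace.rate(population)[sl]
    upper, lower, peak_t, trough_t = envelope_series(t, y)
    final = t >= trace.t_end - 1000.0
    amp = (upper - lower) / 2.0
    A_f = float(np.mean(amp[final]))

    if A_f < amp_floor_hz or len(peak_t) < 3:
        # non-oscillating: settle on the slow trace itself
        y_f = float(np.mean(y[final]))
        band = rel_tol * max(abs(y_f), amp_floor_hz)
        ok = np.abs(y - y_f) <= band
        return _first_sustained(t, ok) - trace.t_onset

    # judge at oscillation peaks: amplitude within the relative band from
    # some peak onwards
    amp_at_peaks = np.interp(peak_t, t, amp)
    within = np.abs(amp_at_peaks - A_f) <= rel_tol * A_f
    for i in range(len(peak_t)):
        if within[i:].all():
            return float(peak_t[i] - trace.t_onset)
    return float("inf")


def _first_sustained(t: np.ndarray, ok: np.ndarray) -> float:
    """First time from which ``ok`` stays true; +inf if never."""
    if ok.all():
        return float(t[0])
    last_bad = int(np.max(np.nonzero(~ok)[0]))
    if last_bad + 1 >= len(t):
        return float("inf")
    return float(t[last_bad + 1])
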