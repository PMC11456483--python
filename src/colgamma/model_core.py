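"""Population-level state and the exact mean-field right-hand side.

Each neuronal population is a heterogeneous ensemble of quadratic
integrate-and-fire (QIF) neurons whose background currents are drawn from a
Lorentzian distribution.  Under the Lorentzian ansatz the ensemble reduces
exactly to three coupled ODEs per population: firing rate ``r`` (ms^-1),
mean membrane potential ``v`` (mV), and synaptic conductance.  This module
holds the per-population parameters, the quadratic-polynomial constants of
the QIF voltage equation, and the pure right-hand-side function used by the
integrator.

Unit system: mV, ms, uF/cm^2, mS/cm^2, mA/cm^2 throughout; firing rates are
carried internally in ms^-1 and converted to Hz (x1000) only when reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

#: Synaptic reversal potential imposed by excitatory / inhibitory sources (mV).
V_SYN_EXC = 0.0
V_SYN_INH = -70.0

#: Synaptic decay time of outgoing synapses by source class (ms).
TAU_D_EXC = 2.0
TAU_D_INH = 5.0

LAYERS = ("L2/3", "L4", "L5", "L6")
CELL_CLASSES = ("excitatory", "inhibitory")


class ConfigurationError(ValueError):
    """Raised for physically inadmissible model parameters."""


def derive_qif_constants(g_L: float, C: float, V_R: float, V_T: float) -> Tuple[float, float, float]:
    """Quadratic-polynomial constants (zeta, eta, kappa) of the QIF voltage equation.

    The subthreshold voltage dynamics are written as
    ``dv/dt = zeta*v**2 + eta*v + kappa``, which factorises as
    ``zeta*(v - V_R)*(v - V_T)``: the two polynomial roots are exactly the
    resting potential and the firing threshold.

    Parameters
    ----------
    g_L : leak conductance, mS/cm^2.
    C : membrane capacitance, uF/cm^2.
    V_R, V_T : resting potential and firing threshold, mV (``V_T > V_R``).

    Returns
    -------
    (zeta, eta, kappa) with units 1/(mV ms), 1/ms, mV/ms respectively.
    """
    if V_T <= V_R:
        raise ConfigurationError(f"V_T ({V_T}) must exceed V_R ({V_R})")
    if g_L <= 0 or C <= 0:
        raise ConfigurationError("g_L and C must be positive")
    denom = C * (V_T - V_R)
    zeta = g_L / denom
    eta = -g_L * (V_T + V_R) / denom
    kappa = g_L * V_T * V_R / denom
    return zeta, eta, kappa


def qif_tonic_rate(zeta: float, eta: float, kappa: float, I: float) -> float:
    """Closed-form firing rate (ms^-1) of a single QIF neuron under constant drive.

    For suprathreshold drive the period is the quadrature of the voltage
    equation over the whole real line, giving ``rate = sqrt(D)/(2*pi)`` with
    discriminant ``D = 4*zeta*(kappa + I) - eta**2``.  Subthreshold drive
    (``D <= 0``) yields a stable fixed point and zero rate.
    """
    disc = 4.0 * zeta * (kappa + I) - eta * eta
    if disc <= 0.0:
        return 0.0
    return float(np.sqrt(disc) / (2.0 * np.pi))


def subthreshold_fixed_point(zeta: float, eta: float, kappa: float, I: float) -> float:
    """Smaller (stable) root of ``zeta*v**2 + eta*v + kappa + I = 0``.

    Raises :class:`ConfigurationError` if the drive is suprathreshold (no
    real root).
    """
    disc = eta * eta - 4.0 * zeta * (kappa + I)
    if disc < 0.0:
        raise ConfigurationError("drive is suprathreshold: no subthreshold fixed point")
    return float((-eta - np.sqrt(disc)) / (2.0 * zeta))


def uncoupled_steady_state(
    zeta: float, eta: float, kappa: float, C: float, I: float, delta: float
) -> Tuple[float, float]:
    """Steady state (r, v) of one isolated population with heterogeneity.

    Solves ``dr/dt = dv/dt = 0`` with all conductances zero: from the rate
    equation ``v(r) = -(eta*r + zeta*delta/(pi*C)) / (2*zeta*r)``, and the
    voltage equation becomes a scalar root problem in r, bracketed by the
    signs of its limits at r -> 0+ (positive, the quadratic dominates) and
    large r (negative, the rate feedback dominates).
    """
    from scipy.optimize import brentq

    if delta <= 0:
        raise ConfigurationError("delta must be positive")

    def v_of_r(r: float) -> float:
        return -(eta * r + zeta * delta / (np.pi * C)) / (2.0 * zeta * r)

    def F(r: float) -> float:
        v = v_of_r(r)
        return zeta * v * v + eta * v + kappa + I - (np.pi ** 2 / zeta) * r * r

    r = brentq(F, 1e-14, 10.0, xtol=1e-16, rtol=8.9e-16)
    return float(r), float(v_of_r(r))


@dataclass
class PopulationParams:
    """Biophysical and heterogeneity parameters of one neuronal population."""

    name: str
    cell_class: str           # "excitatory" | "inhibitory"
    layer: str                # "L2/3" | "L4" | "L5" | "L6"
    column: int               # 1 | 2
    C: float                  # membrane capacitance, uF/cm^2
    g_L: float                # leak conductance, mS/cm^2
    V_R: float                # resting potential, mV
    V_T: float                # firing threshold, mV
    N: int                    # neuron count
    I_back_center: float      # Lorentzian background-current center, mA/cm^2
    I_back_width: float       # Lorentzian background-current half-width, mA/cm^2
    proj_sensory: float = 0.0   # projection probability of bottom-up sensory input
    proj_attention: float = 0.0 # projection probability of top-down attention input
    zeta: float = field(init=False)
    eta: float = field(init=False)
    kappa: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ConfigurationError(f"unknown cell class {self.cell_class!r}")
        if self.N < 1:
            raise ConfigurationError(f"{self.name}: N must be >= 1")
        if self.I_back_width <= 0:
            raise ConfigurationError(f"{self.name}: I_back_width must be positive")
        if self.tau_d <= 0:
            raise ConfigurationError(f"{self.name}: tau_d must be positive")
        self.zeta, self.eta, self.kappa = derive_qif_constants(
            self.g_L, self.C, self.V_R, self.V_T
        )

    @property
    def is_excitatory(self) -> bool:
        return self.cell_class == "excitatory"

    @property
    def V_syn_out(self) -> float:
        """Reversal potential this population's outgoing synapses impose (mV)."""
        return V_SYN_EXC if self.is_excitatory else V_SYN_INH

    @property
    def tau_d(self) -> float:
        """Decay time of this population's outgoing synapses (ms)."""
        return TAU_D_EXC if self.is_excitatory else TAU_D_INH


@dataclass
class PopulationState:
    """Mean-field state of one population.

    ``g_exc_in`` / ``g_inh_in`` aggregate all excitatory / inhibitory afferent
    conductances onto the population; because the synaptic decay time depends
    only on the source class and the conductance ODE is linear, this
    aggregation is exactly equivalent to tracking one conductance per
    pathway.
    """

    r: float                  # firing rate, ms^-1
    v: float                  # mean membrane potential, mV
    g_exc_in: float = 0.0     # total excitatory conductance received, mS/cm^2
    g_inh_in: float = 0.0     # total inhibitory conductance received, mS/cm^2


@dataclass(frozen=True)
class Pathway:
    """Directed synaptic pathway between two populations."""

    source: str
    target: str
    P: float        # connection probability
    g_peak: float   # peak conductance, mS/cm^2

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ConfigurationError(f"{self.source}->{self.target}: P={self.P} outside [0, 1]")
        if self.g_peak <= 0.0:
            raise ConfigurationError(f"{self.source}->{self.target}: g_peak must be positive")


def rhs_arrays(
    r: np.ndarray,
    v: np.ndarray,
    g_exc: np.ndarray,
    g_inh: np.ndarray,
    zeta: np.ndarray,
    eta: np.ndarray,
    kappa: np.ndarray,
    C: np.ndarray,
    delta_back: np.ndarray,
    A_exc: np.ndarray,
    A_inh: np.ndarray,
    I_ext: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised mean-field right-hand side over all populations.

    ``A_exc[x, y] = g_peak * P * N_y`` for excitatory sources y (zero
    otherwise), so the conductance drive is ``A_exc @ r``; likewise
    ``A_inh`` for inhibitory sources.  ``I_ext`` is the total constant
    drive per population (background center + sensory + attention).

    The equations are the exact reduction of the heterogeneous QIF network
    under the Lorentzian ansatz.  With the voltage density's half-width x
    and center v, the firing rate is ``r = zeta*x/pi`` and the complex
    variable ``w = v + i*pi*r/zeta`` obeys the Riccati equation
    ``dw/dt = zeta*w**2 + eta*w + kappa + G + (I - i*Delta)/C`` (G:
    synaptic terms).  Expanding gives the rate source ``zeta*Delta/(pi*C)``
    together with the voltage feedback ``-(pi**2/zeta)*r**2``; this pairing
    is what keeps trajectories bounded (the half-plane r > 0 is invariant
    and the r**2 feedback caps synchronous voltage excursions).
    """
    g_sum = g_exc + g_inh
    dr = (2.0 * zeta * r * v + eta * r - r * g_sum / C
          + zeta * delta_back / (np.pi * C))
    dv = (
        zeta * v * v + eta * v + kappa
        - (np.pi ** 2 / zeta) * r * r
        + (g_exc * V_SYN_EXC + g_inh * V_SYN_INH - v * g_sum) / C
        + I_ext
    )
    dg_exc = -g_exc / TAU_D_EXC + A_exc @ r
    dg_inh = -g_inh / TAU_D_INH + A_inh @ r
    return dr, dv, dg_exc, dg_inh


def mean_field_rhs(
    states: Mapping[str, PopulationState],
    network,
    inputs: Mapping[str, Tuple[float, float]],
    t: float = 0.0,
) -> Dict[str, PopulationState]:
    """Mean-field derivative for every population, keyed by label.

    A pure function of its arguments.  ``inputs`` maps each population label
    to its ``(I_sens, I_attn)`` currents at time ``t``; the background-center
    current is taken from the population parameters.

    Raises ``FloatingPointError`` naming the offending population if any
    state component is non-finite.
    """
    labels = network.labels
    for lab in labels:
        st = states[lab]
        if not all(np.isfinite([st.r, st.v, st.g_exc_in, st.g_inh_in])):
            raise FloatingPointError(f"non-finite state in population {lab} at t={t} ms")

    arrs = network.const_arrays()
    A_exc, A_inh = network.coupling_matrices()
    r = np.array([states[lab].r for lab in labels])
    v = np.array([states[lab].v for lab in labels])
    ge = np.array([states[lab].g_exc_in for lab in labels])
    gi = np.array([states[lab].g_inh_in for lab in labels])
    I_ext = arrs["I_back_center"] + np.array(
        [inputs[lab][0] + inputs[lab][1] for lab in labels]
    )
    dr, dv, dge, dgi = rhs_arrays(
        r, v, ge, gi,
        arrs["zeta"], arrs["eta"], arrs["kappa"], arrs["C"], arrs["I_back_width"],
        A_exc, A_inh, I_ext,
    )
    return {
        lab: PopulationState(r=dr[i], v=dv[i], g_exc_in=dge[i], g_inh_in=dgi[i])
        for i, lab in enumerate(labels)
    }
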