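"""Finite-N spiking QIF network: a brute-force check of the mean-field limit.

Each neuron integrates the quadratic voltage equation with conductance-based
synapses; its background current is drawn once from the population's
Lorentzian distribution via the inverse CDF.  A spike occurs when the
voltage crosses a finite cutoff ``V_peak`` (the exact reduction takes the
cutoff to infinity; the period error of a finite symmetric cutoff is
quadratically small) and the voltage resets to ``V_reset``.  Connectivity
is realized as independent Bernoulli draws per (source, target) neuron
pair, and conductance increments are scaled by ``1/scale`` so the expected
synaptic drive matches the full-size network at reduced neuron counts.

This module validates the reduction on small fixtures; the study's results
themselves are produced by the mean-field equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .model_core import (
    ConfigurationError,
    TAU_D_EXC,
    TAU_D_INH,
    V_SYN_EXC,
    V_SYN_INH,
)
from .network_builder import NetworkSpec
from .stimuli import StimulusCondition, steady_currents


@dataclass
class MicroNetConfig:
    """Settings of the finite-N simulation."""

    scale: float = 0.1          # fraction of the nominal neuron counts
    V_peak: float = 200.0       # mV, spike cutoff
    V_reset: float = -320.0     # mV, reset potential
    seed: int = 0
    dt: float = 0.01            # ms
    bin_ms: float = 1.0         # population-rate bin width
    clip_quantiles: Optional[Tuple[float, float]] = (0.001, 0.999)
    stratified_currents: bool = True   # quantile-stratified Lorentzian draws

    def __post_init__(self) -> None:
        if not 0.0 < self.scale <= 1.0:
            raise ConfigurationError("scale must be in (0, 1]")
        if self.V_peak <= -55.0 or self.V_reset >= -62.0:
            raise ConfigurationError(
                "V_peak must exceed the threshold and V_reset lie below rest"
            )


def lorentzian_currents(
    center: float,
    width: float,
    n: int,
    rng: np.random.Generator,
    clip_quantiles: Optional[Tuple[float, float]] = None,
    stratified: bool = True,
) -> np.ndarray:
    """Draw ``n`` background currents from a Lorentzian via the inverse CDF.

    ``I = center + width * tan(pi * (u - 1/2))``; the quantile range may be
    restricted to exclude pathological outliers in tiny populations.  By
    default the quantiles are stratified (one per equal-probability bin, in
    shuffled order), so the realized sample matches the distribution's
    quantile function exactly and the only sampling noise left at small N
    is which neuron carries which current; ``stratified=False`` gives plain
    i.i.d. draws.
    """
    lo, hi = clip_quantiles if clip_quantiles is not None else (0.0, 1.0)
    if stratified:
        u = lo + (hi - lo) * (np.arange(n) + 0.5) / n
        u = rng.permutation(u)
    else:
        u = rng.uniform(lo, hi, size=n)
    return center + width * np.tan(np.pi * (u - 0.5))


def simulate_micro(
    spec: NetworkSpec,
    cond: StimulusCondition,
    micro: MicroNetConfig,
    t_total: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the spiking network.

    Returns ``(spike_times_ms, spike_neuron_ids, bin_centers_ms, rates)``
    where ``rates`` has shape (n_bins, n_populations) in Hz, aligned to the
    population order of ``spec``.
    """
    rng = np.random.default_rng(micro.seed)
    n_pops = spec.n_populations

    counts = np.array(
        [max(int(round(p.N * micro.scale)), 0) for p in spec.populations]
    )
    if (counts < 10).any():
        small = [spec.labels[i] for i in np.nonzero(counts < 10)[0]]
        raise ConfigurationError(
            f"scale {micro.scale} leaves populations too small (<10): {small}"
        )
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n_total = int(offsets[-1])
    neuron_pop = np.repeat(np.arange(n_pops), counts).astype(np.int64)

    # per-population QIF constants and per-neuron background currents
    zeta = np.array([p.zeta for p in spec.populations])
    eta = np.array([p.eta for p in spec.populations])
    kappa = np.array([p.kappa for p in spec.populations])
    C_inv = np.array([1.0 / p.C for p in spec.populations])
    I_back = np.concatenate([
        lorentzian_currents(p.I_back_center, p.I_back_width, counts[i], rng,
                            micro.clip_quantiles, micro.stratified_currents)
        for i, p in enumerate(spec.populations)
    ]) if n_total else np.empty(0)

    # Bernoulli connectivity, CSR by source neuron.  The increment per spike
    # is g_peak / scale so the expected drive g_peak * P * N_full * r of the
    # mean-field limit is preserved at reduced size.
    targets_per_source = [[] for _ in range(n_total)]
    weights_per_source = [[] for _ in range(n_total)]
    is_exc_source = np.zeros(n_total, dtype=np.bool_)
    for i, p in enumerate(spec.populations):
        sl = slice(offsets[i], offsets[i + 1])
        is_exc_source[sl] = p.is_excitatory
    for pw in spec.pathways:
        if pw.P == 0.0:
            continue
        si = spec.index(pw.source)
        ti = spec.index(pw.target)
        n_src = counts[si]
        n_tgt = counts[ti]
        mask = rng.random((n_src, n_tgt)) < pw.P
        src_base = offsets[si]
        tgt_base = offsets[ti]
        # Per-target in-degree normalization: each target receives exactly
        # the pathway drive g_peak * P * N_full * r of the mean-field limit
        # regardless of its realized connection count, which removes the
        # quenched in-degree disorder that Bernoulli draws add at small N.
        in_degree = mask.sum(axis=0)
        N_full = spec.populations[si].N
        with np.errstate(divide="ignore"):
            w_per_target = np.where(
                in_degree > 0, pw.g_peak * pw.P * N_full / in_degree, 0.0
            )
        for k in range(n_src):
            cols = np.nonzero(mask[k])[0]
            if len(cols):
                targets_per_source[src_base + k].extend((tgt_base + cols).tolist())
                weights_per_source[src_base + k].extend(
                    w_per_target[cols].tolist()
                )

    conn_indptr = np.zeros(n_total + 1, dtype=np.int64)
    for i, tl in enumerate(targets_per_source):
        conn_indptr[i + 1] = conn_indptr[i] + len(tl)
    conn_targets = np.empty(conn_indptr[-1], dtype=np.int64)
    conn_weights = np.empty(conn_indptr[-1])
    for i, (tl, wl) in enumerate(zip(targets_per_source, weights_per_source)):
        conn_targets[conn_indptr[i]:conn_indptr[i + 1]] = tl
        conn_weights[conn_indptr[i]:conn_indptr[i + 1]] = wl

    # background current is per-neuron (I_back); stimulus is per-population
    I_sens, I_attn = steady_currents(cond, spec)
    I_pre_pop = np.zeros(n_pops)
    I_post_pop = I_sens + I_attn

    V0 = np.full(n_total, -62.0)
    ge0 = np.zeros(n_total)
    gi0 = np.zeros(n_total)

    n_steps = int(round(t_total / micro.dt))
    onset_step = int(round(cond.onset / micro.dt))
    bin_steps = max(1, int(round(micro.bin_ms / micro.dt)))

    spike_times, spike_ids, rate_bins, status, bad_step = _kernels.euler_micro(
        V0, ge0, gi0, I_back,
        zeta, eta, kappa, C_inv,
        conn_indptr, conn_targets, conn_weights,
        is_exc_source,
        neuron_pop,
        micro.dt, n_steps, onset_step,
        I_pre_pop, I_post_pop,
        micro.V_peak, micro.V_reset, TAU_D_EXC, TAU_D_INH,
        V_SYN_EXC, V_SYN_INH,
        bin_steps, n_pops, counts.astype(np.float64),
    )
    if status != _kernels.OK:
        raise RuntimeError(
            f"microscopic simulation diverged at t={bad_step * micro.dt:.2f} ms"
        )
    n_bins = rate_bins.shape[0]
    bin_centers = (np.arange(n_bins) + 0.5) * bin_steps * micro.dt
    return spike_times, spike_ids, bin_centers, rate_bins * 1000.0  # ms^-1 -> Hz
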