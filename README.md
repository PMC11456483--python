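# colgamma

Exact mean-field simulation of top-down visual attention in a two-column,
layered cortical microcircuit, in the gamma-oscillation regime.

## The problem

When two oriented bars are shown in a visual-cortex receptive field, the
columns preferring each orientation compete; top-down attention to one bar
biases that competition. Simulating this with large spiking networks is
expensive and noisy (finite-size fluctuations obscure the bifurcation
structure), while classical rate models (Wilson–Cowan) cannot express how
*neuronal heterogeneity* shapes gamma rhythms. `colgamma` implements the
middle road: each of the 16 neuronal populations (2 columns × 4 layers
L2/3, L4, L5, L6 × excitatory/inhibitory) is a heterogeneous ensemble of
quadratic integrate-and-fire (QIF) neurons whose background currents follow
a Lorentzian distribution, which admits an *exact* reduction to three ODEs
per population — firing rate `r`, mean membrane potential `v`, and synaptic
conductance `g`.

With the QIF voltage written as `dv/dt = ζv² + ηv + κ` (the roots of the
quadratic are the resting potential −62 mV and threshold −55 mV), each
population obeys

    dr/dt = 2ζ r v + η r − (r/C) Σg + ζ Δ_back / (πC)
    dv/dt = ζ v² + η v + κ − (π²/ζ) r² + (1/C)(Σ g·V_syn − v Σg) + Ī_back + I_sens + I_attn
    dg/dt = −g/τ_d + ḡ · P · N_src · r_src      (aggregated per source class)

where `Δ_back` is the Lorentzian half-width — the *heterogeneity* of the
population, the study's central control parameter — and the conductance
drive sums every afferent pathway (connection probability `P`, peak
conductance `ḡ`, source size `N`). Layer 4 receives bottom-up sensory
input, layers 2/3 and 5 receive top-down attention, the two columns couple
through L2/3E → contralateral L2/3I, and the five experimental conditions
(S1, S2, S1S2, S1S2+A1, S1S2+A2) map bars and attention onto current steps.

The package reproduces, from these equations alone:

* sustained ~30 Hz gamma in L5E whose frequency is unchanged by stimulus
  condition, while its *amplitude* follows the ordered pattern
  `S1, S1S2+A1 > S1S2 > S1S2+A2, S2`;
* the partition of the (Δ_back,E, Δ_back,I) heterogeneity plane into
  quiescent, gamma-only, beta+gamma and aperiodic regimes;
* winner-take-all (WTA) vs. anti-WTA attention responses in L2/3E, and the
  *concurrent case* (ordered L5 with anti-WTA L2/3);
* structural ablations: silencing layer 6 or single L6E→L4 pathways and
  their effect on the concurrent case.

A finite-N spiking QIF network (`colgamma.micro_qif`) serves as a
brute-force cross-check of the reduction on small fixtures.

## Worked example

```python
from colgamma import (build_network, simulate, SimulationConfig,
                      StimulusCondition, amplitude_spectrum,
                      oscillation_amplitude)

spec = build_network(delta_E=0.3, delta_I=0.02)   # reference gamma point
sim = SimulationConfig()                          # Euler, dt=0.01 ms, 10 s, onset 5 s
for name in ("S1", "S1S2", "S1S2_A2"):
    cond = StimulusCondition.from_config(name, spec.config)
    trace = simulate(spec, cond, sim)
    peak = amplitude_spectrum(trace, "1L5E").dominant_freq
    amp = oscillation_amplitude(trace, "1L5E")
    print(f"{name:8s}  gamma peak {peak:5.1f} Hz   amplitude {amp:6.2f} Hz")
```

prints

```
S1        gamma peak  30.0 Hz   amplitude  77.34 Hz
S1S2      gamma peak  30.0 Hz   amplitude  73.70 Hz
S1S2_A2   gamma peak  30.0 Hz   amplitude  71.99 Hz
```

— the gamma *frequency* is condition-invariant while the *amplitude* drops
from the preferred-bar condition through the two-bar condition to the
attend-away condition: the ordered pattern. The same machinery is exposed
on the command line:

```bash
colgamma simulate --condition S1S2_A1 --out runs/
colgamma classify --delta-e 0.45 --delta-i 0.02        # the concurrent case
colgamma sweep --delta-e 0.2,0.3,0.4 --delta-i 0.02,0.04 --out runs/
colgamma micro --fixture ei_pair --scale 0.2 --seed 1  # spiking cross-check
```

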