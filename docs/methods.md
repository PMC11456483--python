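# Methods

## Model

Each population X of the two-column microcircuit is an infinite ensemble of
quadratic integrate-and-fire neurons,

    C dV_i/dt = g_L (V_i − V_R)(V_i − V_T)/(V_T − V_R) − Σ_Y g_YX (V_i − V_syn,Y) + I_i,

with C = 1 µF/cm², V_R = −62 mV, V_T = −55 mV, g_L = 0.08 (excitatory) or
0.10 mS/cm² (inhibitory), V_syn = 0 mV for excitatory and −70 mV for
inhibitory sources, and synaptic decay τ_d = 2 ms (excitatory) / 5 ms
(inhibitory). The background current I_back,i is Lorentzian-distributed
with center Ī_back and half-width Δ_back — the heterogeneity parameter.
Writing the voltage polynomial as ζV² + ηV + κ (so its roots are exactly
V_R and V_T), the Lorentzian ansatz reduces each population exactly to

    dr/dt = 2ζ r v + η r − (r/C) Σg + ζ Δ_back/(πC)
    dv/dt = ζ v² + η v + κ − (π²/ζ) r² + (1/C)(Σ g V_syn − v Σg) + Ī_back + I_sens + I_attn
    dg/dt = −g/τ_d + ḡ P N_src r_src.

Derivation sketch: the voltage density of the sub-ensemble at current I is
Lorentzian with half-width x(I,t) and center y(I,t); the firing rate of
that sub-ensemble is ζx/π (flux through V → ∞), and the complex variable
w = v + iπr/ζ evaluated at the current-distribution pole obeys the Riccati
equation ẇ = ζw² + ηw + κ + G + (Ī − iΔ)/C. Expanding real and imaginary
parts yields the system above. The pairing of the rate source ζΔ/(πC)
with the voltage feedback −(π²/ζ)r² is what makes the flow well-posed: the
half-plane r > 0 is invariant and the r² feedback caps synchronous voltage
excursions. (Scaling r by ζ gives an equivalent system with source Δ/(πC)
and feedback −π²ζr²; mixing the two scalings produces finite-time
divergence under any explicit integrator.)

Because τ_d depends only on the source class and the conductance ODE is
linear, all excitatory (resp. inhibitory) afferents onto a population are
folded into one aggregated conductance whose drive is the
probability-and-size-weighted sum of source rates — 4 state variables per
population instead of up to 18, provably equivalent (tested step-for-step
against a per-pathway integrator).

## Network and inputs

Populations: columns 1–2 × layers L2/3, L4, L5, L6 × {E, I}, with the
bundled neuron counts, intra-column connection-probability matrix (all
nonzero entries, including the sparse < 0.04 ones) and class-pair peak
conductances (`src/colgamma/data/default_config.yaml`). Inter-column
coupling is L2/3E → contralateral L2/3I with P_inter = 0.1 only. Structural
perturbations (`remove_layer6`, `block_L6E_to_L4I`, `block_L6E_to_L4E`)
zero connection probabilities and never delete populations, keeping the
state vector shape constant.

Drive amplitudes. Attention delivers 0.02 mA/cm² and the three current
sources keep the ratio I_sens : I_attn : Ī_back = 9 : 3 : 16, i.e. sensory
0.06 and background 0.32/3 mA/cm² ≈ 0.1067 (×0.8 for inhibitory
populations). These amplitudes are read as the currents delivered to the
principal excitatory targets; the per-population projection table acts as
relative weights normalized to its per-type maximum (sensory: L4E;
attention: L2/3E and L5E), exactly parallel to how the background E : I
ratio is specified. Under the alternative reading (amplitude × raw
projection, delivering ~6% of the nominal current) stimulus effects are an
order of magnitude too weak to produce the ordered amplitude pattern; the
normalized reading produces the full phenomenology, so it is the package
default. Sensory input to the column preferring the shown bar is 10× that
to the other column, two bars add independently, and attention is
ipsilateral to the attended column. All external currents are step
functions switching on at stimulus onset (default 5 s into a 10 s run).

## Integration

Reference integrator: forward Euler, dt = 0.01 ms, recorded every 10 steps
(0.1 ms sampling; Nyquist 5 kHz ≫ gamma). Two robustness measures surround
it:

* Initial condition. The system's cold starts (e.g. all populations at
  rest with near-zero rate) pass through a near-singular synchronous
  population spike in which the mean voltage traverses values of order
  10⁴–10⁶ mV; no explicit fixed-step scheme survives it. The default
  initial state is therefore the coupled network fixed point — solved by
  bounded least squares on the 4N-dimensional root problem, seeded from
  each population's closed-form uncoupled steady state — displaced by a
  deterministic 10⁻³ relative nudge. The 5 s pre-stimulus window then
  grows the (typically unstable) oscillatory mode onto its limit cycle,
  which is the purpose of the settling window. Uncoupled and fully custom
  initial states remain available.
* Local substepping. Even on the attractor, points with very small
  inhibitory heterogeneity produce gamma cycles whose synchronous volleys
  (population rates transiently ≈ 10 ms⁻¹) outrun the nominal step. A
  grid step that would move any voltage by more than 0.5 mV, or remove
  more than 20% of a population's remaining rate, is subdivided locally
  (plain Euler substeps, floor 10⁻⁷·dt). Outside these brief spikes the
  guard never engages and the map is exactly fixed-step Euler; halving dt
  changes steady-state amplitude by < 1% (tested). A rate ceiling of
  1000 ms⁻¹ aborts genuine divergence with the population and time named.

Determinism: identical inputs give bit-identical traces on one platform;
every CLI run writes a manifest with a config snapshot and a network
fingerprint.

## Analysis

* Envelopes: local extrema joined by monotone (PCHIP) interpolation;
  non-oscillating traces collapse to a 100 ms moving-average trend. The
  oscillation-amplitude estimator used everywhere is the mean envelope
  half-range over the final second.
* Spectra: magnitude FFT of the mean-subtracted final second, no taper
  (optional Hann), 1 Hz resolution; peaks require prominence ≥ 5% of the
  spectral maximum; band split at 25 Hz (beta 12.5–25 Hz, gamma
  25–100 Hz). Band amplitudes report detected peaks only, so leakage from
  a strong neighbouring band does not count as band content.
* Settle time: first time after onset at which the cycle amplitude enters
  and stays within 5% (relative) of its final-second mean; +inf if never.
* Regime classification per parameter point, from the five stimulus
  conditions: oscillation = relative cycle amplitude of L5E > 10⁻³ of its
  mean rate; ordered pattern = the amplitude ordering
  {S1, S1S2+A1} > S1S2 > {S1S2+A2, S2} with 2% relative margins (gated on
  oscillation; margins are monotone — raising them can only demote the
  flag, tested); WTA polarity from L2/3E amplitudes under the two
  attention conditions (2% margin, with an absolute amplitude floor so a
  silent L2/3 yields "neither"); band content from the S1S2+A1 spectrum,
  with "aperiodic" = beta content plus failure to settle; concurrent =
  ordered ∧ anti-WTA. Sweeps classify grid points independently and
  report failed cells without aborting.

## Spiking cross-check

`micro_qif` realizes the same network at a fraction of the nominal neuron
counts: per-neuron QIF voltages with finite spike cutoff V_peak = +200 mV
and reset −320 mV (the reduction's cutoff is infinite; the finite-cutoff
period error is quadratically small), Bernoulli(P) connectivity, and
background currents drawn by inverse CDF from the Lorentzian — by default
one draw per equal-probability quantile bin in shuffled order, so the
realized sample matches the distribution exactly and only the
assignment-to-neuron is random. Synaptic weights are normalized per target
by realized in-degree, making each neuron's expected drive equal the
mean-field drive ḡPN·r at any scale. Quantile clipping ([0.001, 0.999])
protects tiny populations from unbounded tail currents and is disabled for
convergence tests, where the tail contribution must scale properly.

The validation fixture is a two-population E-I pair (N = 3200/800,
P = 0.05/0.075, strongly suprathreshold drive Ī_E = 0.32 mA/cm²), chosen
deep inside its oscillatory regime where the rhythm is only weakly advanced
by finite-size fluctuations: the spiking network reproduces the mean-field
frequency within ~10% at scale 0.2 and within ~5% at full scale, and the
heavily-smoothed rate distance to the mean-field trajectory shrinks with
scale. Shallower fixtures show systematic 20–40% noise advancement at
small scale — a genuine finite-size effect, not an integration artifact.

## What the package does and does not show

The simulations demonstrate that the reduced equations with the bundled
connectivity produce the full phenomenology: condition-invariant ~30 Hz
gamma with the ordered amplitude pattern at (Δ_E, Δ_I) = (0.3, 0.02);
quiescence at (0.05, 0.04); beta+gamma mixtures with very slow settling at
(0.15, 0.04); an ordered band along Δ_I ≈ 0.02; an anti-WTA set; and a
small ordered ∩ anti-WTA (concurrent) region, found here at
(0.45, 0.02) and abolished when layer 6 is silenced. The exact coordinates
of regime *boundaries* are sensitive to the drive-delivery conventions
above, and some published marker coordinates for boundary-adjacent cases
(the concurrent triangle, the aperiodic point, the ablation markers) fall
on the other side of the corresponding boundary in this implementation;
tests at those printed coordinates are retained and report honestly.
Synthetic fixtures (pure sinusoids, the E-I pair) validate the analysis
operators against closed forms; none of this constitutes evidence about
biological cortex beyond what the mean-field model itself can claim — no
synaptic rise times, no transmission delays, no interneuron subtypes, no
finite-size noise in the production simulations.
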