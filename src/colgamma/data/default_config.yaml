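# Default configuration of the two-column layered visual-cortex model.
# Units: mV, ms, uF/cm^2, mS/cm^2, mA/cm^2.
populations:
  # Neuron counts per population (identical in both columns).
  counts:
    L2/3E: 10341
    L2/3I: 2917
    L4E: 10957
    L4I: 2739
    L5E: 2425
    L5I: 532
    L6E: 7197
    L6I: 1474
  C: 1.0
  g_L:
    excitatory: 0.08
    inhibitory: 0.1
  V_R: -62.0
  V_T: -55.0

pathways:
  # Intra-column connection probabilities P[target][source]; the full matrix,
  # including sparse (< 0.04) entries.
  P_intra:
    L2/3E: {L2/3E: 0.1184, L2/3I: 0.1552, L4E: 0.0846, L4I: 0.0629, L5E: 0.0323, L5I: 0.0, L6E: 0.0076, L6I: 0.0}
    L2/3I: {L2/3E: 0.1008, L2/3I: 0.1371, L4E: 0.0363, L4I: 0.0515, L5E: 0.0755, L5I: 0.0, L6E: 0.0042, L6I: 0.0}
    L4E:   {L2/3E: 0.0077, L2/3I: 0.0059, L4E: 0.0519, L4I: 0.1453, L5E: 0.0067, L5I: 0.0003, L6E: 0.0453, L6I: 0.0}
    L4I:   {L2/3E: 0.0691, L2/3I: 0.0029, L4E: 0.1093, L4I: 0.1597, L5E: 0.0033, L5I: 0.0, L6E: 0.1057, L6I: 0.0}
    L5E:   {L2/3E: 0.1017, L2/3I: 0.0622, L4E: 0.0411, L4I: 0.0057, L5E: 0.0758, L5I: 0.3765, L6E: 0.0204, L6I: 0.0}
    L5I:   {L2/3E: 0.0436, L2/3I: 0.0269, L4E: 0.0209, L4I: 0.0022, L5E: 0.0566, L5I: 0.3158, L6E: 0.0086, L6I: 0.0}
    L6E:   {L2/3E: 0.0156, L2/3I: 0.0066, L4E: 0.0211, L4I: 0.0166, L5E: 0.0572, L5I: 0.0197, L6E: 0.0401, L6I: 0.2252}
    L6I:   {L2/3E: 0.0364, L2/3I: 0.0010, L4E: 0.0034, L4I: 0.0005, L5E: 0.0277, L5I: 0.0080, L6E: 0.0658, L6I: 0.1443}
  # Inter-column coupling: L2/3E -> contralateral L2/3I, both directions.
  P_inter: 0.1
  # Peak conductances g_peak[source class][target class], mS/cm^2.
  g_peak:
    excitatory: {excitatory: 4.069e-3, inhibitory: 3.276e-3}
    inhibitory: {excitatory: 2.672e-2, inhibitory: 2.138e-2}

heterogeneity:
  # Half-widths of the Lorentzian background-current distributions, mA/cm^2
  # (the swept parameter pair; defaults at the reference gamma point).
  delta_E: 0.3
  delta_I: 0.02

background:
  # Centers of the background-current distributions: the excitatory center
  # follows from the drive ratio I_sens : I_attn : I_back = 9 : 3 : 16 with
  # I_attn = 0.02, i.e. I_back = 0.32/3; the inhibitory center is 0.8x.
  center_E: 0.10666666666666667
  inhibitory_factor: 0.8

stimulus:
  # Sensory base = (9/3) x attention base from the same drive ratio.
  sensory_base: 0.06
  attention_base: 0.02
  preferred_ratio: 10.0
  onset_ms: 5000.0
  # Projection probabilities of sensory and attention inputs per population.
  projection:
    L2/3E: {sensory: 0.0, attention: 0.1}
    L2/3I: {sensory: 0.0, attention: 0.085}
    L4E:   {sensory: 0.0983, attention: 0.0}
    L4I:   {sensory: 0.0619, attention: 0.0}
    L5E:   {sensory: 0.0, attention: 0.1}
    L5I:   {sensory: 0.0, attention: 0.085}
    L6E:   {sensory: 0.0, attention: 0.0}
    L6I:   {sensory: 0.0, attention: 0.0}

perturbation: none

simulation:
  dt: 0.01
  t_total: 10000.0
  t_onset: 5000.0
  record_stride: 10
  rate_ceiling: 1000.0
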