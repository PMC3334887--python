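# Default MSPN morphology and passive parameters.
#
# Branch lengths are printed model values; diameters and soma dimensions are
# inherited-lineage defaults (tunable). The soma is a cylinder. Passive
# parameters are the documented tuning step: membrane resistivity and leak
# reversal set jointly with Kir so the cell rests near -85 mV and shows the
# inwardly-rectifying I-V relation.
soma: {length_um: 16.0, diameter_um: 16.0}
primary:   {count: 4, length_um: 20.0, diameter_um: 2.25}
secondary: {per_primary: 2, length_um: 24.0, diameter_um: 1.10}
tertiary:  {per_secondary: 2, segments: 11, segment_length_um: 36.0, diameter_um: 0.72}

passive:
  membrane_resistivity_ohm_m2: 3.0
  membrane_capacitance_F_m2: 0.01
  axial_resistivity_ohm_m: 1.0
  leak_reversal_mV: -65.0
  resting_potential_target_mV: -85.0

spine:
  neck_length_um: 0.5
  neck_diameter_um: 0.12
  head_length_um: 0.5
  head_diameter_um: 0.5

# Implicit-spine membrane correction: dendritic membrane capacitance is
# multiplied and membrane resistance divided by
#   f = 1 + density * area_per_spine / area_per_um_of_shaft
spine_compensation:
  density_per_um: 1.0
  regions: [prox_dend, mid_dend, dist_dend]

# Default stimulation sites: two adjacent spines each.
sites:
  secondary:          # ~40 um path distance from the soma
    parent: p0.s0
    positions: [0.79, 0.84]
  tertiary:           # third tertiary segment, ~150 um from the soma
    parent: p0.s0.t0.seg3
    positions: [0.92, 0.97]

# Numerical discretization: morphological sections are subdivided into
# electrical segments no longer than this (kept well below the AC length
# constant so backpropagating spikes attenuate realistically).
electrical:
  max_segment_um: 12.0

calcium:
  rest_uM: 0.05
  decay_tau_ms: 105.0           # NMDA spine pool
  shaft_decay_tau_ms: 12.0      # submembrane shell pools feeding BK/SK
  shell_thickness_um: 0.1       # submembrane shell for shaft pools
  buffer_capacity_shaft: 20.0   # rapid-buffer scaling of effective volume
  buffer_capacity_spine: 250.0  # calibrated: no-AP spine peaks ~ few uM
  nmda_ca_fraction: 0.1         # fraction of NMDA current carried by Ca at -65 mV
  nmda_ca_driving: linear       # "linear" (V - E_Ca) or "ghk" driving term
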