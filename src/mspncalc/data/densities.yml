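# Per-region maximal conductance densities (Gbar, S/m^2) and maximal calcium
# permeabilities (Pbar, m/s) for the MSPN model.
# Regions: soma, prox_dend (primary dendrites), mid_dend (secondary dendrites
# plus the first tertiary segment), dist_dend (tertiary segments 2-11),
# spine (explicit spine heads).
gbar:
  NaF:    {soma: 90000.0, prox_dend: 2730.0, mid_dend: 2730.0, dist_dend: 975.0, spine: 0.0}
  KaF:    {soma: 765.24, prox_dend: 765.24, mid_dend: 168.21, dist_dend: 112.14, spine: 0.0}
  KaS:    {soma: 360.1, prox_dend: 38.93, mid_dend: 38.93, dist_dend: 38.93, spine: 0.0}
  Kir:    {soma: 8.0, prox_dend: 8.0, mid_dend: 8.0, dist_dend: 8.0, spine: 0.0}
  Kdr:    {soma: 6.04, prox_dend: 6.04, mid_dend: 6.04, dist_dend: 6.04, spine: 0.0}
  SK:     {soma: 2.0, prox_dend: 2.0, mid_dend: 2.0, dist_dend: 2.0, spine: 0.0}
  BK:     {soma: 10.0, prox_dend: 10.0, mid_dend: 10.0, dist_dend: 10.0, spine: 0.0}
pbar:
  CaL1.3: {soma: 1.59e-07, prox_dend: 1.59e-07, mid_dend: 1.59e-07, dist_dend: 1.59e-07, spine: 4.25e-07}
  CaT:    {soma: 8.81e-09, prox_dend: 8.81e-09, mid_dend: 8.81e-09, dist_dend: 8.81e-09, spine: 2.35e-08}
  CaR:    {soma: 9.75e-07, prox_dend: 9.75e-07, mid_dend: 9.75e-07, dist_dend: 9.75e-07, spine: 1.30e-06}
  CaN:    {soma: 3.75e-07, prox_dend: 3.75e-07, mid_dend: 3.75e-07, dist_dend: 3.75e-07, spine: 0.0}
  CaL1.2: {soma: 1.26e-07, prox_dend: 1.26e-07, mid_dend: 1.26e-07, dist_dend: 1.26e-07, spine: 3.35e-07}
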