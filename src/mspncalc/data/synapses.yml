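# Glutamatergic synapse parameters.
#
# NMDA decay time constants are the temperature-scaled values (already divided
# by 2 relative to the room-temperature single-exponential fits).
# "mg_A" is the subunit-dependent magnesium-block concentration parameter (mM)
# of the voltage-dependent block 1/(1 + ([Mg]/A) exp(-V/16.129 mV)).

ampa:
  gmax_pS: 342.0
  tau1_ms: 1.1
  tau2_ms: 5.75
  reversal_mV: 0.0

nmda:
  tau1_ms: 2.25            # activation, shared by all subunits
  reversal_mV: 0.0
  subunits:
    GluN2A: {gmax_nS: 0.94, tau_decay_ms: 25.0, mg_A_mM: 3.57}
    GluN2B: {gmax_nS: 0.94, tau_decay_ms: 150.0, mg_A_mM: 3.57}
    GluN2C: {gmax_nS: 0.325, tau_decay_ms: 125.0, mg_A_mM: 25.0}
    GluN2D: {gmax_nS: 0.119, tau_decay_ms: 850.0, mg_A_mM: 40.0}
  mixture:                 # striatal GluN2A/B heteromeric population
    glun2b_fraction: 0.25
    gmax_nS: 0.94
    mg_A_mM: 3.57

# Cortico- vs thalamo-striatal synaptic characterizations (two datasets).
# ding: mouse; NMDA kinetics given as a GluN2B fraction of an A/B mixture.
# smeal: rat; NMDA kinetics given directly as a decay time constant.
sources:
  ding:
    cortical:  {nmdar_ampar_ratio: 2.75, glun2b_fraction: 0.25}
    thalamic:  {nmdar_ampar_ratio: 2.04, glun2b_fraction: 0.42}
  smeal:
    cortical:  {nmdar_ampar_ratio: 1.52, tau_decay_ms: 116.5}
    thalamic:  {nmdar_ampar_ratio: 2.6,  tau_decay_ms: 96.5}

extracellular:
  ca_out_mM: 2.0
  mg_mM: 1.0
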