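# Voltage- and calcium-gated channel kinetics for the striatal MSPN model.
#
# Units: vhalf/slope in mV, rate in 1/s, tau tables and fixed taus in ms,
# "scale" is the dimensionless tuning multiplier applied to time constants.
# Sigmoid convention: inf(v) = rate / (1 + exp((v - vhalf)/slope)); a negative
# slope gives activation (opens with depolarization), a positive slope gives
# inactivation or inward-rectifier activation.
#
# NaF and Kir time constants are table-driven ("tab"); the shipped defaults
# are smooth curves from the source kinetics lineage sampled on a 5 mV grid,
# and are deliberately exposed here as editable data (they are part of the
# documented tuning step, together with "scale").
#
# Voltage-gated calcium channels use the model-lineage gate parameters
# (single activation power, see note below) with fixed time constants; their
# exact values do not feed the NMDA-pool observable.

temperature: 305.0        # K (tuning data at 30-32 C)
reversals_mV:
  na: 50.0
  k: -90.0
mg_voltage_scale_mV: 16.129   # 1/62 V, shared by all NMDA Mg-block variants

tau_table_v_mV: [-120.0, -115.0, -110.0, -105.0, -100.0, -95.0, -90.0, -85.0,
                 -80.0, -75.0, -70.0, -65.0, -60.0, -55.0, -50.0, -45.0,
                 -40.0, -35.0, -30.0, -25.0, -20.0, -15.0, -10.0, -5.0, 0.0,
                 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0,
                 55.0, 60.0]

channels:
  NaF:
    mode: ohmic
    reversal: na
    gates:
      - name: m
        exponent: 3
        form: sigmoid_tab
        vhalf: -25.0
        slope: -9.2
        rate: 1.0
        scale: 1.2
        tau_table_ms: [0.0301, 0.0304, 0.0309, 0.0322, 0.0347, 0.0393, 0.0469,
                       0.0584, 0.0741, 0.0933, 0.1137, 0.1323, 0.1453, 0.1500,
                       0.1453, 0.1323, 0.1137, 0.0933, 0.0741, 0.0584, 0.0469,
                       0.0393, 0.0347, 0.0322, 0.0309, 0.0304, 0.0301, 0.0300,
                       0.0300, 0.0300, 0.0300, 0.0300, 0.0300, 0.0300, 0.0300,
                       0.0300, 0.0300]
      - name: h
        exponent: 1
        form: sigmoid_tab
        vhalf: -62.0
        slope: 6.0
        rate: 1.0
        scale: 1.2
        tau_table_ms: [0.2004, 0.2021, 0.2090, 0.2333, 0.3060, 0.4891, 0.8756,
                       1.5530, 2.5220, 3.6152, 4.5047, 4.8500, 4.5047, 3.6152,
                       2.5220, 1.5530, 0.8756, 0.4891, 0.3060, 0.2333, 0.2090,
                       0.2021, 0.2004, 0.2001, 0.2000, 0.2000, 0.2000, 0.2000,
                       0.2000, 0.2000, 0.2000, 0.2000, 0.2000, 0.2000, 0.2000,
                       0.2000, 0.2000]
  Kir:
    mode: ohmic
    reversal: k
    gates:
      - name: m
        exponent: 1
        form: sigmoid_tab
        vhalf: -102.0
        slope: 13.0
        rate: 1.0
        scale: 0.5
        tau_table_ms: [35.5, 37.6, 39.2, 40.3, 40.8, 40.3, 39.2, 37.6, 35.5,
                       33.2, 30.9, 28.6, 26.6, 24.9, 23.4, 22.3, 21.5, 20.9,
                       20.5, 20.3, 20.1, 20.1, 20.0, 20.0, 20.0, 20.0, 20.0,
                       20.0, 20.0, 20.0, 20.0, 20.0, 20.0, 20.0, 20.0, 20.0,
                       20.0]
  KaF:
    mode: ohmic
    reversal: k
    gates:
      - name: m
        exponent: 2
        form: alpha_beta
        scale: 1.5
        alpha: {vhalf: 4.0, slope: -17.0, rate: 1500.0}
        beta: {vhalf: 10.0, slope: 9.0, rate: 600.0}
      - name: h
        exponent: 1
        form: alpha_beta
        scale: 0.67
        alpha: {vhalf: -121.0, slope: 22.0, rate: 105.0}
        beta: {vhalf: -55.0, slope: -11.0, rate: 65.0}
  KaS:
    mode: ohmic
    reversal: k
    gates:
      - name: m
        exponent: 2
        form: alpha_beta
        scale: 2.5
        alpha: {vhalf: 50.0, slope: -20.0, rate: 250.0}
        beta: {vhalf: -90.0, slope: 35.0, rate: 50.0}
      - name: h
        exponent: 1
        form: alpha_beta
        scale: 2.5
        alpha: {vhalf: -95.0, slope: 16.0, rate: 2.5}
        beta: {vhalf: 50.0, slope: -70.0, rate: 2.0}
  Kdr:
    mode: ohmic
    reversal: k
    gates:
      - name: m
        exponent: 1
        form: kdr
        scale: 0.5
        vhalf: -13.0
        slope_a: 9.09
        slope_b: 12.5
  BK:
    mode: ohmic
    reversal: k
    calcium_source_pool: nr
    gates:
      - name: m
        exponent: 1
        form: bk
        scale: 1.0
        alpha: {D: -0.84, K_mM: 0.003, B: 480.0}
        beta: {D: -1.0, K_mM: 0.009, B: 280.0}
  SK:
    mode: ohmic
    reversal: k
    calcium_source_pool: nr
    gates:
      - name: m
        exponent: 1
        form: sk
        scale: 1.0
        ec50_mM: 0.00057      # 0.57 uM
        hill: 5.4
        tau_ms: 4.0
  # ---- GHK calcium channels (lineage defaults; single activation power) ----
  CaL1.2:
    mode: ghk
    calcium_source_pool: vgcc
    gates:
      - {name: m, exponent: 1, form: sigmoid_tau, vhalf: -8.9, slope: -6.7, rate: 1.0, scale: 1.0, tau_ms: 0.6}
  CaL1.3:
    mode: ghk
    calcium_source_pool: vgcc
    gates:
      - {name: m, exponent: 1, form: sigmoid_tau, vhalf: -33.0, slope: -6.7, rate: 1.0, scale: 1.0, tau_ms: 0.6}
      - {name: h, exponent: 1, form: sigmoid_tau, vhalf: -13.4, slope: 11.9, rate: 1.0, scale: 1.0, tau_ms: 44.3}
  CaN:
    mode: ghk
    calcium_source_pool: nr
    gates:
      - {name: m, exponent: 1, form: sigmoid_tau, vhalf: -8.7, slope: -7.4, rate: 1.0, scale: 1.0, tau_ms: 0.7}
      - {name: h, exponent: 1, form: sigmoid_tau, vhalf: -74.8, slope: 6.5, rate: 1.0, scale: 1.0, tau_ms: 70.0}
  CaR:
    mode: ghk
    calcium_source_pool: nr
    gates:
      - {name: m, exponent: 1, form: sigmoid_tau, vhalf: -10.3, slope: -6.6, rate: 1.0, scale: 1.0, tau_ms: 1.7}
      - {name: h, exponent: 1, form: sigmoid_tau, vhalf: -33.3, slope: 17.0, rate: 1.0, scale: 1.0, tau_ms: 33.0}
  CaT:
    mode: ghk
    calcium_source_pool: vgcc
    gates:
      - {name: m, exponent: 1, form: sigmoid_tau, vhalf: -51.7, slope: -6.5, rate: 1.0, scale: 1.0, tau_ms: 2.0}
      - {name: h, exponent: 1, form: sigmoid_tau, vhalf: -80.0, slope: 6.7, rate: 1.0, scale: 1.0, tau_ms: 15.0}
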