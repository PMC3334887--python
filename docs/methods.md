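# Methods

## The model

`mspncalc` implements a multi-compartment, multi-channel model of a dorsal
striatal medium spiny projection neuron (MSPN) and uses it to ask one
question: how much calcium enters a dendritic spine through its NMDA
receptors when presynaptic glutamate release is paired, at an interval
Δt, with a backpropagating somatic action potential — and how that amount
depends on the GluN2 subunit composition of the receptor, the somatic
depolarization protocol, and the spine's distance from the soma.

The observable throughout is the peak concentration of a calcium pool fed
exclusively by the NMDA-receptor flux in one stimulated spine head,
expressed as a percentage of the "no-AP control" (the same synaptic
stimulation without any somatic depolarization). Working with this ratio
makes every result invariant to the overall calcium scale (pool volume,
buffer capacity, calcium fraction of the NMDA current).

### Morphology

A cylindrical soma (16 µm × 16 µm) carries four primary dendrites (20 µm,
Ø 2.25 µm), each bifurcating into two secondaries (24 µm, Ø 1.10 µm), each
bifurcating into two tertiary branches of eleven chained 36 µm segments
(Ø 0.72 µm). Two adjacent explicit spines (neck 0.5 µm × 0.12 µm, head
0.5 µm × 0.5 µm) are attached at the stimulation site: either on a
secondary dendrite ~40 µm from the soma or on the third tertiary segment
~150 µm out. The membrane of all other spines is folded into the shafts by
multiplying membrane capacitance — and dividing membrane resistance — by
the (shaft+spine)/shaft area ratio at 1 spine/µm; voltage-gated channel
conductances are *not* scaled, since spines carry (almost) none of them.
Sections are subdivided into electrical segments of ≤ 12 µm, well below
the AC length constant, so spike backpropagation attenuates realistically
rather than jumping compartment to compartment.

### Channels

Twelve voltage- and calcium-gated channels follow Hodgkin–Huxley gating
with the kinetics in `src/mspncalc/data/channels.yml` and the per-region
density table in `densities.yml` (soma / proximal = primary / middle =
secondary + first tertiary segment / distal = remaining tertiary / spine).
Fast sodium (NaF), inward rectifier (Kir), fast and slow A-type potassium
(KaF, KaS), delayed rectifier (Kdr), and the calcium-activated BK and SK
channels are ohmic; the five calcium channels (CaL1.2, CaL1.3, CaN, CaR,
CaT) conduct through the Goldman–Hodgkin–Katz flux equation parameterized
by permeability, each with a single activation power.

Three modeling choices deserve mention:

* **Kdr sign convention.** The delayed-rectifier row as commonly printed
  (`exp((V+13)/9.09)` with a `1−a` denominator) closes with depolarization
  and has a pole at −13 mV. We use `a = exp(−(V+13)/9.09)`,
  `b = exp(−(V+13)/12.5)`, steady state `1/(1+a)` and
  `τ = 0.05·b/(1+a)·scale`, which preserves half-activation at −13 mV and
  gives a monotonically opening gate.
* **Tabulated time constants.** NaF and Kir use voltage→τ tables. The
  shipped defaults are smooth curves sampled on a 5 mV grid and are part
  of the documented tuning step: NaF inactivation reaches ~0.24 ms at
  depolarized voltages (set with the "scale" column to produce a ~1 ms
  spike), and Kir relaxes with ~10–20 ms effective τ, which controls how
  fast the cell repolarizes after a depolarizing step.
* **Calcium-channel gates** use lineage-default sigmoid parameters with
  fixed time constants. The recorded observable (the NMDA-fed pool) is
  insulated from their exact values; they matter only through the shaft
  calcium that drives BK/SK.

BK and SK read a dedicated pool fed only by the N- and R-type calcium
channels. The BK voltage factor uses T = 305 K and interprets the K
parameters in mM; SK is a Hill function of that pool (EC50 0.57 µM,
exponent 5.4, τ 4 ms).

### Synapses and calcium

AMPA and NMDA receptors sit on spine heads. Both use the normalized dual
exponential `G(t) = gmax·K·(exp(−t/τ₂) − exp(−t/τ₁))` with K chosen so the
peak equals gmax (an alpha function in the degenerate τ₁ = τ₂ limit).
AMPA: τ₁ = 1.1 ms, τ₂ = 5.75 ms, 342 pS. NMDA: τ₁ = 2.25 ms; τ₂, gmax and
the magnesium-block parameter depend on the GluN2 subunit (A: 25 ms,
0.94 nS, 3.57 mM; B: 150 ms, 0.94 nS, 3.57 mM; C: 125 ms, 0.325 nS,
25 mM; D: 850 ms, 0.119 nS, 40 mM — decay constants are already
temperature-scaled). The block follows the Jahr–Stevens form
`1/(1 + ([Mg]/A)·exp(−V/16.13 mV))` with [Mg] = 1 mM; the voltage scale
(1/62 V) is shared by all subunits. The striatal GluN2A+B population is a
single receptor with the 75/25-weighted mean decay constant (56.25 ms);
blocking GluN2B is emulated either as the GluN2A-only receptor or as the
mixture at 75% conductance. Cortico- vs thalamo-striatal parameter sets
scale NMDA gmax by the measured NMDAR/AMPAR ratio and set kinetics either
from a GluN2B fraction (mouse dataset) or from a measured decay constant
(rat dataset).

Calcium pools are first order:
`d[Ca]/dt = −I_Ca/(2F·V_eff) + ([Ca]_rest − [Ca])/τ`. Every compartment
has a shaft-shell pool (0.1 µm submembrane shell, buffer capacity 20,
τ = 12 ms) for the BK/SK-driving CaN/CaR flux and a parallel pool for the
other calcium channels; stimulated spine heads add the NMDA pool
(anatomical head volume × buffer capacity 250, τ = 105 ms), the recorded
observable. The spine-pool decay constant doubles as the integration
window of the observable; it was calibrated once against the recorded
transient's ~100–200 ms return to baseline and the 30 ms vs 5 ms protocol
contrast. The NMDA calcium component is `κ·g_eff·(V − E_Ca)` with κ set
so calcium carries 10% of the total NMDA current at −65 mV; a GHK-shaped
driving option exists (`calcium.nmda_ca_driving: ghk`) but the linear
driving is the default because it matches how the model lineage derives
pool influx from channel current, and because it keeps the
spike-coincidence contribution effective even where the backpropagating
spike overshoots 0 mV. The normalized curves are insensitive to κ, buffer
capacity and volume by construction.

### Numerics

One step of the solver (default dt = 25 µs): synaptic dual-exponential
states decay analytically and accumulate events; membrane conductances are
evaluated from the gate states at the start of the step; the voltage cable
system is solved implicitly (backward Euler) with Hines elimination on the
tree; gates advance by exponential Euler using steady-state/decay-factor
tables pre-sampled on a 0.05 mV grid (BK and SK use their closed forms
with the local shaft calcium); GHK and NMDA calcium currents enter as
explicit sources and the pools update exactly for a constant current over
the step. Voltages outside the table range are clamped to the nearest
entry; |V| > 200 mV aborts with a diagnostic. Halving dt changes the peak
normalized spine calcium of a reference pairing trial by well under 1%.
The inner loop is compiled with numba.

Every experiment starts from a settled state: gates at steady state for
the nominal resting potential, then a 500 ms stimulus-free pre-run; a
residual drift above 0.5 mV/s raises. All randomness (Poisson background
trains) flows through one integer seed; everything else is deterministic.

### Protocols and calibration

The passive parameters were tuned (with the printed channel densities and
the "scale" column fixed) to the validation behaviors: membrane
resistivity 3.0 Ω·m², leak reversal −65 mV, axial resistivity 2.0 Ω·m,
Cm 0.01 F/m², giving a resting potential near −85 mV, inward
rectification of the I–V relation, a long latency to first spike near
rheobase, and a somatic AP half-width of ~1.1 ms.

Three pairing protocols are implemented: a 30 ms somatic step to one AP, a
5 ms step to one AP, and a 50 Hz triplet of three 5 ms steps. The step
amplitude is calibrated per protocol as the smallest current evoking
exactly one AP plus a 10 pA margin (the triplet amplitude is raised until
all three steps fire, since the AHP elevates the later thresholds). With
a near-minimal step the cell's long latency places the AP at the end of
the depolarization; this is the faithful realization of the protocol —
the depolarization has ended by the time glutamate arrives in
negative-interval trials, which is what keeps an AP *before* the
stimulation from elevating spine calcium. Δt is the time from the
presynaptic stimulation to the (first) AP peak; the step onset is placed
at `t_syn + Δt − latency` using the pre-calibrated latency, the realized
peak is verified to land within ±1 ms (one recalibration allowed), and
the no-AP control simply omits the step. Peak calcium is read in a 500 ms
window after the synaptic event.

Background-input ("jitter") runs attach extra spines across the dendrites
and drive them with seeded homogeneous Poisson trains at 1–10 Hz, which
perturbs the spike timing within the depolarization without changing the
nominal intervals.

## What the synthetic inputs do and do not represent

All inputs are generated: there is no external data. The deterministic
pairing programs represent idealized STDP trials — a single pairing, not
the 100×1 Hz induction trains (spine calcium returns to rest between
pairings, so one pairing carries the Δt information). The Poisson
background emulates low-rate uncorrelated synaptic bombardment only; it
has no spatial structure, short-term plasticity, or inhibition (GABA is
deliberately absent, matching the blocked-inhibition condition the model
represents). Passing tests therefore certify the model's electro-chemical
logic under controlled stimulation, not quantitative agreement with in
vivo activity.

## Known limitations

* Not every reported relation is reproduced simultaneously. The shipped
  configuration reproduces the protocol contrast (30 ms plateau ~250%,
  5 ms ~175%), the negative-interval asymmetry, the GluN2A-alone
  suppression at wide intervals, and the ~+40 ms crossing of the A+B
  mixture curve. It under-reproduces the absolute magnitudes of the
  slow-decaying subunit conditions (GluN2B ~180% and GluN2C ~115% at
  narrow intervals versus the reported ≥250% and ~200%), the +2 ms end
  of the mixture plateau, and the proximal-versus-distal ordering of the
  positive-interval gain (near-equal here instead of clearly lower at
  150 µm). A parameter study (step margin × pool decay × axial
  resistivity) shows these two groups trade off against each other in
  this implementation: configurations that restore the subunit
  magnitudes and distance ordering require the AP to fall early in the
  depolarization, which inflates the plateau values by ~30% and breaks
  the negative-interval asymmetry. The most likely missing ingredients
  are a less regenerative dendritic spike (the spine bAP here overshoots
  ~+40 mV even 150 µm out) and saturable spine calcium buffering.
* Unprinted ingredients (NaF/Kir τ tables, calcium-channel gate
  parameters, diameters, calcium handling) are lineage-informed defaults
  exposed as data files; conclusions that depend on them beyond the tuned
  validation behaviors should be treated accordingly.
* No receptor desensitization, glutamate spillover, triheteromeric
  kinetics, stochastic gating, or plasticity rule: calcium is the proxy
  observable, and the mapping from calcium to potentiation is outside the
  model.
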