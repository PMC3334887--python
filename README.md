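# mspncalc

Spine calcium through NMDA receptors in a striatal medium spiny projection
neuron (MSPN), under spike-timing (pre/post pairing) protocols.

Medium spiny projection neurons make up ~95% of the striatum, and the
timing-dependent long-term potentiation of their cortical and thalamic
inputs requires calcium entering dendritic spines through NMDA receptors.
How much calcium a pairing lets in depends on receptor biophysics that the
GluN2 subunit (A–D) controls — maximal conductance, current decay time τ₂,
and the voltage-dependent magnesium block

    B(V) = 1 / (1 + ([Mg²⁺]/A) · exp(−V / 16.13 mV)),

with the block parameter A = 3.57 mM (GluN2A/B), 25 mM (GluN2C) or 40 mM
(GluN2D) — as well as on the timing interval Δt between presynaptic
glutamate release and the backpropagating action potential, on the somatic
depolarization that evokes the spike, and on the spine's distance from the
soma.

`mspncalc` is a self-contained compartmental simulator for this question:
a branched MSPN morphology with explicit spines, twelve voltage- and
calcium-gated channels (GHK flux for the calcium channels), normalized
dual-exponential AMPA/NMDA synapses, first-order calcium pools, and the
pairing protocols used in striatal plasticity work (30 ms depolarization
to one AP, 5 ms depolarization to one AP, 50 Hz AP triplet). The readout
is the peak concentration of the spine's NMDA-fed calcium pool as a
percentage of the no-AP control (synaptic stimulation alone), plotted
against Δt. It is aimed at computational neuroscientists studying striatal
synaptic plasticity and at anyone who needs a small, hackable,
numba-accelerated cable solver with calcium dynamics.

See `docs/methods.md` for the model equations, parameters, numerics, and
limitations.

## Worked example

```python
from mspncalc.experiments import PairingExperiment
from mspncalc.analysis import build_calcium_curve

# 30 ms depolarization-to-1-AP protocol, two spines on a secondary
# dendrite 40 um from the soma, cortico-striatal GluN2A+B receptors
exp = PairingExperiment(protocol="dep30ms")
sweep = exp.sweep([-12.0, 2.0, 5.0, 10.0, 20.0, 30.0])
curve = build_calcium_curve(sweep)
print(curve.to_frame().to_string(index=False))
```

```
 delta_t_ms  normalized_peak_pct protocol      site           condition
      -12.0            96.172405  dep30ms secondary GluN2A+B(0.75/0.25)
        2.0           172.227345  dep30ms secondary GluN2A+B(0.75/0.25)
        5.0           211.900712  dep30ms secondary GluN2A+B(0.75/0.25)
       10.0           258.492799  dep30ms secondary GluN2A+B(0.75/0.25)
       20.0           297.693334  dep30ms secondary GluN2A+B(0.75/0.25)
       30.0           292.730603  dep30ms secondary GluN2A+B(0.75/0.25)
```

Reading the output: pairing the synaptic stimulation with an AP 2–30 ms
*after* it elevates the spine's NMDA-mediated calcium to ~170–300% of
what the synaptic stimulation alone produces (the mean over +2..+20 ms is
~250%); an AP 12 ms *before* the stimulation leaves the peak at control
level (96%), and the gain decays for wide positive intervals as the
receptor current wanes. Swapping
`nmda=make_nmda("GluN2A")` (or `"GluN2C"`, ...) or `site="tertiary"`
(spines 150 µm out) reshapes this curve — that reshaping is the package's
subject matter.

The same experiments are available from a shell:

```bash
mspncalc --out-dir out validate                 # rheobase, AP width, I-V
mspncalc --out-dir out stdp-sweep --protocol dep30ms --subunit GluN2A+B
mspncalc --out-dir out subunit-compare          # GluN2A..D curves
mspncalc --out-dir out distance-compare         # 40 um vs 150 um spines
mspncalc --out-dir out source-compare --dataset ding
mspncalc --out-dir out jitter --seed 1          # Poisson-background control
```

Each subcommand writes CSV curves, JSON summaries and a calibration log
into the output directory; `--config` points at a YAML file overriding any
of the packaged model parameters.

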