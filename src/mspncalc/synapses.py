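"""Glutamatergic synapses, GluN2-subunit NMDA receptors, and calcium pools.

The synaptic conductance is the classic normalized dual exponential

    G(t) = gmax * K * (exp(-t/tau2) - exp(-t/tau1)),

with K chosen so the peak equals gmax.  NMDA receptors add a
voltage-dependent magnesium block

    B(V) = 1 / (1 + ([Mg]/A) * exp(-V / 16.129 mV)),

where the concentration parameter A is set by the GluN2 subunit (A/B: 3.57,
C: 25, D: 40 mM) and the voltage scale is 1/62 V for every subunit.  Calcium
entering through the NMDA receptor feeds a dedicated first-order pool in the
spine head, the observable of every pairing experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .channels import FARADAY, _load_yaml

MG_VOLTAGE_SCALE = 16.129  # mV == 1/62 V

SUBUNIT_LABELS = ("GluN2A", "GluN2B", "GluN2C", "GluN2D")


class SynapseError(ValueError):
    pass


@dataclass(frozen=True)
class SynapseSpec:
    """Dual-exponential conductance synapse (SI units: seconds, siemens, mV)."""

    tau1: float            # activation, s
    tau2: float            # inactivation, s
    gmax: float            # S
    reversal: float = 0.0  # mV
    label: str = "AMPA"

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise SynapseError("synaptic time constants must be positive")
        if self.gmax < 0:
            raise SynapseError("gmax must be nonnegative")

    @property
    def norm_const(self) -> float:
        return norm_const(self.tau1, self.tau2)


@dataclass(frozen=True)
class NMDASubunitParams:
    """NMDA receptor with GluN2-subunit-dependent kinetics and Mg block."""

    label: str
    gmax: float            # S
    tau_decay: float       # s, temperature-scaled
    mg_A: float            # mM
    tau_rise: float = 2.25e-3
    mg_B_scale: float = MG_VOLTAGE_SCALE  # mV; identical for all subunits

    def as_synapse(self) -> SynapseSpec:
        return SynapseSpec(tau1=self.tau_rise, tau2=self.tau_decay,
                           gmax=self.gmax, reversal=0.0, label=self.label)


@dataclass(frozen=True)
class SynapseSourceParams:
    """Cortico- or thalamo-striatal synaptic characterization."""

    source: str                        # "cortical" | "thalamic"
    dataset: str                       # "ding" | "smeal"
    nmdar_ampar_ratio: float
    glun2b_fraction: float | None = None  # ding
    tau_decay: float | None = None        # s, smeal


@dataclass
class CalciumPool:
    """First-order calcium pool: d[Ca]/dt = -I_Ca/(2 F vol) + (rest-[Ca])/tau.

    Concentrations in mM; an inward calcium current (negative by membrane
    convention) raises the concentration.
    """

    label: str                 # "nmda" | "nr" | "vgcc"
    concentration: float       # mM
    rest: float = 5e-5         # mM (0.05 uM)
    decay_tau: float = 0.05    # s
    effective_volume: float = 1e-19   # m^3 (buffer-scaled)
    source_currents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise SynapseError("calcium concentration cannot be negative")
        if self.label == "nr" and self.source_currents and \
                set(self.source_currents) != {"CaN", "CaR"}:
            raise SynapseError("the BK/SK pool is fed exactly by CaN and CaR")


@dataclass(frozen=True)
class SynapticEvent:
    time: float      # s
    spine_id: str
    receptor_set: tuple[str, ...] = ("AMPA", "NMDA")

    def __post_init__(self) -> None:
        if self.time < 0:
            raise SynapseError("event time must be nonnegative")


# ---------------------------------------------------------------------------
# dual-exponential conductance


def peak_time(tau1: float, tau2: float) -> float:
    """Time of the dual-exponential peak (the alpha-function peak for equal taus)."""
    if tau1 == tau2:
        return tau1
    return math.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1)


def norm_const(tau1: float, tau2: float) -> float:
    """Normalization K making the conductance peak equal gmax.

    For tau1 == tau2 the waveform degenerates to the alpha function
    ``(t/tau) exp(1 - t/tau)`` whose K is e/tau on the difference-quotient
    limit; the peak still equals gmax.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise SynapseError("time constants must be positive")
    if tau1 == tau2:
        return math.e / tau1  # limiting alpha form, used with t*exp(-t/tau)
    tp = peak_time(tau1, tau2)
    return 1.0 / (math.exp(-tp / tau2) - math.exp(-tp / tau1))


def syn_conductance(t_since_event, spec: SynapseSpec):
    """Conductance (S) at time(s) since one presynaptic event (0 before it).

    Contributions of multiple events superpose linearly; callers sum.
    """
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise SynapseError("t_since_event must be nonnegative")
    if spec.tau1 == spec.tau2:
        wave = spec.norm_const * t * np.exp(-t / spec.tau1)
    else:
        wave = spec.norm_const * (np.exp(-t / spec.tau2) - np.exp(-t / spec.tau1))
    return spec.gmax * wave


def mg_block(v, params: NMDASubunitParams, mg: float = 1.0):
    """Fraction of NMDA conductance unblocked at voltage v (mV), [Mg] in mM."""
    if mg < 0:
        raise SynapseError("magnesium concentration must be nonnegative")
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + (mg / params.mg_A) * np.exp(-v / params.mg_B_scale))


# ---------------------------------------------------------------------------
# receptor construction


def _synapse_data() -> dict:
    return _load_yaml("synapses.yml")


def make_nmda(kind: str, weights: tuple[float, float] | None = None,
              conductance_scale: float = 1.0,
              data: dict | None = None) -> NMDASubunitParams:
    """Build NMDA receptor parameters for a subunit, mixture, or scaled variant.

    ``kind`` is one of the pure subunit labels, or ``"GluN2A+B"`` for the
    striatal mixture (single population with the conductance-weighted mean
    decay time; default 75% GluN2A / 25% GluN2B).  ``conductance_scale``
    multiplies gmax while keeping the kinetics (e.g. 0.75 emulates blocking
    the GluN2B fraction without changing the mixture decay).
    """
    d = data or _synapse_data()
    nm = d["nmda"]
    tau1 = nm["tau1_ms"] * 1e-3
    if kind in SUBUNIT_LABELS:
        row = nm["subunits"][kind]
        p = NMDASubunitParams(label=kind, gmax=row["gmax_nS"] * 1e-9,
                              tau_decay=row["tau_decay_ms"] * 1e-3,
                              mg_A=row["mg_A_mM"], tau_rise=tau1)
    elif kind in ("GluN2A+B", "mixture"):
        mix = nm["mixture"]
        fb = mix["glun2b_fraction"] if weights is None else weights[1]
        fa = 1.0 - fb if weights is None else weights[0]
        if abs(fa + fb - 1.0) > 1e-9:
            raise SynapseError("mixture weights must sum to 1")
        ta = nm["subunits"]["GluN2A"]["tau_decay_ms"] * 1e-3
        tb = nm["subunits"]["GluN2B"]["tau_decay_ms"] * 1e-3
        p = NMDASubunitParams(label=f"GluN2A+B({fa:.2f}/{fb:.2f})",
                              gmax=mix["gmax_nS"] * 1e-9,
                              tau_decay=fa * ta + fb * tb,
                              mg_A=mix["mg_A_mM"], tau_rise=tau1)
    else:
        raise SynapseError(f"unknown NMDA receptor kind {kind!r}")
    if conductance_scale != 1.0:
        p = replace(p, gmax=p.gmax * conductance_scale,
                    label=f"{p.label}x{conductance_scale:g}")
    return p


def load_source_params(dataset: str, source: str,
                       data: dict | None = None) -> SynapseSourceParams:
    d = data or _synapse_data()
    try:
        row = d["sources"][dataset][source]
    except KeyError as exc:
        raise SynapseError(f"unknown synapse source {dataset!r}/{source!r}") from exc
    return SynapseSourceParams(
        source=source, dataset=dataset,
        nmdar_ampar_ratio=row["nmdar_ampar_ratio"],
        glun2b_fraction=row.get("glun2b_fraction"),
        tau_decay=None if "tau_decay_ms" not in row else row["tau_decay_ms"] * 1e-3)


def make_synapse_pair(source_params: SynapseSourceParams,
                      ampa_gmax: float | None = None,
                      data: dict | None = None
                      ) -> tuple[SynapseSpec, NMDASubunitParams]:
    """AMPA spec plus NMDA parameters for one input pathway.

    NMDA gmax = NMDAR/AMPAR ratio x AMPA gmax; kinetics either from the
    dataset's GluN2B fraction (A/B mixture) or its measured decay constant.
    """
    d = data or _synapse_data()
    am = d["ampa"]
    if ampa_gmax is None:
        ampa_gmax = am["gmax_pS"] * 1e-12
    if ampa_gmax <= 0:
        raise SynapseError("AMPA gmax must be positive")
    ampa = SynapseSpec(tau1=am["tau1_ms"] * 1e-3, tau2=am["tau2_ms"] * 1e-3,
                       gmax=ampa_gmax, reversal=am["reversal_mV"], label="AMPA")
    gmax_nmda = source_params.nmdar_ampar_ratio * ampa_gmax
    if source_params.glun2b_fraction is not None:
        fb = source_params.glun2b_fraction
        nmda = make_nmda("GluN2A+B", weights=(1.0 - fb, fb), data=d)
    elif source_params.tau_decay is not None:
        nm = d["nmda"]
        nmda = NMDASubunitParams(
            label=f"{source_params.dataset}-{source_params.source}",
            gmax=gmax_nmda, tau_decay=source_params.tau_decay,
            mg_A=nm["mixture"]["mg_A_mM"], tau_rise=nm["tau1_ms"] * 1e-3)
    else:
        raise SynapseError("source parameters specify neither kinetics form")
    nmda = replace(nmda, gmax=gmax_nmda,
                   label=f"{source_params.dataset}-{source_params.source}")
    return ampa, nmda


# ---------------------------------------------------------------------------
# NMDA calcium flux and pool dynamics


def ghk_driving_term(v, ca_in: float, ca_out: float,
                     temperature: float = 305.0):
    """GHK-shaped driving function D(V) with unit permeability-area (A per m^3/s)."""
    from .channels import ghk_current
    return ghk_current(1.0, v, ca_in, ca_out, temperature)


def calcium_nernst(ca_in: float, ca_out: float,
                   temperature: float = 305.0) -> float:
    """Calcium Nernst potential (mV)."""
    from .channels import FARADAY, GAS_CONSTANT
    return (GAS_CONSTANT * temperature / (2.0 * FARADAY)
            * math.log(ca_out / ca_in) * 1e3)


def nmda_calcium_scale(fraction: float = 0.1, v_ref: float = -65.0,
                       ca_rest: float = 5e-5, ca_out: float = 2.0,
                       reversal: float = 0.0, driving: str = "linear",
                       temperature: float = 305.0) -> float:
    """Scale kappa such that Ca carries ``fraction`` of NMDA current at v_ref.

    With the default linear driving, the calcium component is
    kappa * g_eff * (V - E_Ca); with ``driving="ghk"`` it is
    kappa * g_eff * D(V) with the GHK driving term D.  Either way kappa is
    fixed so the calcium current equals ``fraction`` of the total NMDA
    current g_eff*(v_ref - E_syn) at the reference voltage.
    """
    if driving == "linear":
        e_ca = calcium_nernst(ca_rest, ca_out, temperature)
        return fraction * (v_ref - reversal) / (v_ref - e_ca)
    d_ref = float(ghk_driving_term(v_ref, ca_rest, ca_out, temperature))
    return fraction * (v_ref - reversal) * 1e-3 / d_ref


def nmda_calcium_flux(g_effective, v, ca_in: float = 5e-5, ca_out: float = 2.0,
                      kappa: float | None = None, driving: str = "linear",
                      temperature: float = 305.0):
    """Calcium current (A) through the NMDA receptor at conductance g_effective (S).

    Zero when the receptor is closed and at the calcium reversal potential;
    linear in g_effective.  ``v`` in mV.
    """
    g = np.asarray(g_effective, dtype=float)
    if np.any(g < 0):
        raise SynapseError("effective conductance must be nonnegative")
    if kappa is None:
        kappa = nmda_calcium_scale(ca_rest=ca_in, ca_out=ca_out,
                                   driving=driving, temperature=temperature)
    if driving == "linear":
        e_ca = calcium_nernst(ca_in, ca_out, temperature)
        return kappa * g * (np.asarray(v, dtype=float) - e_ca) * 1e-3
    return kappa * g * ghk_driving_term(v, ca_in, ca_out, temperature)


def update_pool(pool: CalciumPool, i_ca: float, dt: float) -> CalciumPool:
    """Advance a calcium pool one step (exact exponential update).

    d[Ca]/dt = -i_ca/(2 F vol) + (rest - [Ca])/tau; with constant influx the
    fixed point is rest - i_ca*tau/(2 F vol).
    """
    if dt <= 0:
        raise SynapseError("dt must be positive")
    j = -i_ca / (2.0 * FARADAY * pool.effective_volume)   # mM/s
    target = pool.rest + j * pool.decay_tau
    decay = math.exp(-dt / pool.decay_tau)
    new_conc = target + (pool.concentration - target) * decay
    return replace(pool, concentration=max(new_conc, 0.0))
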