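"""Voltage- and calcium-dependent ionic channels of the MSPN model.

Gating follows the Hodgkin-Huxley formalism: each channel carries one or two
gates (activation m, inactivation h) raised to small integer powers.  Gate
kinetics come in a handful of closed forms -- a sigmoid steady state with a
tabulated or fixed time constant, forward/backward sigmoid rates
(alpha/beta), a delayed-rectifier special form, and the calcium-dependent
BK / SK forms.  Calcium channels conduct through the Goldman-Hodgkin-Katz
flux equation parameterized by a maximal permeability instead of a
conductance.

Voltages in this module are in mV (the unit the kinetic parameters are
quoted in); returned time constants are in seconds; calcium concentrations
are in mM unless a parameter name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)

#: Channel names admitted on neuronal membrane (Table-style density set).
CHANNEL_NAMES = (
    "NaF", "Kir", "KaF", "KaS", "Kdr", "BK", "SK",
    "CaL1.2", "CaL1.3", "CaN", "CaR", "CaT",
)

GATE_FORMS = ("sigmoid_tab", "alpha_beta", "sigmoid_tau", "kdr", "bk", "sk")


def sigmoid(v: float | np.ndarray, rate: float, vhalf: float, slope: float):
    """``rate / (1 + exp((v - vhalf)/slope))`` -- the basic gating sigmoid.

    ``slope`` must be nonzero; its sign decides whether the curve rises or
    falls with depolarization.
    """
    if slope == 0:
        raise ValueError("sigmoid slope must be nonzero")
    return rate / (1.0 + np.exp((np.asarray(v, dtype=float) - vhalf) / slope))


@dataclass
class GateSpec:
    """One Hodgkin-Huxley gate.

    ``form`` selects the kinetic scheme; only the fields that scheme uses are
    meaningful.  ``tau_scale`` is the tuning multiplier applied to every time
    constant ("scale" in the kinetics table).
    """

    name: str
    form: str
    exponent: int = 1
    vhalf: float = 0.0        # mV
    slope: float = 1.0        # mV
    rate: float = 1.0
    tau_scale: float = 1.0
    # sigmoid_tab
    tau_table_v: np.ndarray | None = None   # mV
    tau_table: np.ndarray | None = None     # s
    # alpha_beta: (vhalf mV, slope mV, rate 1/s)
    alpha: tuple[float, float, float] | None = None
    beta: tuple[float, float, float] | None = None
    # sigmoid_tau / sk
    tau_fixed: float | None = None          # s
    # kdr
    slope_a: float = 9.09
    slope_b: float = 12.5
    # bk: (D, K mM, B 1/s)
    bk_alpha: tuple[float, float, float] | None = None
    bk_beta: tuple[float, float, float] | None = None
    # sk
    ec50: float = 5.7e-4      # mM
    hill: float = 5.4

    def __post_init__(self) -> None:
        if self.form not in GATE_FORMS:
            raise ValueError(f"unknown gate form {self.form!r}")
        if self.exponent not in (1, 2, 3):
            raise ValueError("gate exponent must be 1, 2 or 3")
        if self.tau_scale <= 0:
            raise ValueError("tau_scale must be positive")
        if self.form in ("sigmoid_tab", "sigmoid_tau") and self.slope == 0:
            raise ValueError("sigmoid slope must be nonzero")


@dataclass
class CaDepParams:
    """Calcium-dependence constants of the BK and SK channels."""

    bk_alpha: tuple[float, float, float] = (-0.84, 0.003, 480.0)  # D, K mM, B 1/s
    bk_beta: tuple[float, float, float] = (-1.0, 0.009, 280.0)
    sk_ec50: float = 5.7e-4   # mM
    sk_hill: float = 5.4
    sk_tau: float = 4e-3      # s
    temperature: float = 305.0  # K

    def __post_init__(self) -> None:
        if self.bk_alpha[2] <= 0 or self.bk_beta[2] <= 0:
            raise ValueError("BK B rates must be positive")
        if self.sk_ec50 <= 0:
            raise ValueError("SK EC50 must be positive")


@dataclass
class ChannelSpec:
    name: str
    gates: list[GateSpec]
    mode: str = "ohmic"            # "ohmic" or "ghk"
    reversal: float = 0.0          # mV, ohmic only
    calcium_source_pool: str | None = None  # pool read (BK/SK) or fed (Ca)

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {self.name!r}")
        if self.mode not in ("ohmic", "ghk"):
            raise ValueError("mode must be 'ohmic' or 'ghk'")
        if self.name.startswith("Ca") and self.mode != "ghk":
            raise ValueError("calcium channels must use GHK conduction")
        if self.name in ("BK", "SK") and self.calcium_source_pool != "nr":
            raise ValueError("BK/SK must read the N/R-fed calcium pool")


def gate_inf_tau(gate: GateSpec, v: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steady state and time constant (s) of a voltage-dependent gate.

    Voltages outside a tau table's range are clamped to the nearest entry.
    """
    v = np.asarray(v, dtype=float)
    if gate.form == "alpha_beta":
        a = sigmoid(v, gate.alpha[2], gate.alpha[0], gate.alpha[1])
        b = sigmoid(v, gate.beta[2], gate.beta[0], gate.beta[1])
        inf = a / (a + b)
        tau = gate.tau_scale / (a + b)
    elif gate.form == "sigmoid_tab":
        inf = sigmoid(v, gate.rate, gate.vhalf, gate.slope)
        tau = np.interp(v, gate.tau_table_v, gate.tau_table) * gate.tau_scale
    elif gate.form == "sigmoid_tau":
        inf = sigmoid(v, gate.rate, gate.vhalf, gate.slope)
        tau = np.full_like(inf, gate.tau_fixed * gate.tau_scale)
    elif gate.form == "kdr":
        return kdr_inf_tau(v, tau_scale=gate.tau_scale,
                           vhalf=gate.vhalf, slope_a=gate.slope_a,
                           slope_b=gate.slope_b)
    else:
        raise ValueError(f"gate form {gate.form!r} is not purely voltage dependent")
    return inf, tau


def kdr_inf_tau(v, tau_scale: float = 0.5, vhalf: float = -13.0,
                slope_a: float = 9.09, slope_b: float = 12.5):
    """Delayed-rectifier steady state ``1/(1+a)`` and tau ``0.05 b/(1+a)`` s.

    ``a = exp(-(v - vhalf)/slope_a)``, ``b = exp(-(v - vhalf)/slope_b)``; the
    sign convention makes activation increase monotonically with voltage and
    keeps half-activation at ``vhalf``.
    """
    v = np.asarray(v, dtype=float)
    a = np.exp(-(v - vhalf) / slope_a)
    b = np.exp(-(v - vhalf) / slope_b)
    inf = 1.0 / (1.0 + a)
    tau = 0.05 * b / (1.0 + a) * tau_scale
    return inf, tau


def bk_rates(v, ca, params: CaDepParams | None = None):
    """BK channel opening/closing rates (1/s) at voltage v (mV), calcium ca (mM).

    ``alpha = B ca/(ca + K exp(2 v D F/(R T)))`` rises with calcium and
    saturates at B; ``beta = B/(1 + ca/(K exp(2 v D F/(R T))))`` falls with
    calcium.  D < 0 makes depolarization favor opening.
    """
    p = params or CaDepParams()
    v = np.asarray(v, dtype=float)
    ca = np.asarray(ca, dtype=float)
    vf = FARADAY / (GAS_CONSTANT * p.temperature) * 1e-3  # per mV
    d_a, k_a, b_a = p.bk_alpha
    d_b, k_b, b_b = p.bk_beta
    alpha = b_a * ca / (ca + k_a * np.exp(2.0 * v * d_a * vf))
    beta = b_b / (1.0 + ca / (k_b * np.exp(2.0 * v * d_b * vf)))
    return alpha, beta


def sk_inf(ca, ec50: float = 5.7e-4, hill: float = 5.4):
    """SK activation: Hill function of calcium (mM) with EC50 0.57 uM."""
    ca = np.asarray(ca, dtype=float)
    x = np.where(ca > 0, (ca / ec50) ** hill, 0.0)
    return x / (1.0 + x)


def ghk_current(permeability, v, ca_in, ca_out, temperature: float = 305.0):
    """GHK current density (A/m^2) for divalent calcium.

    ``permeability`` in m/s, ``v`` in mV, concentrations in mM (== mol/m^3).
    The v -> 0 singularity is removed analytically; the current vanishes at
    the calcium Nernst potential.
    """
    z = 2.0
    v_si = np.asarray(v, dtype=float) * 1e-3
    ca_in = np.asarray(ca_in, dtype=float)
    ca_out = np.asarray(ca_out, dtype=float)
    u = z * FARADAY * v_si / (GAS_CONSTANT * temperature)
    small = np.abs(u) < 1e-9
    u_safe = np.where(small, 1.0, u)
    ratio = np.where(
        small,
        ca_in - ca_out,  # L'Hopital limit of (cin - cout e^-u)/((1-e^-u)/u)
        (ca_in - ca_out * np.exp(-u_safe)) / (-np.expm1(-u_safe)) * u_safe,
    )
    return permeability * z * FARADAY * ratio


def channel_current(spec: ChannelSpec, gate_states, v, density,
                    ca_in: float = 5e-5, ca_out: float = 2.0,
                    temperature: float = 305.0):
    """Membrane current density (A/m^2) of one channel.

    ``gate_states`` lists the instantaneous gate values (one per gate, each in
    [0,1]); ``density`` is Gbar (S/m^2) for ohmic channels or Pbar (m/s) for
    GHK channels.
    """
    if len(gate_states) != len(spec.gates):
        raise ValueError("one gate state per gate required")
    open_frac = 1.0
    for g, x in zip(spec.gates, gate_states):
        if not 0.0 <= x <= 1.0:
            raise ValueError("gate state outside [0, 1]")
        open_frac *= x ** g.exponent
    if spec.mode == "ohmic":
        return density * open_frac * (v - spec.reversal) * 1e-3  # mV -> V
    return open_frac * ghk_current(density, v, ca_in, ca_out, temperature)


# ---------------------------------------------------------------------------
# channel library loading


def _load_yaml(name: str) -> dict:
    with resources.files("mspncalc.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _build_gate(raw: dict, tab_v: list[float]) -> GateSpec:
    form = raw["form"]
    kw = dict(name=raw["name"], form=form, exponent=int(raw.get("exponent", 1)),
              tau_scale=float(raw.get("scale", 1.0)))
    if form == "sigmoid_tab":
        kw.update(vhalf=raw["vhalf"], slope=raw["slope"], rate=raw.get("rate", 1.0),
                  tau_table_v=np.asarray(tab_v, dtype=float),
                  tau_table=np.asarray(raw["tau_table_ms"], dtype=float) * 1e-3)
    elif form == "alpha_beta":
        kw.update(alpha=(raw["alpha"]["vhalf"], raw["alpha"]["slope"], raw["alpha"]["rate"]),
                  beta=(raw["beta"]["vhalf"], raw["beta"]["slope"], raw["beta"]["rate"]))
    elif form == "sigmoid_tau":
        kw.update(vhalf=raw["vhalf"], slope=raw["slope"], rate=raw.get("rate", 1.0),
                  tau_fixed=raw["tau_ms"] * 1e-3)
    elif form == "kdr":
        kw.update(vhalf=raw["vhalf"], slope_a=raw["slope_a"], slope_b=raw["slope_b"])
    elif form == "bk":
        kw.update(bk_alpha=(raw["alpha"]["D"], raw["alpha"]["K_mM"], raw["alpha"]["B"]),
                  bk_beta=(raw["beta"]["D"], raw["beta"]["K_mM"], raw["beta"]["B"]))
    elif form == "sk":
        kw.update(ec50=raw["ec50_mM"], hill=raw["hill"], tau_fixed=raw["tau_ms"] * 1e-3)
    return GateSpec(**kw)


@dataclass
class ChannelLibrary:
    """All channel definitions plus shared constants, as loaded from data."""

    channels: dict[str, ChannelSpec]
    temperature: float
    reversals: dict[str, float]           # mV
    ca_params: CaDepParams
    mg_voltage_scale: float = 16.129      # mV

    def __getitem__(self, name: str) -> ChannelSpec:
        return self.channels[name]


def load_channel_library(path: str | None = None) -> ChannelLibrary:
    """Load the channel kinetics data file (the packaged default if no path)."""
    if path is None:
        raw = _load_yaml("channels.yml")
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    tab_v = raw["tau_table_v_mV"]
    temperature = float(raw["temperature"])
    reversals = {k: float(val) for k, val in raw["reversals_mV"].items()}
    channels: dict[str, ChannelSpec] = {}
    ca_params = CaDepParams(temperature=temperature)
    for name, cdef in raw["channels"].items():
        gates = [_build_gate(g, tab_v) for g in cdef["gates"]]
        rev = reversals.get(cdef.get("reversal", ""), 0.0)
        channels[name] = ChannelSpec(
            name=name, gates=gates, mode=cdef["mode"], reversal=rev,
            calcium_source_pool=cdef.get("calcium_source_pool"))
        if name == "BK":
            g = gates[0]
            ca_params = CaDepParams(bk_alpha=g.bk_alpha, bk_beta=g.bk_beta,
                                    sk_ec50=ca_params.sk_ec50,
                                    sk_hill=ca_params.sk_hill,
                                    sk_tau=ca_params.sk_tau,
                                    temperature=temperature)
        elif name == "SK":
            g = gates[0]
            ca_params = CaDepParams(bk_alpha=ca_params.bk_alpha,
                                    bk_beta=ca_params.bk_beta,
                                    sk_ec50=g.ec50, sk_hill=g.hill,
                                    sk_tau=g.tau_fixed, temperature=temperature)
    return ChannelLibrary(channels=channels, temperature=temperature,
                          reversals=reversals, ca_params=ca_params,
                          mg_voltage_scale=float(raw.get("mg_voltage_scale_mV", 16.129)))


def load_densities(path: str | None = None) -> dict[str, dict[str, float]]:
    """Load the per-region Gbar/Pbar density table (channel -> region -> value)."""
    if path is None:
        raw = _load_yaml("densities.yml")
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    out: dict[str, dict[str, float]] = {}
    for section in ("gbar", "pbar"):
        for name, regions in raw[section].items():
            out[name] = {r: float(x) for r, x in regions.items()}
    return out
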