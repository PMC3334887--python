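"""Assembly of morphology + channels + synapses into solver-ready arrays.

`MSPNCell` builds the full model cell for one experimental configuration
(stimulation site, NMDA receptor variant, optional background spines) and
`MSPNCell.compile` flattens it into the plain numpy arrays the integration
kernel consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import channels as ch
from . import morphology as mo
from . import synapses as sy

GATE_TABLE, GATE_BK, GATE_SK = 0, 1, 2


@dataclass
class SimState:
    """Full dynamical state of a compiled model."""

    v: np.ndarray          # V, per compartment
    gates: np.ndarray      # [ngk, n]
    ca_pools: np.ndarray   # [3, n], mM (nr, vgcc, nmda)
    syn_a: np.ndarray      # [ns]
    syn_b: np.ndarray

    def copy(self) -> "SimState":
        return SimState(self.v.copy(), self.gates.copy(), self.ca_pools.copy(),
                        self.syn_a.copy(), self.syn_b.copy())


@dataclass
class CompiledModel:
    """Flattened model arrays plus index maps (see `_kernel.run_kernel`)."""

    dt: float
    n: int
    parent: np.ndarray
    cm: np.ndarray
    ga: np.ndarray
    gleak: np.ndarray
    eleak: float
    special: np.ndarray
    inf_tab: np.ndarray
    fac_tab: np.ndarray
    vmin: float
    dv: float
    bk: tuple
    sk: tuple
    ch_mode: np.ndarray
    ch_erev: np.ndarray
    ch_g1: np.ndarray
    ch_g2: np.ndarray
    ch_e1: np.ndarray
    ch_e2: np.ndarray
    ch_gbar: np.ndarray
    ch_pool: np.ndarray
    ca_out: float
    rt_inv: float
    pool_rest: np.ndarray
    pool_decay: np.ndarray
    pool_tau2fv: np.ndarray
    syn_comp: np.ndarray
    syn_gmax: np.ndarray
    syn_k: np.ndarray
    syn_faca: np.ndarray
    syn_facb: np.ndarray
    syn_erev: np.ndarray
    syn_mga: np.ndarray
    syn_mgscale: float
    mg_conc: float
    syn_kappa: np.ndarray
    nmda_ca_linear: bool
    eca: float               # V, calcium Nernst at rest (linear driving)
    comp_index: dict[str, int]
    gate_index: dict[tuple[str, str], int]
    syn_index: dict[tuple[str, str], int]   # (spine head id, receptor) -> syn row
    v_init: float

    def initial_state(self) -> SimState:
        """State with every gate at steady state for v_init and pools at rest."""
        n = self.n
        ngk = self.inf_tab.shape[0]
        v = np.full(n, self.v_init)
        gates = np.empty((ngk, n))
        v_mv = self.v_init * 1e3
        x = (v_mv - self.vmin) / self.dv
        j = int(min(max(x, 0.0), self.inf_tab.shape[1] - 1.001))
        w = x - j
        ca0 = self.pool_rest[0]
        for gk in range(ngk):
            if self.special[gk] == GATE_TABLE:
                gates[gk, :] = self.inf_tab[gk, j] * (1 - w) + self.inf_tab[gk, j + 1] * w
            elif self.special[gk] == GATE_BK:
                a_d, a_k, a_b, b_d, b_k, b_b = self.bk
                t = 1.0 / (self.rt_inv * ch.GAS_CONSTANT)  # recover temperature
                al, be = ch.bk_rates(v_mv, ca0, ch.CaDepParams(
                    bk_alpha=(a_d, a_k, a_b), bk_beta=(b_d, b_k, b_b),
                    temperature=t))
                gates[gk, :] = al / (al + be)
            else:
                gates[gk, :] = float(ch.sk_inf(ca0, self.sk[0], self.sk[1]))
        ca_pools = np.empty((3, n))
        for p in range(3):
            ca_pools[p, :] = self.pool_rest[p]
        ns = self.syn_comp.shape[0]
        return SimState(v, gates, ca_pools, np.zeros(ns), np.zeros(ns))


@dataclass
class PlacedSynapse:
    spine_head: str
    receptor: str            # "AMPA" | "NMDA"
    gmax: float
    tau1: float
    tau2: float
    reversal: float          # mV
    mg_A: float = 0.0        # 0 disables the Mg block
    ca_kappa: float = 0.0    # NMDA calcium-flux scale


class MSPNCell:
    """A fully specified model cell for one experiment.

    Parameters
    ----------
    site:
        "secondary" (spines ~40 um from the soma) or "tertiary" (third
        tertiary segment, ~150 um); selects where the two stimulated spines
        attach.
    nmda:
        `NMDASubunitParams` for the stimulated (and background) synapses;
        default is the cortico-striatal GluN2A+B mixture.
    ampa:
        `SynapseSpec`; default 342 pS dual exponential.
    background_spines:
        number of extra spines (with synapses) spread over the dendrites for
        Poisson background input.
    """

    def __init__(self, config: dict | None = None, site: str = "secondary",
                 nmda: sy.NMDASubunitParams | None = None,
                 ampa: sy.SynapseSpec | None = None,
                 background_spines: int = 0,
                 channel_lib: ch.ChannelLibrary | None = None,
                 densities: dict | None = None):
        self.config = config or mo.default_morphology_config()
        self.lib = channel_lib or ch.load_channel_library()
        self.densities = densities or ch.load_densities()
        syn_data = sy._synapse_data()
        if ampa is None:
            am = syn_data["ampa"]
            ampa = sy.SynapseSpec(tau1=am["tau1_ms"] * 1e-3,
                                  tau2=am["tau2_ms"] * 1e-3,
                                  gmax=am["gmax_pS"] * 1e-12,
                                  reversal=am["reversal_mV"])
        self.ampa = ampa
        self.nmda = nmda or sy.make_nmda("GluN2A+B", data=syn_data)
        self.mg_conc = syn_data["extracellular"]["mg_mM"]
        self.ca_out = syn_data["extracellular"]["ca_out_mM"]
        self.site = site

        spine_cfg = self.config["spine"]
        self._spine_geom = dict(
            neck_length=spine_cfg["neck_length_um"],
            neck_diameter=spine_cfg["neck_diameter_um"],
            head_length=spine_cfg["head_length_um"],
            head_diameter=spine_cfg["head_diameter_um"])

        morph = mo.build_mspn_tree(self.config)
        comp_cfg = self.config["spine_compensation"]
        ref_spine = mo.SpineSpec(parent_compartment="_", position_along_parent=0.0,
                                 **self._spine_geom)
        for region in comp_cfg["regions"]:
            morph = mo.apply_spine_compensation(
                morph, comp_cfg["density_per_um"], region, spine=ref_spine)

        sites_cfg = self.config["sites"]
        if site not in sites_cfg:
            raise mo.MorphologyError(f"unknown stimulation site {site!r}")
        site_def = sites_cfg[site]
        specs = [mo.SpineSpec(parent_compartment=site_def["parent"],
                              position_along_parent=pos, **self._spine_geom)
                 for pos in site_def["positions"]]
        n_stim = len(specs)

        bg_parents: list[str] = []
        if background_spines > 0:
            shafts = [c.id for c in morph.compartments
                      if c.region in ("mid_dend", "dist_dend")]
            for b in range(background_spines):
                parent = shafts[(b * 7) % len(shafts)]  # deterministic spread
                bg_parents.append(parent)
                specs.append(mo.SpineSpec(parent_compartment=parent,
                                          position_along_parent=0.5,
                                          **self._spine_geom))
        morph = mo.attach_spines(morph, specs)
        heads = [c.id for c in morph.spine_heads()]
        self.morph = morph
        self.stim_spines = heads[:n_stim]
        self.background_spines_ids = heads[n_stim:]
        self.recorded_spine = self.stim_spines[0]

        cal = self.config["calcium"]
        self.ca_rest = cal["rest_uM"] * 1e-3           # mM
        self.ca_tau = cal["decay_tau_ms"] * 1e-3
        self.ca_tau_shaft = cal.get("shaft_decay_tau_ms",
                                    cal["decay_tau_ms"]) * 1e-3
        self.shell = cal["shell_thickness_um"] * 1e-6
        self.buf_shaft = cal["buffer_capacity_shaft"]
        self.buf_spine = cal["buffer_capacity_spine"]
        self.nmda_ca_fraction = cal["nmda_ca_fraction"]
        self.nmda_ca_driving = cal.get("nmda_ca_driving", "linear")

        kappa = sy.nmda_calcium_scale(
            fraction=self.nmda_ca_fraction, ca_rest=self.ca_rest,
            ca_out=self.ca_out, reversal=0.0, driving=self.nmda_ca_driving,
            temperature=self.lib.temperature)
        self.synapses: list[PlacedSynapse] = []
        for head in heads:
            self.synapses.append(PlacedSynapse(
                spine_head=head, receptor="AMPA", gmax=self.ampa.gmax,
                tau1=self.ampa.tau1, tau2=self.ampa.tau2,
                reversal=self.ampa.reversal))
            self.synapses.append(PlacedSynapse(
                spine_head=head, receptor="NMDA", gmax=self.nmda.gmax,
                tau1=self.nmda.tau_rise, tau2=self.nmda.tau_decay,
                reversal=0.0, mg_A=self.nmda.mg_A, ca_kappa=kappa))

    # ------------------------------------------------------------------
    def compile(self, dt: float) -> CompiledModel:
        """Flatten the cell into kernel arrays for time step ``dt``."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        morph = self.morph
        order = mo.topological_order(morph)
        passive = morph.passive

        # electrical subdivision: sections are split into segments no longer
        # than max_segment_um (soma and spine compartments stay single nodes)
        seg_max = float(self.config.get("electrical", {})
                        .get("max_segment_um", 12.0))
        nseg_map: dict[str, int] = {}
        node_comp: list[tuple[str, int]] = []
        node_index: dict[tuple[str, int], int] = {}
        for cid in order:
            c = morph[cid]
            if c.parent_id is None or c.is_spine_head or c.is_spine_neck:
                nseg = 1
            else:
                nseg = max(1, math.ceil(c.length / seg_max))
            nseg_map[cid] = nseg
            for k in range(nseg):
                node_index[(cid, k)] = len(node_comp)
                node_comp.append((cid, k))
        n = len(node_comp)

        def node_at(cid: str, frac: float) -> int:
            ns = nseg_map[cid]
            k = min(max(math.ceil(frac * ns) - 1, 0), ns - 1)
            return node_index[(cid, k)]

        # distal-end node of each section is its reference node
        index = {cid: node_index[(cid, nseg_map[cid] - 1)] for cid in order}

        parent = np.full(n, -1, dtype=np.int64)
        cm = np.empty(n)
        ga = np.zeros(n)
        gleak = np.empty(n)
        area = np.empty(n)
        half_r = np.empty(n)
        for cid, k in node_comp:
            i = node_index[(cid, k)]
            c = morph[cid]
            ns = nseg_map[cid]
            area[i] = c.membrane_area / ns
            cm[i] = passive.membrane_capacitance * area[i]
            gleak[i] = area[i] / passive.membrane_resistivity
            half_r[i] = (passive.axial_resistivity
                         * (c.length / ns * 1e-6 / 2.0) / c.cross_section)
            if k > 0:
                parent[i] = node_index[(cid, k - 1)]
            elif c.parent_id is not None:
                parent[i] = node_at(c.parent_id, c.parent_attach)
            if parent[i] >= 0:
                ga[i] = 1.0 / (half_r[i] + half_r[parent[i]])

        # ---- gate kinds and tables
        vmin, vmax, dv = -120.0, 60.0, 0.05
        vgrid = np.arange(vmin, vmax + dv / 2, dv)
        nv = vgrid.shape[0]
        gate_index: dict[tuple[str, str], int] = {}
        specials: list[int] = []
        inf_rows: list[np.ndarray] = []
        fac_rows: list[np.ndarray] = []
        for cname, spec in self.lib.channels.items():
            for gate in spec.gates:
                gate_index[(cname, gate.name)] = len(specials)
                if gate.form == "bk":
                    specials.append(GATE_BK)
                    inf_rows.append(np.zeros(nv))
                    fac_rows.append(np.zeros(nv))
                elif gate.form == "sk":
                    specials.append(GATE_SK)
                    inf_rows.append(np.zeros(nv))
                    fac_rows.append(np.zeros(nv))
                else:
                    inf, tau = ch.gate_inf_tau(gate, vgrid)
                    specials.append(GATE_TABLE)
                    inf_rows.append(np.asarray(inf, dtype=float))
                    fac_rows.append(1.0 - np.exp(-dt / np.asarray(tau, dtype=float)))
        special = np.asarray(specials, dtype=np.int64)
        inf_tab = np.vstack(inf_rows)
        fac_tab = np.vstack(fac_rows)

        # ---- channels
        pool_code = {"nr": 0, "vgcc": 1}
        names = list(self.lib.channels)
        nch = len(names)
        ch_mode = np.zeros(nch, dtype=np.int64)
        ch_erev = np.zeros(nch)
        ch_g1 = np.zeros(nch, dtype=np.int64)
        ch_g2 = np.full(nch, -1, dtype=np.int64)
        ch_e1 = np.ones(nch, dtype=np.int64)
        ch_e2 = np.ones(nch, dtype=np.int64)
        ch_pool = np.zeros(nch, dtype=np.int64)
        ch_gbar = np.zeros((nch, n))
        for k, cname in enumerate(names):
            spec = self.lib.channels[cname]
            ch_mode[k] = 0 if spec.mode == "ohmic" else 1
            ch_erev[k] = spec.reversal * 1e-3
            ch_g1[k] = gate_index[(cname, spec.gates[0].name)]
            ch_e1[k] = spec.gates[0].exponent
            if len(spec.gates) > 1:
                ch_g2[k] = gate_index[(cname, spec.gates[1].name)]
                ch_e2[k] = spec.gates[1].exponent
            if spec.mode == "ghk":
                ch_pool[k] = pool_code[spec.calcium_source_pool]
            dens = self.densities.get(cname, {})
            for cid, kseg in node_comp:
                i = node_index[(cid, kseg)]
                c = morph[cid]
                if c.is_spine_neck:
                    continue
                d = dens.get(c.region, 0.0)
                if d:
                    # spine compensation scales passive membrane only; the
                    # folded-in spine membrane carries no extra channels
                    ch_gbar[k, i] = d * area[i] / c.area_scale

        # ---- calcium pools (shaft pools clear faster than the spine pool)
        pool_rest = np.full(3, self.ca_rest)
        pool_decay = np.array([math.exp(-dt / self.ca_tau_shaft),
                               math.exp(-dt / self.ca_tau_shaft),
                               math.exp(-dt / self.ca_tau)])
        pool_tau2fv = np.empty((3, n))
        for cid, kseg in node_comp:
            i = node_index[(cid, kseg)]
            c = morph[cid]
            shell_vol = area[i] / max(c.area_scale, 1.0) * self.shell
            vol_shaft = shell_vol * self.buf_shaft
            pool_tau2fv[0, i] = self.ca_tau_shaft / (2 * ch.FARADAY * vol_shaft)
            pool_tau2fv[1, i] = self.ca_tau_shaft / (2 * ch.FARADAY * vol_shaft)
            if c.is_spine_head:
                vol_sp = c.volume * self.buf_spine
                pool_tau2fv[2, i] = self.ca_tau / (2 * ch.FARADAY * vol_sp)
            else:
                pool_tau2fv[2, i] = self.ca_tau / (2 * ch.FARADAY * vol_shaft)

        # ---- synapses
        ns = len(self.synapses)
        syn_comp = np.zeros(ns, dtype=np.int64)
        syn_gmax = np.zeros(ns)
        syn_k = np.zeros(ns)
        syn_faca = np.zeros(ns)
        syn_facb = np.zeros(ns)
        syn_erev = np.zeros(ns)
        syn_mga = np.zeros(ns)
        syn_kappa = np.zeros(ns)
        syn_index: dict[tuple[str, str], int] = {}
        for s, psy in enumerate(self.synapses):
            syn_comp[s] = index[psy.spine_head]
            syn_gmax[s] = psy.gmax
            syn_k[s] = sy.norm_const(psy.tau1, psy.tau2)
            syn_faca[s] = math.exp(-dt / psy.tau1)
            syn_facb[s] = math.exp(-dt / psy.tau2)
            syn_erev[s] = psy.reversal * 1e-3
            syn_mga[s] = psy.mg_A
            syn_kappa[s] = psy.ca_kappa
            syn_index[(psy.spine_head, psy.receptor)] = s

        bkp = self.lib.ca_params
        return CompiledModel(
            dt=dt, n=n, parent=parent, cm=cm, ga=ga, gleak=gleak,
            eleak=passive.leak_reversal * 1e-3,
            special=special, inf_tab=inf_tab, fac_tab=fac_tab, vmin=vmin, dv=dv,
            bk=(bkp.bk_alpha[0], bkp.bk_alpha[1], bkp.bk_alpha[2],
                bkp.bk_beta[0], bkp.bk_beta[1], bkp.bk_beta[2]),
            sk=(bkp.sk_ec50, bkp.sk_hill, 1.0 - math.exp(-dt / bkp.sk_tau)),
            ch_mode=ch_mode, ch_erev=ch_erev, ch_g1=ch_g1, ch_g2=ch_g2,
            ch_e1=ch_e1, ch_e2=ch_e2, ch_gbar=ch_gbar, ch_pool=ch_pool,
            ca_out=self.ca_out,
            rt_inv=1.0 / (ch.GAS_CONSTANT * self.lib.temperature),
            pool_rest=pool_rest, pool_decay=pool_decay, pool_tau2fv=pool_tau2fv,
            syn_comp=syn_comp, syn_gmax=syn_gmax, syn_k=syn_k,
            syn_faca=syn_faca, syn_facb=syn_facb, syn_erev=syn_erev,
            syn_mga=syn_mga, syn_mgscale=self.lib.mg_voltage_scale,
            mg_conc=self.mg_conc, syn_kappa=syn_kappa,
            nmda_ca_linear=(self.nmda_ca_driving == "linear"),
            eca=sy.calcium_nernst(self.ca_rest, self.ca_out,
                                  self.lib.temperature) * 1e-3,
            comp_index=index, gate_index=gate_index, syn_index=syn_index,
            v_init=passive.resting_potential_target * 1e-3)
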