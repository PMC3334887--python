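"""MSPN compartmental tree: soma, branched dendrites, explicit spines.

The default cell has four primary dendrites (20 um), each bifurcating into
two secondaries (24 um), each bifurcating into two tertiary branches of 11
chained 36 um segments.  Explicit two-compartment spines (neck + head) are
attached only where synapses are placed or recorded; the membrane of the
remaining spines is folded into the dendritic shafts by scaling membrane
capacitance up and membrane resistance down ("spine compensation").

Compartment ids follow the branch path, e.g. ``p0.s1.t0.seg3`` is the third
segment of tertiary branch 0 off secondary 1 off primary 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .channels import _load_yaml

REGIONS = ("soma", "prox_dend", "mid_dend", "dist_dend", "spine")


class MorphologyError(ValueError):
    """Raised for invalid morphology configurations."""


@dataclass(frozen=True)
class PassiveParams:
    """Passive electrical membrane parameters.

    membrane_resistivity in ohm m^2, membrane_capacitance in F/m^2, axial
    resistivity in ohm m, potentials in mV.
    """

    membrane_resistivity: float = 3.0
    membrane_capacitance: float = 0.01
    axial_resistivity: float = 1.0
    leak_reversal: float = -65.0
    resting_potential_target: float = -85.0

    def __post_init__(self) -> None:
        if min(self.membrane_resistivity, self.membrane_capacitance,
               self.axial_resistivity) <= 0:
            raise MorphologyError("passive resistivities/capacitance must be positive")
        if not -120.0 <= self.leak_reversal <= 0.0:
            raise MorphologyError("leak reversal outside [-120, 0] mV")


@dataclass
class CompartmentSpec:
    """One cylindrical compartment (lengths/diameters in um)."""

    id: str
    parent_id: str | None
    length: float
    diameter: float
    region: str
    channel_densities: dict[str, float] = field(default_factory=dict)
    is_spine_head: bool = False
    is_spine_neck: bool = False
    parent_attach: float = 1.0   # fraction along the parent where this attaches
    area_scale: float = 1.0      # spine-compensation membrane scaling

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise MorphologyError(f"{self.id}: length and diameter must be positive")
        if self.region not in REGIONS:
            raise MorphologyError(f"{self.id}: unknown region {self.region!r}")

    @property
    def membrane_area(self) -> float:
        """Lateral membrane area in m^2 (spine compensation included)."""
        return math.pi * self.diameter * self.length * 1e-12 * self.area_scale

    @property
    def cross_section(self) -> float:
        """Axial cross-section in m^2."""
        return math.pi * (self.diameter / 2.0) ** 2 * 1e-12

    @property
    def volume(self) -> float:
        """Cylinder volume in m^3."""
        return self.cross_section * self.length * 1e-6


@dataclass(frozen=True)
class SpineSpec:
    """Explicit spine geometry (um) and attachment point."""

    parent_compartment: str
    position_along_parent: float
    neck_length: float = 0.5
    neck_diameter: float = 0.12
    head_length: float = 0.5
    head_diameter: float = 0.5

    def __post_init__(self) -> None:
        if min(self.neck_length, self.neck_diameter,
               self.head_length, self.head_diameter) <= 0:
            raise MorphologyError("spine dimensions must be positive")
        if not 0.0 <= self.position_along_parent <= 1.0:
            raise MorphologyError("spine position must lie in [0, 1]")

    @property
    def membrane_area(self) -> float:
        """Added membrane per spine (um^2), neck plus head lateral area."""
        return math.pi * (self.neck_diameter * self.neck_length
                          + self.head_diameter * self.head_length)


@dataclass
class MorphologySpec:
    compartments: list[CompartmentSpec]
    passive: PassiveParams
    spine_compensation_factor_by_region: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {c.id: c for c in self.compartments}
        roots = [c for c in self.compartments if c.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError("exactly one root (soma) compartment required")
        for c in self.compartments:
            if c.parent_id is not None and c.parent_id not in self._index:
                raise MorphologyError(f"{c.id}: parent {c.parent_id!r} missing")

    def __getitem__(self, comp_id: str) -> CompartmentSpec:
        return self._index[comp_id]

    def __contains__(self, comp_id: str) -> bool:
        return comp_id in self._index

    @property
    def root(self) -> CompartmentSpec:
        return next(c for c in self.compartments if c.parent_id is None)

    def children(self, comp_id: str) -> list[CompartmentSpec]:
        return [c for c in self.compartments if c.parent_id == comp_id]

    def spine_heads(self) -> list[CompartmentSpec]:
        return [c for c in self.compartments if c.is_spine_head]


DEFAULT_CONFIG_FILE = "morphology.yml"


def default_morphology_config() -> dict:
    """The packaged default morphology/passive/site configuration."""
    return _load_yaml(DEFAULT_CONFIG_FILE)


def passive_from_config(cfg: dict) -> PassiveParams:
    p = cfg["passive"]
    return PassiveParams(
        membrane_resistivity=p["membrane_resistivity_ohm_m2"],
        membrane_capacitance=p["membrane_capacitance_F_m2"],
        axial_resistivity=p["axial_resistivity_ohm_m"],
        leak_reversal=p["leak_reversal_mV"],
        resting_potential_target=p["resting_potential_target_mV"],
    )


def build_mspn_tree(config: dict | None = None) -> MorphologySpec:
    """Build the branched MSPN tree (no spines) from a morphology config.

    Region labels: primaries are proximal dendrite; secondaries and the first
    tertiary segment are middle dendrite; tertiary segments 2-11 are distal
    dendrite (this matches the three-zone density gradient of the fast
    channels and the proximal/distal stimulation sites).
    """
    cfg = config or default_morphology_config()
    passive = passive_from_config(cfg)
    soma = cfg["soma"]
    prim, sec, ter = cfg["primary"], cfg["secondary"], cfg["tertiary"]
    n_prim = int(prim["count"])
    n_sec = int(sec["per_primary"])
    n_ter = int(ter["per_secondary"])
    n_seg = int(ter["segments"])
    if min(n_prim, n_sec, n_ter, n_seg) <= 0:
        raise MorphologyError("branch counts and segment counts must be positive")
    for blk in (soma, prim, sec, ter):
        for key, val in blk.items():
            if key.endswith("_um") and val <= 0:
                raise MorphologyError(f"non-positive morphology length: {key}")

    comps: list[CompartmentSpec] = [
        CompartmentSpec(id="soma", parent_id=None, region="soma",
                        length=soma["length_um"], diameter=soma["diameter_um"])
    ]
    for i in range(n_prim):
        pid = f"p{i}"
        comps.append(CompartmentSpec(
            id=pid, parent_id="soma", region="prox_dend",
            length=prim["length_um"], diameter=prim["diameter_um"]))
        for j in range(n_sec):
            sid = f"{pid}.s{j}"
            comps.append(CompartmentSpec(
                id=sid, parent_id=pid, region="mid_dend",
                length=sec["length_um"], diameter=sec["diameter_um"]))
            for k in range(n_ter):
                prev = sid
                for seg in range(1, n_seg + 1):
                    tid = f"{sid}.t{k}.seg{seg}"
                    comps.append(CompartmentSpec(
                        id=tid, parent_id=prev,
                        region="mid_dend" if seg == 1 else "dist_dend",
                        length=ter["segment_length_um"],
                        diameter=ter["diameter_um"]))
                    prev = tid
    return MorphologySpec(compartments=comps, passive=passive)


def attach_spines(morph: MorphologySpec, sites: list[SpineSpec]) -> MorphologySpec:
    """Return a new morphology with explicit neck+head spine compartments added.

    Spine heads carry the spine-region channel density column and are the
    synapse attachment points.
    """
    comps = [replace(c) for c in morph.compartments]
    existing = {c.id for c in comps}
    for n, site in enumerate(sites):
        parent = site.parent_compartment
        if parent not in existing:
            raise MorphologyError(f"spine parent {parent!r} not in morphology")
        pc = morph[parent]
        if pc.is_spine_head or pc.is_spine_neck:
            raise MorphologyError("cannot attach a spine to a spine")
        neck_id = f"{parent}.sp{n}.neck"
        head_id = f"{parent}.sp{n}.head"
        comps.append(CompartmentSpec(
            id=neck_id, parent_id=parent, region="spine",
            length=site.neck_length, diameter=site.neck_diameter,
            is_spine_neck=True, parent_attach=site.position_along_parent))
        comps.append(CompartmentSpec(
            id=head_id, parent_id=neck_id, region="spine",
            length=site.head_length, diameter=site.head_diameter,
            is_spine_head=True))
        existing.update((neck_id, head_id))
    return MorphologySpec(compartments=comps, passive=morph.passive,
                          spine_compensation_factor_by_region=dict(
                              morph.spine_compensation_factor_by_region))


def path_distance(morph: MorphologySpec, compartment: str,
                  position: float = 1.0) -> float:
    """Path distance (um) from the soma center to ``position`` along a compartment.

    The soma contributes zero length; each ancestor dendrite contributes the
    fraction of its length up to the point where the path branches off it.
    """
    if compartment not in morph:
        raise MorphologyError(f"unknown compartment {compartment!r}")
    comp = morph[compartment]
    dist = 0.0
    frac = position
    while comp.parent_id is not None:
        dist += frac * comp.length
        frac = comp.parent_attach
        comp = morph[comp.parent_id]
    return dist


def apply_spine_compensation(morph: MorphologySpec, density: float,
                             region: str,
                             spine: SpineSpec | None = None) -> MorphologySpec:
    """Fold unmodeled spine membrane into shaft compartments of one region.

    ``density`` is spines per um of dendrite.  Each compartment's membrane
    area (hence capacitance, and conductance densities referred to area) is
    scaled by ``f = 1 + density * area_per_spine / (pi * diameter)``, which
    equals the (shaft + spine)/shaft membrane ratio; ``f(0) = 1``.
    """
    if density < 0:
        raise MorphologyError("spine density must be nonnegative")
    if region not in REGIONS:
        raise MorphologyError(f"unknown region {region!r}")
    spine_area = (spine or SpineSpec(parent_compartment="_", position_along_parent=0.0)
                  ).membrane_area  # um^2 per spine
    comps = []
    factors = dict(morph.spine_compensation_factor_by_region)
    for c in morph.compartments:
        c = replace(c)
        if c.region == region and not (c.is_spine_head or c.is_spine_neck):
            f = 1.0 + density * spine_area / (math.pi * c.diameter)
            c.area_scale *= f
            factors[region] = f
        comps.append(c)
    return MorphologySpec(compartments=comps, passive=morph.passive,
                          spine_compensation_factor_by_region=factors)


def to_swc(morph: MorphologySpec) -> str:
    """Serialize the tree as SWC text (coordinates synthesized from path layout).

    Soma is type 1, dendrites type 3, spines type 4 by local convention.
    Each compartment becomes one SWC point at its distal end.
    """
    order = topological_order(morph)
    index = {cid: i + 1 for i, cid in enumerate(order)}
    # lay each root-emanating subtree along its own direction in the xy plane
    angles: dict[str, float] = {}
    prim_ids = [c.id for c in morph.children(morph.root.id)]
    for i, pid in enumerate(prim_ids):
        angles[pid] = 2.0 * math.pi * i / max(len(prim_ids), 1)
    lines = ["# generated by mspncalc", "# id type x y z radius parent"]
    coords: dict[str, tuple[float, float, float]] = {morph.root.id: (0.0, 0.0, 0.0)}
    for cid in order:
        c = morph[cid]
        if c.parent_id is None:
            kind = 1
            x = y = z = 0.0
        else:
            px, py, pz = coords[c.parent_id]
            top = cid
            while morph[top].parent_id is not None and morph[top].parent_id != morph.root.id:
                top = morph[top].parent_id
            theta = angles.get(top, 0.0)
            if c.is_spine_neck or c.is_spine_head:
                kind = 4
                x, y, z = px, py, pz + c.length
            else:
                kind = 3
                x = px + c.length * math.cos(theta)
                y = py + c.length * math.sin(theta)
                z = pz
        coords[cid] = (x, y, z)
        parent_idx = -1 if c.parent_id is None else index[c.parent_id]
        lines.append(f"{index[cid]} {kind} {x:.3f} {y:.3f} {z:.3f} "
                     f"{c.diameter / 2.0:.4f} {parent_idx}")
    return "\n".join(lines) + "\n"


def topological_order(morph: MorphologySpec) -> list[str]:
    """Compartment ids ordered root-first with every parent before its children."""
    children: dict[str | None, list[str]] = {}
    for c in morph.compartments:
        children.setdefault(c.parent_id, []).append(c.id)
    order: list[str] = []
    stack = [morph.root.id]
    while stack:
        cid = stack.pop()
        order.append(cid)
        stack.extend(reversed(children.get(cid, [])))
    if len(order) != len(morph.compartments):
        raise MorphologyError("morphology tree is not connected")
    return order
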