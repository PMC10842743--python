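"""Multi-compartment neuron morphologies: representation, SWC I/O, synthetic
archetypes, discretization and myelination.

A morphology is a rooted tree of cylindrical compartments. The root is always
a single isopotential soma cylinder; every other compartment is an edge from
its parent's attachment point to its own distal point ``p1``. Geometry is in
micrometres throughout.

Synthetic archetypes are stylized stand-ins for layer-specific cortical cell
types (pyramidal cells in L2/3, L5, L6; an L1 neurogliaform cell; an L4 large
basket cell): straight apical trunks, radiating basal dendrites and descending
axons with oblique collaterals, with stochastically varied branch geometry per
clone seed. They reproduce qualitative polarization orderings (terminals over
soma, pyramidal over interneuron somas), not any specific reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SectionKind",
    "Compartment",
    "Morphology",
    "ArchetypeSpec",
    "MyelinRule",
    "ARCHETYPE_LABELS",
    "archetype_spec",
    "read_swc",
    "write_swc",
    "read_myelin_sidecar",
    "write_myelin_sidecar",
    "generate_archetype",
    "discretize",
    "apply_myelin",
    "region_index",
]

ROOT_PARENT = -1

# SWC type codes. 1-4 are the standard assignments; 7 (the "custom" code) is
# used for myelin internodes and documented in the file header on write.
_SWC_CODE_TO_KIND = {}
_KIND_TO_SWC_CODE = {}


class SectionKind(str, Enum):
    """Subcellular section label carried by every compartment."""

    SOMA = "soma"
    AXON = "axon"
    BASAL_DENDRITE = "basal_dendrite"
    APICAL_DENDRITE = "apical_dendrite"
    MYELIN_INTERNODE = "myelin_internode"


_SWC_CODE_TO_KIND.update(
    {
        1: SectionKind.SOMA,
        2: SectionKind.AXON,
        3: SectionKind.BASAL_DENDRITE,
        4: SectionKind.APICAL_DENDRITE,
        7: SectionKind.MYELIN_INTERNODE,
    }
)
_KIND_TO_SWC_CODE.update({k: c for c, k in _SWC_CODE_TO_KIND.items()})


class MorphologyError(ValueError):
    """Structural or parse error in a morphology or SWC file."""


@dataclass(frozen=True)
class Compartment:
    """One cylindrical cable element.

    ``p0`` and ``p1`` are the proximal and distal end points in μm; ``diameter``
    is in μm. ``parent_id`` is the index of the parent compartment, or
    ``ROOT_PARENT`` for the soma root.
    """

    id: int
    parent_id: int
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    diameter: float
    kind: SectionKind
    myelinated: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.p0) + np.asarray(self.p1)) / 2.0


@dataclass
class Morphology:
    """Rooted compartmental tree with a somatodendritic reference axis."""

    compartments: list[Compartment]
    somatodendritic_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    archetype_label: str = ""
    clone_seed: int = 0

    def __post_init__(self) -> None:
        self.somatodendritic_axis = np.asarray(self.somatodendritic_axis, float)
        n = np.linalg.norm(self.somatodendritic_axis)
        if n > 0:
            self.somatodendritic_axis = self.somatodendritic_axis / n
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        comps = self.compartments
        if not comps:
            raise MorphologyError("morphology has no compartments")
        ids = [c.id for c in comps]
        if ids != list(range(len(comps))):
            raise MorphologyError("compartment ids must be 0..n-1 in order")
        roots = [c for c in comps if c.parent_id == ROOT_PARENT]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        if roots[0].kind is not SectionKind.SOMA:
            raise MorphologyError("root compartment must be the soma")
        idset = set(ids)
        for c in comps:
            if c.parent_id != ROOT_PARENT:
                if c.parent_id not in idset:
                    raise MorphologyError(
                        f"compartment {c.id} references missing parent {c.parent_id}"
                    )
                if c.parent_id >= c.id:
                    raise MorphologyError(
                        f"compartment {c.id} has non-topological parent order "
                        f"(parent {c.parent_id}); cycles are impossible only for "
                        "parent_id < id"
                    )
            if c.length <= 0:
                raise MorphologyError(f"compartment {c.id} has zero length")
            if c.diameter <= 0:
                raise MorphologyError(f"compartment {c.id} has non-positive diameter")

    # -- convenience array views ------------------------------------------
    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def root(self) -> Compartment:
        return next(c for c in self.compartments if c.parent_id == ROOT_PARENT)

    @property
    def soma_center(self) -> np.ndarray:
        return self.root.midpoint

    def midpoints(self) -> np.ndarray:
        """(n, 3) array of compartment midpoints, μm."""
        return np.array([c.midpoint for c in self.compartments])

    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.compartments])

    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.compartments])

    def parents(self) -> np.ndarray:
        return np.array([c.parent_id for c in self.compartments])

    def kinds(self) -> list[SectionKind]:
        return [c.kind for c in self.compartments]

    def children_counts(self) -> np.ndarray:
        counts = np.zeros(self.n, dtype=int)
        for c in self.compartments:
            if c.parent_id != ROOT_PARENT:
                counts[c.parent_id] += 1
        return counts

    def leaves(self) -> np.ndarray:
        """Indices of terminal compartments (no children), excluding the soma."""
        counts = self.children_counts()
        return np.array(
            [c.id for c in self.compartments
             if counts[c.id] == 0 and c.parent_id != ROOT_PARENT],
            dtype=int,
        )

    def attach_point(self, comp_id: int) -> np.ndarray:
        """Point where children of ``comp_id`` attach (soma children attach at
        the soma center; otherwise at the distal end)."""
        c = self.compartments[comp_id]
        if c.parent_id == ROOT_PARENT:
            return c.midpoint
        return np.asarray(c.p1, float)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    SWC samples are points; each non-root sample becomes the distal end of a
    compartment whose proximal end is its parent sample's position (the soma
    center for children of the root). The root sample becomes a single soma
    cylinder of length equal to its diameter, oriented along +z.
    """
    path = Path(path)
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            sid = int(parts[0])
            code = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise MorphologyError(f"{path}:{lineno}: malformed record: {exc}") from exc
        if code not in _SWC_CODE_TO_KIND:
            raise MorphologyError(f"{path}:{lineno}: unsupported SWC type code {code}")
        if sid in samples:
            raise MorphologyError(f"{path}:{lineno}: duplicate sample id {sid}")
        samples[sid] = (code, x, y, z, r, parent)
        order.append(sid)

    if not order:
        raise MorphologyError(f"{path}: no SWC records")

    roots = [sid for sid in order if samples[sid][5] == -1]
    if len(roots) != 1:
        raise MorphologyError(f"{path}: expected exactly one root sample, found {len(roots)}")
    for sid in order:
        parent = samples[sid][5]
        if parent != -1 and parent not in samples:
            raise MorphologyError(f"{path}: sample {sid} references missing parent {parent}")

    # Topological order (parents before children) preserving file order where
    # possible, so write_swc(read_swc(f)) round-trips records; detects cycles.
    import heapq

    children: dict[int, list[int]] = {sid: [] for sid in order}
    for sid in order:
        parent = samples[sid][5]
        if parent != -1:
            children[parent].append(sid)
    pos = {sid: i for i, sid in enumerate(order)}
    topo: list[int] = []
    ready = [pos[roots[0]]]
    while ready:
        sid = order[heapq.heappop(ready)]
        topo.append(sid)
        for child in children[sid]:
            heapq.heappush(ready, pos[child])
    if len(topo) != len(order):
        raise MorphologyError(f"{path}: cyclic or disconnected parent links")

    new_id = {sid: i for i, sid in enumerate(topo)}
    comps: list[Compartment] = []
    root_code, rx, ry, rz, rr, _ = samples[roots[0]]
    if _SWC_CODE_TO_KIND[root_code] is not SectionKind.SOMA:
        raise MorphologyError(f"{path}: root sample must be soma (type 1)")
    half = rr  # soma cylinder length = diameter
    comps.append(
        Compartment(0, ROOT_PARENT, (rx, ry, rz - half), (rx, ry, rz + half),
                    2.0 * rr, SectionKind.SOMA)
    )
    positions = {roots[0]: np.array([rx, ry, rz])}
    for sid in topo[1:]:
        code, x, y, z, r, parent = samples[sid]
        kind = _SWC_CODE_TO_KIND[code]
        p0 = positions[parent] if new_id[parent] > 0 else np.array([rx, ry, rz])
        comps.append(
            Compartment(
                new_id[sid], new_id[parent], tuple(p0), (x, y, z), 2.0 * r, kind,
                myelinated=kind is SectionKind.MYELIN_INTERNODE,
            )
        )
        positions[sid] = np.array([x, y, z])
    return Morphology(comps, archetype_label=path.stem)


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write a :class:`Morphology` as SWC (one sample per compartment).

    The root sample is the soma center with radius = diameter/2; other samples
    are distal compartment ends. Myelin internodes use custom type code 7.
    """
    if not m.compartments:
        raise MorphologyError("cannot write an empty morphology")
    path = Path(path)
    lines = [
        "# SWC written by neuropolar",
        "# type codes: 1 soma, 2 axon, 3 basal dendrite, 4 apical dendrite,"
        " 7 myelin internode (custom)",
        "# index type x y z radius parent",
    ]
    for c in m.compartments:
        if c.parent_id == ROOT_PARENT:
            x, y, z = c.midpoint
            r = c.diameter / 2.0
            lines.append(f"1 1 {x:.6g} {y:.6g} {z:.6g} {r:.6g} -1")
        else:
            x, y, z = c.p1
            code = _KIND_TO_SWC_CODE[c.kind]
            lines.append(
                f"{c.id + 1} {code} {x:.6g} {y:.6g} {z:.6g} {c.diameter / 2.0:.6g} "
                f"{c.parent_id + 1}"
            )
    path.write_text("\n".join(lines) + "\n")


def write_myelin_sidecar(m: Morphology, path: str | Path) -> None:
    """Write the myelination flags as a TSV sidecar (compartment_id, myelinated).

    SWC has no myelin field; the sidecar keeps the SWC itself readable by
    standard tools while preserving the flags losslessly.
    """
    lines = ["compartment_id\tmyelinated"]
    lines += [f"{c.id}\t{int(c.myelinated)}" for c in m.compartments]
    Path(path).write_text("\n".join(lines) + "\n")


def read_myelin_sidecar(m: Morphology, path: str | Path) -> Morphology:
    """Apply myelination flags from a sidecar TSV to ``m`` (returns a copy)."""
    flags = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines()):
        if lineno == 0 and line.startswith("compartment_id"):
            continue
        if not line.strip():
            continue
        cid, flag = line.split("\t")
        flags[int(cid)] = bool(int(flag))
    comps = [
        replace(
            c,
            myelinated=flags.get(c.id, False),
            kind=(
                SectionKind.MYELIN_INTERNODE
                if flags.get(c.id, False)
                else (SectionKind.AXON if c.kind is SectionKind.MYELIN_INTERNODE else c.kind)
            ),
        )
        for c in m.compartments
    ]
    return Morphology(comps, m.somatodendritic_axis, m.archetype_label, m.clone_seed)


# ---------------------------------------------------------------------------
# Synthetic archetypes
# ---------------------------------------------------------------------------

ARCHETYPE_LABELS = ("L1_NGC", "L23_PC", "L4_LBC", "L5_PC", "L6_PC")
_PC_LABELS = ("L23_PC", "L5_PC", "L6_PC")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of a stylized layer-specific cell archetype.

    Pyramidal-cell (PC) archetypes carry an apical trunk with a distal tuft;
    interneuron archetypes (L1 neurogliaform, L4 large basket) have no apical
    dendrite and radially symmetric dendrites.
    """

    archetype_label: str
    n_basal_branches: int
    n_apical_tuft_branches: int
    n_axon_collaterals: int
    trunk_length: float  # μm
    collateral_length_mean: float  # μm
    branch_angle_spread: float  # degrees
    myelinate_axon: bool
    seed: int

    def __post_init__(self) -> None:
        if self.archetype_label not in ARCHETYPE_LABELS:
            raise MorphologyError(f"unknown archetype {self.archetype_label!r}")
        if min(self.n_basal_branches, self.n_apical_tuft_branches,
               self.n_axon_collaterals) < 0:
            raise MorphologyError("branch counts must be non-negative")
        if self.trunk_length <= 0 or self.collateral_length_mean <= 0:
            raise MorphologyError("lengths must be positive")
        is_pc = self.archetype_label in _PC_LABELS
        if is_pc and self.n_apical_tuft_branches < 1:
            raise MorphologyError("PC archetypes need at least one apical tuft branch")
        if not is_pc and self.n_apical_tuft_branches != 0:
            raise MorphologyError("interneuron archetypes have no apical dendrite")

    @property
    def is_pyramidal(self) -> bool:
        return self.archetype_label in _PC_LABELS


_ARCHETYPE_DEFAULTS: dict[str, dict] = {
    # Trunk lengths scale roughly with somatodendritic extent by layer;
    # interneurons are compact and radially symmetric.
    "L1_NGC": dict(n_basal_branches=8, n_apical_tuft_branches=0,
                   n_axon_collaterals=4, trunk_length=120.0,
                   collateral_length_mean=150.0, branch_angle_spread=60.0,
                   myelinate_axon=False),
    "L23_PC": dict(n_basal_branches=5, n_apical_tuft_branches=4,
                   n_axon_collaterals=4, trunk_length=420.0,
                   collateral_length_mean=250.0, branch_angle_spread=35.0,
                   myelinate_axon=True),
    "L4_LBC": dict(n_basal_branches=8, n_apical_tuft_branches=0,
                   n_axon_collaterals=5, trunk_length=180.0,
                   collateral_length_mean=200.0, branch_angle_spread=55.0,
                   myelinate_axon=False),
    "L5_PC": dict(n_basal_branches=6, n_apical_tuft_branches=5,
                  n_axon_collaterals=5, trunk_length=700.0,
                  collateral_length_mean=300.0, branch_angle_spread=35.0,
                  myelinate_axon=True),
    "L6_PC": dict(n_basal_branches=5, n_apical_tuft_branches=3,
                  n_axon_collaterals=4, trunk_length=550.0,
                  collateral_length_mean=250.0, branch_angle_spread=30.0,
                  myelinate_axon=True),
}


def archetype_spec(label: str, seed: int = 0, **overrides) -> ArchetypeSpec:
    """Default :class:`ArchetypeSpec` for one of the five archetype labels."""
    if label not in _ARCHETYPE_DEFAULTS:
        raise MorphologyError(f"unknown archetype {label!r}")
    kw = dict(_ARCHETYPE_DEFAULTS[label])
    kw.update(overrides)
    return ArchetypeSpec(archetype_label=label, seed=seed, **kw)


class _Builder:
    """Accumulates compartments during archetype generation."""

    def __init__(self, soma_diameter: float):
        half = soma_diameter / 2.0
        self.comps: list[Compartment] = [
            Compartment(0, ROOT_PARENT, (0.0, 0.0, -half), (0.0, 0.0, half),
                        soma_diameter, SectionKind.SOMA)
        ]
        self.points: dict[int, np.ndarray] = {0: np.zeros(3)}

    def add(self, parent: int, p1: np.ndarray, diameter: float,
            kind: SectionKind) -> int:
        cid = len(self.comps)
        p0 = self.points[parent]
        self.comps.append(
            Compartment(cid, parent, tuple(p0), tuple(p1), diameter, kind)
        )
        self.points[cid] = np.asarray(p1, float)
        return cid

    def grow(self, parent: int, direction: np.ndarray, length: float,
             diameter: float, kind: SectionKind, n_seg: int = 1) -> int:
        """Grow a straight unbranched cable of ``n_seg`` compartments."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        cur = parent
        for i in range(n_seg):
            p1 = self.points[cur] + d * (length / n_seg)
            cur = self.add(cur, p1, diameter, kind)
        return cur


def _unit_from_angles(polar_deg: float, azim_deg: float) -> np.ndarray:
    t, p = math.radians(polar_deg), math.radians(azim_deg)
    return np.array(
        [math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)]
    )


def generate_archetype(spec: ArchetypeSpec) -> Morphology:
    """Generate a stylized morphology from an archetype spec.

    Deterministic given ``spec.seed``. PCs: apical trunk along +z with a distal
    tuft, radiating basal dendrites, a descending axon with oblique
    collaterals. Interneurons: radially symmetric dendrites, a local axon with
    collaterals. The somatodendritic axis is +z.
    """
    rng = np.random.default_rng(spec.seed)
    soma_diam = 15.0 if spec.is_pyramidal else 10.0
    b = _Builder(soma_diam)
    spread = spec.branch_angle_spread

    # Apical trunk + tuft (PCs only)
    if spec.is_pyramidal:
        trunk_tip = b.grow(0, [0, 0, 1], spec.trunk_length, 2.5,
                           SectionKind.APICAL_DENDRITE, n_seg=4)
        for k in range(spec.n_apical_tuft_branches):
            azim = 360.0 * k / spec.n_apical_tuft_branches + rng.uniform(-20, 20)
            polar = rng.uniform(15, spread)
            length = spec.trunk_length * rng.uniform(0.25, 0.45)
            b.grow(trunk_tip, _unit_from_angles(polar, azim), length, 1.2,
                   SectionKind.APICAL_DENDRITE, n_seg=2)

    # Basal dendrites: radiate downward/lateral for PCs, isotropically for
    # interneurons.
    for k in range(spec.n_basal_branches):
        azim = 360.0 * k / max(spec.n_basal_branches, 1) + rng.uniform(-25, 25)
        if spec.is_pyramidal:
            polar = rng.uniform(95, 150)
        else:
            polar = rng.uniform(15, 165)
        length = spec.collateral_length_mean * rng.uniform(0.5, 0.9)
        tip = b.grow(0, _unit_from_angles(polar, azim), length, 1.5,
                     SectionKind.BASAL_DENDRITE, n_seg=2)
        if rng.random() < 0.5:  # terminal bifurcation on some branches
            for sign in (+1.0, -1.0):
                d2 = _unit_from_angles(polar + sign * rng.uniform(10, spread),
                                       azim + rng.uniform(-spread, spread))
                b.grow(tip, d2, length * 0.5, 1.0, SectionKind.BASAL_DENDRITE)

    # Axon: initial segment descends, main branch continues, oblique
    # collaterals leave the main branch at staggered depths.
    axon_diam = 1.2
    main_dir = _unit_from_angles(170.0 if spec.is_pyramidal else 150.0,
                                 rng.uniform(0, 360))
    hillock = b.grow(0, main_dir, 40.0, axon_diam, SectionKind.AXON)
    main_len = spec.trunk_length * (1.2 if spec.is_pyramidal else 1.5)
    n_nodes = max(spec.n_axon_collaterals, 1)
    cur = hillock
    branch_points = []
    for k in range(n_nodes):
        cur = b.grow(cur, main_dir, main_len / n_nodes, axon_diam,
                     SectionKind.AXON, n_seg=2)
        branch_points.append(cur)
    # main axon terminal segment
    b.grow(cur, main_dir, spec.collateral_length_mean * 0.4, axon_diam,
           SectionKind.AXON)
    for k in range(spec.n_axon_collaterals):
        parent = branch_points[k % len(branch_points)]
        azim = rng.uniform(0, 360)
        polar = rng.uniform(60, 120) if spec.is_pyramidal else rng.uniform(30, 150)
        length = spec.collateral_length_mean * rng.uniform(0.7, 1.3)
        b.grow(parent, _unit_from_angles(polar, azim), length, 0.8,
               SectionKind.AXON, n_seg=2)

    m = Morphology(
        b.comps,
        somatodendritic_axis=np.array([0.0, 0.0, 1.0]),
        archetype_label=spec.archetype_label,
        clone_seed=spec.seed,
    )
    if spec.myelinate_axon:
        m = apply_myelin(m, MyelinRule())
    return m


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(m: Morphology, max_len: float = 20.0) -> Morphology:
    """Split compartments so every one is at most ``max_len`` μm long.

    Length-conserving and idempotent; kinds, diameters and myelin flags are
    inherited, topology (branch points, terminals) is unchanged. The soma root
    is kept as a single isopotential compartment.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    new_comps: list[Compartment] = []
    # map old id -> new id of the distal-most piece (attachment for children)
    tail: dict[int, int] = {}
    for c in m.compartments:
        if c.parent_id == ROOT_PARENT:
            new_comps.append(replace(c, id=0))
            tail[c.id] = 0
            continue
        parent_new = tail[c.parent_id]
        n_pieces = max(1, math.ceil(c.length / max_len - 1e-12))
        p0 = np.asarray(c.p0, float)
        p1 = np.asarray(c.p1, float)
        prev = parent_new
        for i in range(n_pieces):
            a = p0 + (p1 - p0) * (i / n_pieces)
            bpt = p0 + (p1 - p0) * ((i + 1) / n_pieces)
            cid = len(new_comps)
            new_comps.append(
                Compartment(cid, prev, tuple(a), tuple(bpt), c.diameter,
                            c.kind, c.myelinated)
            )
            prev = cid
        tail[c.id] = prev
    return Morphology(new_comps, m.somatodendritic_axis, m.archetype_label,
                      m.clone_seed)


# ---------------------------------------------------------------------------
# Myelination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MyelinRule:
    """Geometry-based myelination rule (a documented stand-in; the exact rule
    used for the reference reconstructions is not published in a reusable
    form).

    Axonal compartments become internodes when their diameter is at least
    ``diameter_threshold`` and their path distance from the soma exceeds
    ``exclusion_zone``; terminal compartments and branch points stay bare so
    nodes exist at every discontinuity. ``rule="none"`` strips all flags.
    """

    rule: str = "default"
    diameter_threshold: float = 0.5  # μm
    exclusion_zone: float = 50.0  # μm path distance from soma


def apply_myelin(m: Morphology, rule: MyelinRule) -> Morphology:
    """Apply (or strip, for rule "none") myelination flags."""
    if rule.rule == "none":
        comps = [
            replace(c, myelinated=False,
                    kind=SectionKind.AXON if c.kind is SectionKind.MYELIN_INTERNODE
                    else c.kind)
            for c in m.compartments
        ]
        return Morphology(comps, m.somatodendritic_axis, m.archetype_label,
                          m.clone_seed)
    if rule.rule != "default":
        raise ValueError(f"unknown myelination rule {rule.rule!r}")

    # path distance from soma to each compartment's distal end
    dist = np.zeros(m.n)
    for c in m.compartments:
        if c.parent_id == ROOT_PARENT:
            continue
        parent_d = dist[c.parent_id] if c.parent_id != m.root.id else 0.0
        dist[c.id] = parent_d + c.length
    counts = m.children_counts()
    comps = []
    for c in m.compartments:
        axonal = c.kind in (SectionKind.AXON, SectionKind.MYELIN_INTERNODE)
        flag = (
            axonal
            and c.diameter >= rule.diameter_threshold
            and dist[c.id] > rule.exclusion_zone
            and counts[c.id] == 1  # terminals (0) and branch points (>1) stay bare
        )
        kind = c.kind
        if axonal:
            kind = SectionKind.MYELIN_INTERNODE if flag else SectionKind.AXON
        comps.append(replace(c, myelinated=flag, kind=kind))
    return Morphology(comps, m.somatodendritic_axis, m.archetype_label,
                      m.clone_seed)


# ---------------------------------------------------------------------------
# Region index
# ---------------------------------------------------------------------------

REGIONS = ("soma", "axon", "basal_dendrite", "apical_dendrite")

_KIND_TO_REGION = {
    SectionKind.SOMA: "soma",
    SectionKind.AXON: "axon",
    SectionKind.MYELIN_INTERNODE: "axon",  # internodes are axonal
    SectionKind.BASAL_DENDRITE: "basal_dendrite",
    SectionKind.APICAL_DENDRITE: "apical_dendrite",
}


def region_index(m: Morphology) -> dict[str, dict[str, np.ndarray]]:
    """Partition compartment indices by region.

    Returns ``{region: {"all": indices, "terminals": leaf indices}}`` with
    myelin internodes grouped under ``axon``. Regions with no compartments are
    omitted (interneurons have no apical dendrite).
    """
    leaves = set(m.leaves().tolist())
    out: dict[str, dict[str, list[int]]] = {}
    for c in m.compartments:
        region = _KIND_TO_REGION[c.kind]
        d = out.setdefault(region, {"all": [], "terminals": []})
        d["all"].append(c.id)
        if c.id in leaves:
            d["terminals"].append(c.id)
    return {
        r: {k: np.array(v, dtype=int) for k, v in d.items()}
        for r, d in out.items()
    }
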