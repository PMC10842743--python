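"""Placement of neuron morphologies on cortical layer surfaces: synthetic
folded sheets, ray–triangle intersection, pial-violation detection and
binary-search repositioning.

A :class:`CorticalSheet` is a pair of triangulated surfaces (pial and white
matter, mm) with per-vertex correspondence, so any normalized depth d ∈ [0, 1]
defines an intermediate layer surface by linear interpolation. Cells are
placed at triangle centroids of their layer surface with the somatodendritic
axis aligned to the element normal and a random azimuthal rotation; branches
that poke out of the pial surface are detected and repaired by translating the
cell inward along its column, bounded so the soma stays within its layer.

Layer depth conventions (normalized cortical depth, pial = 0, white = 1):
boundaries L1–L2/3 at 0.0993, L2/3–L4 at 0.466, L4–L5 at 0.524, L5–L6 at
0.753; placement depths L1 0.01, L2/3 0.4, L4 0.5, L5 0.75, L6 0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

from .morphology import Compartment, Morphology, ROOT_PARENT

__all__ = [
    "LAYER_BOUNDARIES",
    "PLACEMENT_DEPTHS",
    "LayerSpec",
    "CorticalSheet",
    "Placement",
    "PlacedNeuron",
    "flat_slab",
    "folded_sheet",
    "layer_surface",
    "ray_triangle",
    "detect_violations",
    "reposition",
    "populate",
    "placements_to_csv",
]

MM_PER_UM = 1e-3

# normalized depth of the boundary *below* each layer (its lower edge)
LAYER_BOUNDARIES = {
    "L1": 0.0993,    # L1–L2/3
    "L23": 0.466,    # L2/3–L4
    "L4": 0.524,     # L4–L5
    "L5": 0.753,     # L5–L6
    "L6": 1.0,       # gray–white
}
PLACEMENT_DEPTHS = {"L1": 0.01, "L23": 0.4, "L4": 0.5, "L5": 0.75, "L6": 0.95}


@dataclass(frozen=True)
class LayerSpec:
    """One layer's placement depth and lower boundary (normalized depths)."""

    name: str
    placement_depth: float
    lower_boundary: float

    def __post_init__(self) -> None:
        if not 0.0 < self.placement_depth < 1.0:
            raise ValueError("placement depth must be in (0, 1)")
        if not self.placement_depth <= self.lower_boundary <= 1.0:
            raise ValueError("lower boundary must be at or below the placement depth")

    @classmethod
    def named(cls, name: str) -> "LayerSpec":
        return cls(name, PLACEMENT_DEPTHS[name], LAYER_BOUNDARIES[name])


@dataclass
class CorticalSheet:
    """Pial and white-matter surfaces with shared triangulation (mm)."""

    vertices_pial: np.ndarray
    vertices_white: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices_pial = np.asarray(self.vertices_pial, float)
        self.vertices_white = np.asarray(self.vertices_white, float)
        self.faces = np.asarray(self.faces, int)
        if self.vertices_pial.shape != self.vertices_white.shape:
            raise ValueError("pial and white surfaces need matching vertex counts")

    def pial_mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices_pial, self.faces, process=False)

    def thickness_at(self, element: int) -> float:
        """Local gray-matter thickness (mm) at an element centroid."""
        f = self.faces[element]
        return float(
            np.linalg.norm(
                self.vertices_pial[f].mean(axis=0)
                - self.vertices_white[f].mean(axis=0)
            )
        )

    @classmethod
    def load(cls, pial_path: str | Path, white_path: str | Path) -> "CorticalSheet":
        """Load matching pial/white surfaces from PLY or STL files."""
        pial = trimesh.load_mesh(pial_path, process=False)
        white = trimesh.load_mesh(white_path, process=False)
        if not np.array_equal(pial.faces, white.faces):
            raise ValueError("surfaces must share a triangulation")
        return cls(np.asarray(pial.vertices), np.asarray(white.vertices),
                   np.asarray(pial.faces))

    def save(self, pial_path: str | Path, white_path: str | Path) -> None:
        trimesh.Trimesh(self.vertices_pial, self.faces,
                        process=False).export(pial_path)
        trimesh.Trimesh(self.vertices_white, self.faces,
                        process=False).export(white_path)


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return np.array(faces, int)


def flat_slab(extent: float = 4.0, thickness: float = 2.5,
              n: int = 9) -> CorticalSheet:
    """Flat cortical slab fixture: pial plane at z=0 (outward normal +z),
    white plane at z=−thickness, over [−extent/2, extent/2]² (mm)."""
    xs = np.linspace(-extent / 2, extent / 2, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pial = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    white = pial.copy()
    white[:, 2] -= thickness
    return CorticalSheet(pial, white, _grid_faces(n, n))


def folded_sheet(extent: float = 6.0, thickness: float = 2.0,
                 amplitude: float = 1.0, period: float = 4.0,
                 n: int = 25) -> CorticalSheet:
    """Sinusoidally folded "gyrus" fixture: pial height z = A sin(2πx/P),
    white surface offset inward along the analytic vertex normal."""
    xs = np.linspace(-extent / 2, extent / 2, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    Z = amplitude * np.sin(2 * math.pi * X / period)
    pial = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dzdx = (2 * math.pi * amplitude / period) * np.cos(2 * math.pi * X / period)
    normals = np.column_stack(
        [-dzdx.ravel(), np.zeros(n * n), np.ones(n * n)]
    )
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    white = pial - thickness * normals
    return CorticalSheet(pial, white, _grid_faces(n, n))


def layer_surface(sheet: CorticalSheet, depth: float) -> trimesh.Trimesh:
    """Surface at normalized depth ``depth`` (0 = pial, 1 = white), obtained
    by vertex-wise linear interpolation; triangle topology inherited."""
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must be in [0, 1]")
    verts = (1.0 - depth) * sheet.vertices_pial + depth * sheet.vertices_white
    return trimesh.Trimesh(verts, sheet.faces, process=False)


# ---------------------------------------------------------------------------
# Ray–triangle intersection (Möller–Trumbore)
# ---------------------------------------------------------------------------

def ray_triangle(origin: Sequence[float], direction: Sequence[float],
                 tri: np.ndarray, eps: float = 1e-9
                 ) -> float | None:
    """Möller–Trumbore ray–triangle test.

    Returns the ray parameter t ≥ 0 of the hit (distance when ``direction``
    is unit), or None. Boundary hits (edges, vertices) count as hits within
    ``eps``. Degenerate triangles return None.
    """
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    if np.linalg.norm(d) == 0:
        raise ValueError("ray direction must be non-zero")
    v0, v1, v2 = np.asarray(tri, float)
    e1, e2 = v1 - v0, v2 - v0
    pvec = np.cross(d, e2)
    det = e1 @ pvec
    if abs(det) < eps * max(1.0, float(np.abs(e1).max() * np.abs(e2).max())):
        return None  # parallel or degenerate
    inv = 1.0 / det
    tvec = o - v0
    u = (tvec @ pvec) * inv
    if u < -eps or u > 1.0 + eps:
        return None
    qvec = np.cross(tvec, e1)
    v = (d @ qvec) * inv
    if v < -eps or u + v > 1.0 + eps:
        return None
    t = (e2 @ qvec) * inv
    if t < -eps:
        return None
    return float(max(t, 0.0))


def _ray_mesh_hits(origins: np.ndarray, direction: np.ndarray,
                   vertices: np.ndarray, faces: np.ndarray,
                   eps: float = 1e-9) -> np.ndarray:
    """Vectorized hit count of one ray direction from many origins against a
    triangle soup. Returns (n_origins,) intersection counts."""
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    d = np.asarray(direction, float)
    pvec = np.cross(d, e2)  # (m, 3)
    det = np.einsum("ij,ij->i", e1, pvec)  # (m,)
    ok = np.abs(det) > eps
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    counts = np.zeros(len(origins), dtype=int)
    for i, o in enumerate(origins):
        tvec = o - v0  # (m, 3)
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
        counts[i] = int(hit.sum())
    return counts


# ---------------------------------------------------------------------------
# Placement and violation detection
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    """Where and how one cell sits on its layer surface."""

    element: int
    position: np.ndarray  # soma center, mm (world frame)
    normal: np.ndarray  # unit outward normal = somatodendritic axis
    azimuth: float  # degrees about the normal
    translation_applied: float = 0.0  # mm, inward along the normal
    seed: int = 0
    layer: str = ""
    status: str = "ok"

    def rotation(self) -> np.ndarray:
        """Rotation matrix taking cell-frame vectors to world frame (cell +z
        → element normal, then azimuthal spin about it)."""
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        z = np.array([0.0, 0.0, 1.0])
        c = float(z @ n)
        if c > 1.0 - 1e-12:
            align = np.eye(3)
        elif c < -1.0 + 1e-12:
            align = np.diag([1.0, -1.0, -1.0])
        else:
            axis = np.cross(z, n)
            axis = axis / np.linalg.norm(axis)
            align = _axis_angle(axis, math.acos(c))
        spin = _axis_angle(n, math.radians(self.azimuth))
        return spin @ align


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    a = np.asarray(axis, float)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _closest_on_triangles(points: np.ndarray, vertices: np.ndarray,
                          faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on a triangle soup for each query point (vectorized
    Voronoi-region classification over all point–triangle pairs, after
    Ericson, "Real-Time Collision Detection").

    Returns (closest_points (n,3), face_index (n,)). Brute force over
    point–triangle pairs — fine for the fixture-scale meshes this package
    targets; per-mesh static quantities are cached.
    """
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    ab, ac, bc = b - a, c - a, c - b
    gabab = np.einsum("mk,mk->m", ab, ab)
    gabac = np.einsum("mk,mk->m", ab, ac)
    gacac = np.einsum("mk,mk->m", ac, ac)

    p = points[:, None, :]  # (n, 1, 3)
    ap = p - a  # (n, m, 3)
    d1 = np.einsum("nmk,mk->nm", ap, ab)
    d2 = np.einsum("nmk,mk->nm", ap, ac)
    # remaining products follow from bp = ap − ab, cp = ap − ac
    d3 = d1 - gabab
    d4 = d2 - gabac
    d5 = d1 - gabac
    d6 = d2 - gacac
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    vert_a = (d1 <= 0) & (d2 <= 0)
    vert_b = (d3 >= 0) & (d4 <= d3)
    vert_c = (d6 >= 0) & (d5 <= d6)
    edge_ab = (~vert_a & ~vert_b & (vc <= 0) & (d1 >= 0) & (d3 <= 0))
    edge_ac = (~vert_a & ~vert_c & (vb <= 0) & (d2 >= 0) & (d6 <= 0))
    edge_bc = (~vert_b & ~vert_c & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0))
    q = a + np.clip(v, 0, 1)[..., None] * ab + np.clip(w, 0, 1)[..., None] * ac
    q = np.where(edge_bc[..., None], b + np.clip(w_bc, 0, 1)[..., None] * bc, q)
    q = np.where(edge_ac[..., None], a + np.clip(w_ac, 0, 1)[..., None] * ac, q)
    q = np.where(edge_ab[..., None], a + np.clip(v_ab, 0, 1)[..., None] * ab, q)
    q = np.where(vert_c[..., None], np.broadcast_to(c, q.shape), q)
    q = np.where(vert_b[..., None], np.broadcast_to(b, q.shape), q)
    q = np.where(vert_a[..., None], np.broadcast_to(a, q.shape), q)
    diff = p - q
    d2_all = np.einsum("nmk,nmk->nm", diff, diff)
    best = np.argmin(d2_all, axis=1)
    return q[np.arange(len(points)), best], best


@dataclass
class PlacedNeuron:
    """A morphology (local μm frame) bound to a placement (world mm frame)."""

    morphology: Morphology
    placement: Placement

    def world_midpoints(self) -> np.ndarray:
        """Compartment midpoints in world coordinates (mm). The soma center
        maps onto the placement position."""
        R = self.placement.rotation()
        local = self.morphology.midpoints() - self.morphology.soma_center
        return self.placement.position + (local * MM_PER_UM) @ R.T

    def world_midpoints_um(self) -> np.ndarray:
        return self.world_midpoints() / MM_PER_UM


def detect_violations(neuron: PlacedNeuron, pial: trimesh.Trimesh,
                      eps: float = 1e-9) -> tuple[np.ndarray, str]:
    """Indices of compartments lying outside the pial surface.

    For watertight pial meshes, outside/inside is decided by ray-casting
    parity. Open patches (the synthetic slab and gyrus fixtures) use a
    signed-distance fallback: a compartment is outside when it lies on the
    positive side of the outward normal of its nearest face; the returned
    status reports which test ran.
    """
    pts = neuron.world_midpoints()
    if len(pts) == 0:
        return np.array([], dtype=int), "ok"
    if pial.is_watertight:
        inside = pial.contains(pts)
        return np.nonzero(~inside)[0].astype(int), "ok"
    closest, tri_id = _closest_on_triangles(
        pts, np.asarray(pial.vertices), np.asarray(pial.faces)
    )
    normals = pial.face_normals[tri_id]
    signed = np.einsum("ij,ij->i", pts - closest, normals)
    return np.nonzero(signed > eps)[0].astype(int), "open_surface_fallback"


def _element_centroid(sheet: CorticalSheet, layer: LayerSpec,
                      element: int) -> np.ndarray:
    f = sheet.faces[element]
    d = layer.placement_depth
    verts = (1.0 - d) * sheet.vertices_pial[f] + d * sheet.vertices_white[f]
    return verts.mean(axis=0)


def _place(morph: Morphology, sheet: CorticalSheet, layer: LayerSpec,
           element: int, azimuth: float, translation: float,
           seed: int = 0) -> PlacedNeuron:
    centroid = _element_centroid(sheet, layer, element)
    normal = _element_outward_normal(sheet, element)
    pos = centroid - translation * normal
    placement = Placement(element, pos, normal, azimuth, translation,
                          seed=seed, layer=layer.name)
    return PlacedNeuron(morph, placement)


def _element_outward_normal(sheet: CorticalSheet, element: int) -> np.ndarray:
    """Outward (pial-pointing) normal of an element, from the pial surface
    triangle with orientation fixed by the pial→white direction."""
    f = sheet.faces[element]
    v = sheet.vertices_pial[f]
    n = np.cross(v[1] - v[0], v[2] - v[0])
    n = n / np.linalg.norm(n)
    inward = sheet.vertices_white[f].mean(axis=0) - v.mean(axis=0)
    if n @ inward > 0:  # normal points toward white matter: flip
        n = -n
    return n


def reposition(morph: Morphology, sheet: CorticalSheet, layer: LayerSpec,
               element: int, azimuth: float, seed: int = 0,
               n_azimuth_candidates: int = 36,
               tol_mm: float = 1e-3) -> PlacedNeuron:
    """Find a violation-free placement by binary search over inward
    translation, combined with a seeded set of azimuthal candidates.

    The maximal allowed translation is the distance from the placement depth
    to the layer's lower boundary (scaled by local thickness), so the soma
    never leaves its layer. Among all candidates achieving zero violations,
    the minimal translation wins; ties go to the smallest azimuth change.
    A cell with no admissible configuration gets status ``failed`` at its
    original pose.
    """
    pial = layer_surface(sheet, 0.0)
    thickness = sheet.thickness_at(element)
    max_t = (layer.lower_boundary - layer.placement_depth) * thickness

    rng = np.random.default_rng(seed)
    candidates = [azimuth] + [
        float(a) for a in rng.uniform(0.0, 360.0, n_azimuth_candidates - 1)
    ]

    def n_viol(az: float, t: float) -> int:
        pn = _place(morph, sheet, layer, element, az, t, seed)
        return len(detect_violations(pn, pial)[0])

    best: tuple[float, float, float] | None = None  # (translation, |Δaz|, az)
    for az in candidates:
        daz = min(abs(az - azimuth), 360.0 - abs(az - azimuth))
        if n_viol(az, 0.0) == 0:
            t_min = 0.0
        else:
            # inward translation clears violations monotonically, so a
            # candidate that still violates just below the current best
            # translation cannot improve on it — prune before bisecting
            hi = max_t if best is None else min(max_t, best[0] - tol_mm)
            if hi <= 0 or n_viol(az, hi) > 0:
                continue
            lo = 0.0  # invariant: hi admissible, lo not
            while hi - lo > tol_mm:
                mid = (lo + hi) / 2.0
                if n_viol(az, mid) == 0:
                    hi = mid
                else:
                    lo = mid
            t_min = hi
        key = (t_min, daz, az)
        if best is None or key[:2] < best[:2]:
            best = key
        if t_min == 0.0 and daz == 0.0:
            break  # original pose is fine; nothing can beat it

    if best is None:
        pn = _place(morph, sheet, layer, element, azimuth, 0.0, seed)
        pn.placement.status = "failed"
        return pn
    t_min, _, az = best
    return _place(morph, sheet, layer, element, az, t_min, seed)


def populate(sheet: CorticalSheet, layer: LayerSpec,
             morphologies: Sequence[Morphology], n_elements: int,
             seed: int = 0) -> list[PlacedNeuron]:
    """Place every supplied clone morphology in each of ``n_elements``
    elements of the layer surface, with seeded random azimuths and automatic
    repair of pial violations. Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    n_faces = len(sheet.faces)
    if n_elements > n_faces:
        raise ValueError(f"requested {n_elements} elements but the surface has "
                         f"only {n_faces}")
    elements = rng.choice(n_faces, size=n_elements, replace=False)
    pial = layer_surface(sheet, 0.0)
    placed: list[PlacedNeuron] = []
    for element in elements:
        for morph in morphologies:
            azimuth = float(rng.uniform(0.0, 360.0))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            pn = _place(morph, sheet, layer, int(element), azimuth, 0.0, sub_seed)
            if len(detect_violations(pn, pial)[0]) > 0:
                pn = reposition(morph, sheet, layer, int(element), azimuth,
                                seed=sub_seed)
            placed.append(pn)
    return placed


def placements_to_csv(placed: Sequence[PlacedNeuron], path: str | Path) -> None:
    """Write placements as CSV (element_id, x, y, z, nx, ny, nz, azimuth_deg,
    translation_mm, layer, status)."""
    import pandas as pd

    rows = []
    for pn in placed:
        p = pn.placement
        rows.append(
            dict(element_id=p.element, x=p.position[0], y=p.position[1],
                 z=p.position[2], nx=p.normal[0], ny=p.normal[1],
                 nz=p.normal[2], azimuth_deg=p.azimuth,
                 translation_mm=p.translation_applied, layer=p.layer,
                 status=p.status)
        )
    pd.DataFrame(rows).to_csv(path, index=False)
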