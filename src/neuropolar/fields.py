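"""Extracellular field sources: uniform, analytic point-source, and
mesh-interpolated potentials, with sampling and normal/tangential
decomposition.

Unit conventions (fixed package-wide): morphology coordinates in μm, mesh and
point-source geometry in mm, potentials returned in mV, E-field vectors in
V/m. The μm→mm conversion happens once, at sampling time, inside each source.

The uniform field follows the spherical direction convention of the
polarization–direction maps: polar angle θ from the somatodendritic (+z)
axis, azimuth φ from +x, and extracellular potential

    Ve(x, y, z) = −|E| · (x sinθ cosφ + y sinθ sinφ + z cosθ),

zero at the origin (the soma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FieldDirection",
    "UniformField",
    "PointSourceField",
    "MeshField",
    "FieldSample",
    "FieldDecomposition",
    "uniform_potential",
    "sample",
    "decompose",
    "direction_sector",
    "GRAY_MATTER_CONDUCTIVITY",
]

# Isotropic gray-matter conductivity (S/m) used as the default homogeneous
# medium for analytic point sources.
GRAY_MATTER_CONDUCTIVITY = 0.275

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class FieldDirection:
    """Uniform-field direction: polar angle θ ∈ [0, 180]°, azimuth φ ∈ [0, 360)°.

    At the poles (θ = 0 or 180) the azimuth is degenerate and canonicalized
    to φ = 0.
    """

    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError(f"theta must be in [0, 180], got {self.theta}")
        phi = self.phi % 360.0
        if self.theta in (0.0, 180.0):
            phi = 0.0
        object.__setattr__(self, "phi", phi)

    @property
    def unit_vector(self) -> np.ndarray:
        t, p = math.radians(self.theta), math.radians(self.phi)
        return np.array(
            [math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)]
        )

    @staticmethod
    def from_vector(v: np.ndarray) -> "FieldDirection":
        v = np.asarray(v, float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero vector has no direction")
        v = v / n
        theta = math.degrees(math.acos(np.clip(v[2], -1.0, 1.0)))
        phi = math.degrees(math.atan2(v[1], v[0])) % 360.0
        return FieldDirection(theta, phi)

    def antipode(self) -> "FieldDirection":
        return FieldDirection(180.0 - self.theta, (self.phi + 180.0) % 360.0)


@dataclass(frozen=True)
class UniformField:
    """Spatially uniform E-field of given magnitude (V/m) and direction.

    The potential is zero at ``origin`` (μm; by convention the soma center).
    """

    magnitude: float
    direction: FieldDirection
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")


@dataclass(frozen=True)
class PointSourceField:
    """Monopolar current sources in an infinite homogeneous medium.

    ``sources`` is a list of (position_mm, current_mA); potentials superpose:
    V = I / (4πσr) per source. An analytic stand-in for a spatially
    non-uniform stimulation field with a controllable gradient scale.
    """

    sources: tuple[tuple[tuple[float, float, float], float], ...]
    medium_conductivity: float = GRAY_MATTER_CONDUCTIVITY

    def __post_init__(self) -> None:
        if self.medium_conductivity <= 0:
            raise ValueError("conductivity must be positive")
        object.__setattr__(
            self,
            "sources",
            tuple((tuple(map(float, p)), float(i)) for p, i in self.sources),
        )


class MeshField:
    """Per-node electric potentials on a tetrahedral or triangular mesh.

    Nodes in mm, potentials in V (as exported by FEM solvers). Interpolation
    within an element uses its first-order (linear) basis, so the E-field is
    constant per element: E = −∇V of the linear interpolant.
    """

    def __init__(self, nodes: np.ndarray, elements: np.ndarray,
                 node_potentials: np.ndarray):
        self.nodes = np.asarray(nodes, float)
        self.elements = np.asarray(elements, int)
        self.node_potentials = np.asarray(node_potentials, float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] not in (3, 4):
            raise ValueError("elements must be (m, 3) triangles or (m, 4) tetrahedra")
        if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
            raise ValueError("element references an invalid node")
        if len(self.node_potentials) != len(self.nodes):
            raise ValueError("one potential per node required")

    @property
    def is_tetrahedral(self) -> bool:
        return self.elements.shape[1] == 4

    @classmethod
    def from_csv(cls, node_path: str | Path, element_path: str | Path) -> "MeshField":
        """Load from a node table CSV (id,x,y,z,potential) and an element
        table CSV (id,n0,n1,n2[,n3]); node ids must be 0-based and dense."""
        import pandas as pd

        nodes = pd.read_csv(node_path)
        elems = pd.read_csv(element_path)
        nodes = nodes.sort_values(nodes.columns[0])
        return cls(
            nodes[["x", "y", "z"]].to_numpy(),
            elems.iloc[:, 1:].to_numpy(int),
            nodes["potential"].to_numpy(),
        )

    def to_csv(self, node_path: str | Path, element_path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "id": np.arange(len(self.nodes)),
                "x": self.nodes[:, 0],
                "y": self.nodes[:, 1],
                "z": self.nodes[:, 2],
                "potential": self.node_potentials,
            }
        ).to_csv(node_path, index=False)
        cols = ["n0", "n1", "n2"] + (["n3"] if self.is_tetrahedral else [])
        df = pd.DataFrame(self.elements, columns=cols)
        df.insert(0, "id", np.arange(len(self.elements)))
        df.to_csv(element_path, index=False)


FieldSource = UniformField | PointSourceField | MeshField


@dataclass(frozen=True)
class FieldSample:
    """Potential (mV) and E-field vector (V/m) at one query point."""

    potential: float
    E: np.ndarray
    in_domain: bool = True

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.E))


@dataclass(frozen=True)
class FieldDecomposition:
    """E-field split into normal (inward-positive) and tangential parts, V/m."""

    E_n: float
    E_t: float
    magnitude: float


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def uniform_potential(f: UniformField, p: Sequence[float]) -> float:
    """Extracellular potential (mV) of a uniform field at point ``p`` (μm).

    ``p`` is in the cell-centered frame (origin at the soma, z along the
    somatodendritic axis). Exactly linear in |E|.
    """
    rel = np.asarray(p, float) - np.asarray(f.origin, float)
    # V/m × μm = 1e-6 V = 1e-3 mV
    return float(-f.magnitude * rel @ f.direction.unit_vector * 1e-3)


def _sample_uniform(f: UniformField, pts: np.ndarray) -> list[FieldSample]:
    rel = pts - np.asarray(f.origin, float)
    ve = -f.magnitude * (rel @ f.direction.unit_vector) * 1e-3
    E = f.magnitude * f.direction.unit_vector
    return [FieldSample(float(v), E.copy()) for v in ve]


def _sample_point_source(f: PointSourceField, pts_um: np.ndarray) -> list[FieldSample]:
    pts = pts_um / UM_PER_MM  # μm → mm boundary
    sigma = f.medium_conductivity
    ve = np.zeros(len(pts))
    E = np.zeros((len(pts), 3))
    for pos, current in f.sources:
        d = pts - np.asarray(pos)  # mm
        r_mm = np.linalg.norm(d, axis=1)
        if np.any(r_mm == 0):
            raise ValueError("sample point coincides with a current source")
        r_m = r_mm * 1e-3
        # I in mA → A: 1e-3; V = I/(4πσr)
        ve += (current * 1e-3) / (4.0 * math.pi * sigma * r_m)
        # E = I/(4πσr²) r̂, V/m
        E += ((current * 1e-3) / (4.0 * math.pi * sigma * r_m**2))[:, None] \
            * (d / r_mm[:, None])
    return [FieldSample(float(v * 1e3), e) for v, e in zip(ve, E)]  # V → mV


class _MeshLocator:
    """Brute-force point location with per-element linear-basis gradients."""

    def __init__(self, mesh: MeshField, tol: float = 1e-9):
        self.mesh = mesh
        self.tol = tol
        self._grads = None  # lazily computed per-element ∇V (V/mm)

    def gradients(self) -> np.ndarray:
        if self._grads is None:
            m = self.mesh
            grads = np.zeros((len(m.elements), 3))
            for i, el in enumerate(m.elements):
                grads[i] = _element_gradient(m.nodes[el], m.node_potentials[el])
            self._grads = grads
        return self._grads


def _element_gradient(verts: np.ndarray, pots: np.ndarray) -> np.ndarray:
    """Gradient (V/mm) of the linear interpolant on one element."""
    if len(verts) == 4:
        A = verts[1:] - verts[0]
        b = pots[1:] - pots[0]
        return np.linalg.solve(A, b)
    # triangle: in-plane gradient (zero out-of-plane component)
    e1, e2 = verts[1] - verts[0], verts[2] - verts[0]
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("degenerate element")
    A = np.vstack([e1, e2, n / nn])
    b = np.array([pots[1] - pots[0], pots[2] - pots[0], 0.0])
    return np.linalg.solve(A, b)


def _tet_barycentric(verts: np.ndarray, p: np.ndarray) -> np.ndarray:
    T = (verts[1:] - verts[0]).T
    lam = np.linalg.solve(T, p - verts[0])
    return np.concatenate([[1.0 - lam.sum()], lam])


def _tri_barycentric(verts: np.ndarray, p: np.ndarray, tol: float
                     ) -> np.ndarray | None:
    e1, e2 = verts[1] - verts[0], verts[2] - verts[0]
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n)
    if nn == 0:
        return None
    d = p - verts[0]
    if abs(d @ (n / nn)) > max(tol, 1e-6 * max(np.linalg.norm(e1),
                                               np.linalg.norm(e2))):
        return None  # off the surface
    A = np.array([[e1 @ e1, e1 @ e2], [e1 @ e2, e2 @ e2]])
    b = np.array([d @ e1, d @ e2])
    uv = np.linalg.solve(A, b)
    return np.concatenate([[1.0 - uv.sum()], uv])


def _sample_mesh(mesh: MeshField, pts_um: np.ndarray,
                 tol: float = 1e-9) -> list[FieldSample]:
    pts = pts_um / UM_PER_MM  # μm → mm boundary
    loc = _MeshLocator(mesh, tol)
    grads = loc.gradients()
    out: list[FieldSample] = []
    for p in pts:
        found = None
        for i, el in enumerate(mesh.elements):
            verts = mesh.nodes[el]
            if mesh.is_tetrahedral:
                lam = _tet_barycentric(verts, p)
            else:
                lam = _tri_barycentric(verts, p, tol)
                if lam is None:
                    continue
            if np.all(lam >= -tol - 1e-9):
                found = i
                break
        if found is None:
            out.append(FieldSample(math.nan, np.full(3, math.nan), in_domain=False))
            continue
        el = mesh.elements[found]
        verts = mesh.nodes[el]
        if mesh.is_tetrahedral:
            lam = _tet_barycentric(verts, p)
        else:
            lam = _tri_barycentric(verts, p, tol)
        v = float(lam @ mesh.node_potentials[el])  # V
        E = -grads[found] * 1e3  # V/mm → V/m, constant per element
        out.append(FieldSample(v * 1e3, E))  # V → mV
    return out


def sample(source: FieldSource, points: np.ndarray) -> list[FieldSample]:
    """Potential (mV) and E-vector (V/m) of ``source`` at ``points`` (μm).

    Mesh samples outside every element are flagged ``in_domain=False`` rather
    than extrapolated; the caller decides whether to skip or fail.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if isinstance(source, UniformField):
        return _sample_uniform(source, pts)
    if isinstance(source, PointSourceField):
        return _sample_point_source(source, pts)
    if isinstance(source, MeshField):
        return _sample_mesh(source, pts)
    raise TypeError(f"unknown field source type {type(source).__name__}")


# ---------------------------------------------------------------------------
# Decomposition and sectors
# ---------------------------------------------------------------------------

def decompose(E: Sequence[float], outward_normal: Sequence[float]
              ) -> FieldDecomposition:
    """Split ``E`` into inward-positive normal and tangential components.

    ``E_n = −E·n̂`` (positive when the field points into the cortex) and
    ``E_t = |E − (E·n̂)n̂|``; E_n² + E_t² = |E|².
    """
    E = np.asarray(E, float)
    n = np.asarray(outward_normal, float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("outward normal must be non-zero")
    n = n / nn
    en_signed = float(E @ n)
    et = float(np.linalg.norm(E - en_signed * n))
    return FieldDecomposition(E_n=-en_signed, E_t=et,
                              magnitude=float(np.linalg.norm(E)))


def direction_sector(d: FieldDirection) -> str:
    """Classify a direction as downward / upward / transverse.

    Downward (field into the cortex): 120° < θ ≤ 180°; upward (out of the
    cortex): 0° ≤ θ ≤ 60°; transverse: 60° < θ ≤ 120°.
    """
    if d.theta <= 60.0:
        return "upward"
    if d.theta <= 120.0:
        return "transverse"
    return "downward"
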