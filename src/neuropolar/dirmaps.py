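"""Polarization–direction maps over the spherical uniform-field direction
grid: construction, interpolation, Mollweide projection and serialization.

A direction map stores, for one subcellular region, the signed peak
polarization per unit field (mV per V/m) produced by a 1 V/m uniform E-field
at each direction of a regular (θ, φ) grid. The default 15° grid has
2 + 11·24 = 266 unique directions (poles sampled once). Maps are the lookup
table of the quasi-uniform estimator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .cable import CableParameters, CableSystem, peak_polarization
from .fields import FieldDirection, UniformField, uniform_potential
from .morphology import Morphology, region_index

__all__ = [
    "DirectionGrid",
    "DirectionMap",
    "build_grid",
    "build_map",
    "build_maps",
    "interpolate",
    "mollweide",
    "mollweide_inverse",
    "export_map",
    "import_map",
    "render_map_png",
]


@dataclass(frozen=True)
class DirectionGrid:
    """Regular spherical grid of uniform-field directions.

    θ-major ordering: the north pole (θ=0) first, then rows θ = s, 2s, …,
    180−s each sweeping φ = 0, s, …, 360−s, then the south pole (θ=180).
    """

    step: float
    directions: tuple[FieldDirection, ...]

    @property
    def n(self) -> int:
        return len(self.directions)

    @property
    def theta_rows(self) -> np.ndarray:
        return np.arange(0.0, 180.0 + self.step / 2, self.step)

    @property
    def phi_cols(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.step)


def build_grid(step: float = 15.0) -> DirectionGrid:
    """Build the direction grid for angular step ``step`` (degrees).

    ``step`` must divide both 180 and 360; the grid then has
    2 + (180/step − 1)·(360/step) unique directions (15° → 266).
    """
    if step <= 0 or (180.0 / step) % 1 or (360.0 / step) % 1:
        raise ValueError(f"step must divide 180 and 360, got {step}")
    dirs: list[FieldDirection] = [FieldDirection(0.0, 0.0)]
    for theta in np.arange(step, 180.0, step):
        for phi in np.arange(0.0, 360.0, step):
            dirs.append(FieldDirection(float(theta), float(phi)))
    dirs.append(FieldDirection(180.0, 0.0))
    return DirectionGrid(step=float(step), directions=tuple(dirs))


@dataclass
class DirectionMap:
    """Signed peak polarization per unit field over a direction grid.

    ``values[i]`` (mV per V/m) corresponds to ``grid.directions[i]``. Built at
    1 V/m so values are per-unit-field; passive maps are antipodally
    antisymmetric: value(θ, φ) = −value(180−θ, φ+180°).
    """

    grid: DirectionGrid
    region: str
    values: np.ndarray
    archetype_label: str = ""
    clone_seed: int = 0
    myelination: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.grid.n,):
            raise ValueError("one value per grid direction required")
        self._interp = None

    def lattice(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Rectangular (θ, φ) lattice with pole rows replicated across φ and
        the φ=360 column duplicating φ=0 for periodic wrap."""
        g = self.grid
        thetas = g.theta_rows
        phis = np.append(g.phi_cols, 360.0)
        n_phi = len(g.phi_cols)
        Z = np.empty((len(thetas), len(phis)))
        Z[0, :] = self.values[0]
        Z[-1, :] = self.values[-1]
        inner = self.values[1:-1].reshape(len(thetas) - 2, n_phi)
        Z[1:-1, :n_phi] = inner
        Z[1:-1, -1] = inner[:, 0]
        return thetas, phis, Z

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            thetas, phis, Z = self.lattice()
            self._interp = RegularGridInterpolator(
                (thetas, phis), Z, method="linear", bounds_error=True
            )
        return self._interp


def build_maps(m: Morphology, params: CableParameters,
               grid: DirectionGrid | None = None,
               magnitude: float = 1.0) -> dict[str, DirectionMap]:
    """Direction maps for every region of ``m`` in one batched solve.

    The cable system is factorized once and all grid directions are solved as
    a single multi-column right-hand side, so cost is one sparse LU plus
    ``grid.n`` triangular solves.
    """
    if grid is None:
        grid = build_grid()
    sysm = CableSystem(m, params)
    origin = m.soma_center
    pts = m.midpoints() - origin  # cell frame, origin at soma
    U = np.stack([d.unit_vector for d in grid.directions], axis=1)  # (3, k)
    ve = -magnitude * (pts @ U) * 1e-3  # mV, (n, k)
    dvm = sysm.solve(ve)  # (n, k)
    regions = region_index(m)
    myel = "myelinated" if any(c.myelinated for c in m.compartments) else "unmyelinated"
    maps: dict[str, DirectionMap] = {}
    for region, d in regions.items():
        idx = d["all"]
        sub = dvm[idx, :]
        k = np.argmax(np.abs(sub), axis=0)
        vals = sub[k, np.arange(sub.shape[1])] / magnitude
        maps[region] = DirectionMap(
            grid, region, vals, m.archetype_label, m.clone_seed, myel
        )
    return maps


def build_map(m: Morphology, params: CableParameters,
              grid: DirectionGrid | None = None,
              region: str = "soma") -> DirectionMap:
    """Direction map of the signed regional peak for one region."""
    maps = build_maps(m, params, grid)
    if region not in maps:
        raise KeyError(f"morphology has no {region!r} compartments")
    return maps[region]


def interpolate(dmap: DirectionMap, d: FieldDirection) -> float:
    """Bilinear interpolation of the map at direction ``d`` (mV per V/m).

    Periodic in φ, pole rows constant; exact at grid nodes.
    """
    return float(dmap._interpolator()([[d.theta, d.phi % 360.0]])[0])


# ---------------------------------------------------------------------------
# Mollweide projection
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)


def _mollweide_alpha(lat_rad: float, tol: float = 1e-14, max_iter: int = 200
                     ) -> float:
    """Solve 2α + sin 2α = π sin(lat) for α ∈ [−π/2, π/2].

    Bracketed Newton with bisection fallback: f is monotone increasing but its
    derivative vanishes at the poles, where a plain Newton step started from
    α = lat diverges; the bracket keeps every iterate admissible.
    """
    if abs(abs(lat_rad) - math.pi / 2) < 1e-12:
        return math.copysign(math.pi / 2, lat_rad)
    target = math.pi * math.sin(lat_rad)

    def f(a: float) -> float:
        return 2 * a + math.sin(2 * a) - target

    lo, hi = -math.pi / 2, math.pi / 2
    alpha = lat_rad
    for _ in range(max_iter):
        fa = f(alpha)
        if fa > 0:
            hi = alpha
        else:
            lo = alpha
        fp = 2 + 2 * math.cos(2 * alpha)
        if fp > 1e-15:
            nxt = alpha - fa / fp
            if not lo < nxt < hi:
                nxt = 0.5 * (lo + hi)
        else:
            nxt = 0.5 * (lo + hi)
        if abs(nxt - alpha) < tol:
            return nxt
        alpha = nxt
    return alpha


def mollweide(d: FieldDirection) -> tuple[float, float]:
    """Project a direction to Mollweide plane coordinates.

    Latitude = 90° − θ (so the somatodendritic +z axis maps to the top edge),
    longitude = φ wrapped to (−180°, 180°]. Returns (x, y) with
    x ∈ [−2√2, 2√2], y ∈ [−√2, √2].
    """
    lat = math.radians(90.0 - d.theta)
    lon_deg = d.phi % 360.0
    if lon_deg > 180.0:
        lon_deg -= 360.0
    lon = math.radians(lon_deg)
    alpha = _mollweide_alpha(lat)
    x = (2.0 * _SQRT2 / math.pi) * lon * math.cos(alpha)
    y = _SQRT2 * math.sin(alpha)
    return x, y


def mollweide_inverse(x: float, y: float) -> FieldDirection:
    """Inverse Mollweide projection back to a :class:`FieldDirection`."""
    s = y / _SQRT2
    if abs(s) > 1.0 + 1e-12:
        raise ValueError("point outside the projection ellipse")
    alpha = math.asin(max(-1.0, min(1.0, s)))
    lat = math.asin(
        max(-1.0, min(1.0, (2 * alpha + math.sin(2 * alpha)) / math.pi))
    )
    ca = math.cos(alpha)
    if ca < 1e-12:  # pole: longitude degenerate
        lon = 0.0
    else:
        lon = math.pi * x / (2.0 * _SQRT2 * ca)
    theta = 90.0 - math.degrees(lat)
    phi = math.degrees(lon) % 360.0
    return FieldDirection(min(180.0, max(0.0, theta)), phi)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def export_map(dmap: DirectionMap, path: str | Path) -> None:
    """Write a map as CSV (theta_deg, phi_deg, value_mV_per_Vm) plus a JSON
    metadata sidecar at ``<path>.json``. Lossless round trip via
    :func:`import_map`."""
    if dmap.values.size == 0:
        raise ValueError("cannot export an empty map")
    path = Path(path)
    lines = ["theta_deg,phi_deg,value_mV_per_Vm"]
    for d, v in zip(dmap.grid.directions, dmap.values):
        lines.append(f"{d.theta:.10g},{d.phi:.10g},{v:.17g}")
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "region": dmap.region,
        "step": dmap.grid.step,
        "archetype_label": dmap.archetype_label,
        "clone_seed": dmap.clone_seed,
        "myelination": dmap.myelination,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def import_map(path: str | Path) -> DirectionMap:
    """Read a map written by :func:`export_map`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split(",") != ["theta_deg", "phi_deg",
                                            "value_mV_per_Vm"]:
        raise ValueError(f"{path}: not a direction-map CSV")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        t, p, v = line.split(",")
        rows.append((float(t), float(p), float(v)))
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    step = float(meta.get("step", 0.0))
    if not step:
        thetas = sorted({r[0] for r in rows if 0.0 < r[0] < 180.0})
        step = thetas[0] if thetas else 180.0
    grid = build_grid(step)
    if len(rows) != grid.n:
        raise ValueError(f"{path}: expected {grid.n} rows for step {step}, "
                         f"got {len(rows)}")
    for (t, p, _), d in zip(rows, grid.directions):
        if abs(t - d.theta) > 1e-9 or abs(p - d.phi) > 1e-9:
            raise ValueError(f"{path}: direction ordering does not match the "
                             "canonical θ-major grid")
    return DirectionMap(
        grid,
        meta.get("region", "unknown"),
        np.array([r[2] for r in rows]),
        meta.get("archetype_label", ""),
        int(meta.get("clone_seed", 0)),
        meta.get("myelination", ""),
    )


def render_map_png(dmap: DirectionMap, path: str | Path, dpi: int = 100) -> None:
    """Diagnostic PNG of a map in the Mollweide projection (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = np.array([mollweide(d) for d in dmap.grid.directions])
    fig, ax = plt.subplots(figsize=(8, 4))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=dmap.values, cmap="RdBu_r", s=40)
    fig.colorbar(sc, ax=ax, label="polarization (mV per V/m)")
    ax.set_title(f"{dmap.archetype_label} {dmap.region} ({dmap.myelination})")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
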