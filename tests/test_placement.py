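"""Layer surfaces, ray–triangle intersection, pial-violation detection and
binary-search repositioning."""

import numpy as np
import pytest

import neuropolar as npl
from neuropolar.morphology import Compartment, Morphology, SectionKind, ROOT_PARENT
from neuropolar.placement import (
    LayerSpec,
    PlacedNeuron,
    Placement,
    _place,
    detect_violations,
    layer_surface,
    ray_triangle,
    reposition,
)


class TestLayerSpec:
    def test_named_layers_consistent(self):
        for name in npl.PLACEMENT_DEPTHS:
            spec = LayerSpec.named(name)
            assert 0 < spec.placement_depth < 1
            assert spec.placement_depth <= spec.lower_boundary <= 1.0

    def test_boundaries_strictly_increasing(self):
        vals = [npl.LAYER_BOUNDARIES[k] for k in ("L1", "L23", "L4", "L5", "L6")]
        assert vals == sorted(vals)
        assert vals[0] == pytest.approx(0.0993)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            LayerSpec("bad", 0.9, 0.5)


class TestLayerSurface:
    def test_depth_zero_is_pial(self, flat_sheet):
        surf = layer_surface(flat_sheet, 0.0)
        assert np.allclose(surf.vertices, flat_sheet.vertices_pial)

    def test_depth_one_is_white(self, flat_sheet):
        surf = layer_surface(flat_sheet, 1.0)
        assert np.allclose(surf.vertices, flat_sheet.vertices_white)

    def test_midway_vertices_are_midpoints(self, gyrus_sheet):
        surf = layer_surface(gyrus_sheet, 0.5)
        assert np.allclose(
            surf.vertices,
            (gyrus_sheet.vertices_pial + gyrus_sheet.vertices_white) / 2,
        )
        assert np.array_equal(surf.faces, gyrus_sheet.faces)


TRI = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


class TestRayTriangle:
    def test_axis_aligned_hit(self):
        t = ray_triangle((0.2, 0.2, 1.0), (0.0, 0.0, -1.0), TRI)
        assert t == pytest.approx(1.0)

    def test_reversed_ray_misses(self):
        assert ray_triangle((0.2, 0.2, 1.0), (0.0, 0.0, 1.0), TRI) is None

    def test_boundary_hit_counts(self):
        assert ray_triangle((0.0, 0.0, 1.0), (0.0, 0.0, -1.0), TRI) is not None

    def test_degenerate_triangle_returns_none(self):
        degen = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        assert ray_triangle((0.5, 0.5, 1.0), (0.0, 0.0, -1.0), degen) is None

    def test_agreement_with_brute_force_oracle(self):
        """Möller–Trumbore agrees with a plane-intersection + barycentric
        point-in-triangle oracle on random instances (half aimed at the
        triangle plane so hits and misses are both well exercised)."""
        rng = np.random.default_rng(42)
        n_hits = n_misses = 0
        for k in range(10_000):
            tri = rng.uniform(-1, 1, (3, 3))
            o = rng.uniform(-2, 2, 3)
            if k % 2 == 0:
                # aim at a random point in the triangle plane (u,v can leave
                # the triangle, giving near-miss coverage too)
                u, v = rng.uniform(-0.3, 1.3, 2)
                target = tri[0] + u * (tri[1] - tri[0]) + v * (tri[2] - tri[0])
                d = target - o
            else:
                d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            got = ray_triangle(o, d, tri)
            expected = _brute_force_ray_tri(o, d, tri)
            if expected is None:
                assert got is None or _near_boundary(o, d, tri, got)
                n_misses += 1
            else:
                t, boundary = expected
                if boundary:
                    continue  # boundary hits are epsilon-dependent either way
                assert got is not None
                assert got == pytest.approx(t, abs=1e-6)
                n_hits += 1
        assert n_hits > 1000 and n_misses > 1000


def _plane_barycentric(p, tri):
    """Least-squares (u, v) of p in the triangle's edge basis, closed form."""
    e1, e2 = tri[1] - tri[0], tri[2] - tri[0]
    d = p - tri[0]
    g11, g12, g22 = e1 @ e1, e1 @ e2, e2 @ e2
    det = g11 * g22 - g12 * g12
    if abs(det) < 1e-15:
        return None
    u = (g22 * (d @ e1) - g12 * (d @ e2)) / det
    v = (g11 * (d @ e2) - g12 * (d @ e1)) / det
    return u, v


def _brute_force_ray_tri(o, d, tri):
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    denom = n @ d
    if abs(denom) < 1e-12:
        return None
    t = n @ (tri[0] - o) / denom
    if t < 0:
        return None
    uv = _plane_barycentric(o + t * d, tri)
    if uv is None:
        return None
    u, v = uv
    margin = 1e-7
    if u < -margin or v < -margin or u + v > 1 + margin:
        return None
    boundary = u < margin or v < margin or u + v > 1 - margin
    return t, boundary


def _near_boundary(o, d, tri, t):
    uv = _plane_barycentric(o + t * d, tri)
    if uv is None:
        return True
    u, v = uv
    m = 1e-6
    return u < m or v < m or u + v > 1 - m


def _vertical_cable(length_um: float) -> Morphology:
    """Soma at origin with a straight apical cable of ``length_um`` along +z."""
    comps = [
        Compartment(0, ROOT_PARENT, (0, 0, -5.0), (0, 0, 5.0), 10.0,
                    SectionKind.SOMA)
    ]
    n = max(2, int(length_um / 50))
    z = 0.0
    parent = 0
    for _ in range(n):
        comps.append(
            Compartment(len(comps), parent, (0, 0, z), (0, 0, z + length_um / n),
                        2.0, SectionKind.APICAL_DENDRITE)
        )
        parent = len(comps) - 1
        z += length_um / n
    return Morphology(comps)


class TestDetectViolations:
    def test_fully_inside_is_clean(self, flat_sheet):
        m = _vertical_cable(500.0)
        layer = LayerSpec("test", 0.4, 0.9)
        pn = _place(m, flat_sheet, layer, element=60, azimuth=0.0, translation=0.0)
        offenders, status = detect_violations(pn, layer_surface(flat_sheet, 0.0))
        assert len(offenders) == 0

    def test_protruding_compartments_flagged_match_signed_distance(self, flat_sheet):
        """A cable poking through the flat pial plane: exactly the compartments
        with world z > 0 are flagged."""
        m = _vertical_cable(2000.0)
        layer = LayerSpec("test", 0.4, 0.9)  # soma 1.0 mm deep (thickness 2.5)
        pn = _place(m, flat_sheet, layer, element=60, azimuth=0.0, translation=0.0)
        offenders, status = detect_violations(pn, layer_surface(flat_sheet, 0.0))
        world_z = pn.world_midpoints()[:, 2]
        assert status == "open_surface_fallback"
        assert set(offenders.tolist()) == set(np.nonzero(world_z > 1e-9)[0].tolist())
        assert len(offenders) > 0


class TestReposition:
    def test_no_violation_keeps_pose(self, flat_sheet):
        m = _vertical_cable(400.0)
        layer = LayerSpec("test", 0.4, 0.9)
        pn = reposition(m, flat_sheet, layer, element=60, azimuth=33.0, seed=5)
        assert pn.placement.translation_applied == 0.0
        assert pn.placement.azimuth == 33.0
        assert pn.placement.status == "ok"

    def test_flat_plane_recovers_analytic_translation(self, flat_sheet):
        """Cable of length 2d with its tip protruding depth d above the flat
        pial plane needs an inward translation of exactly d (±1 μm)."""
        d_mm = 0.3
        m = _vertical_cable(2 * d_mm * 1000.0)
        # soma placed d below the pial plane: tip at +d, protrusion depth d
        layer = LayerSpec("test", d_mm / 2.5, 0.9)  # thickness 2.5 mm
        pn = reposition(m, flat_sheet, layer, element=60, azimuth=0.0, seed=1)
        assert pn.placement.status == "ok"
        # tip midpoint sits half a compartment below the tip; account for it
        half_seg = m.compartments[-1].length / 2 * 1e-3
        assert pn.placement.translation_applied == pytest.approx(
            d_mm - half_seg, abs=2e-3
        )

    def test_translation_bounded_by_layer(self, gyrus_sheet):
        m = _vertical_cable(1500.0)
        layer = LayerSpec("L23", 0.4, 0.466)
        for element in (10, 100, 250):
            pn = reposition(m, gyrus_sheet, layer, element=element, azimuth=0.0,
                            seed=2)
            max_t = (layer.lower_boundary - layer.placement_depth) * \
                gyrus_sheet.thickness_at(element)
            assert pn.placement.translation_applied <= max_t + 1e-9

    def test_unplaceable_cell_reports_failure(self, flat_sheet):
        m = _vertical_cable(4000.0)  # far longer than any allowed translation
        layer = LayerSpec("test", 0.1, 0.12)
        pn = reposition(m, flat_sheet, layer, element=60, azimuth=0.0, seed=3)
        assert pn.placement.status == "failed"


class TestPopulate:
    def test_deterministic_given_seed(self, gyrus_sheet):
        m = npl.discretize(
            npl.generate_archetype(npl.archetype_spec("L1_NGC", seed=0)), 40.0
        )
        layer = LayerSpec.named("L1")
        a = npl.populate(gyrus_sheet, layer, [m], n_elements=6, seed=9)
        b = npl.populate(gyrus_sheet, layer, [m], n_elements=6, seed=9)
        for pa, pb in zip(a, b):
            assert pa.placement.element == pb.placement.element
            assert pa.placement.azimuth == pb.placement.azimuth
            assert np.allclose(pa.placement.position, pb.placement.position)

    def test_clone_count_per_element(self, flat_sheet):
        clones = [
            npl.discretize(
                npl.generate_archetype(npl.archetype_spec("L4_LBC", seed=s)), 40.0
            )
            for s in range(5)
        ]
        placed = npl.populate(flat_sheet, LayerSpec.named("L4"), clones,
                              n_elements=2, seed=1)
        assert len(placed) == 10
        per_element = {}
        for pn in placed:
            per_element.setdefault(pn.placement.element, 0)
            per_element[pn.placement.element] += 1
        assert all(v == 5 for v in per_element.values())

    def test_no_pial_violations_after_populate(self, gyrus_sheet):
        m = npl.discretize(
            npl.generate_archetype(npl.archetype_spec("L1_NGC", seed=2)), 40.0
        )
        layer = LayerSpec.named("L1")
        placed = npl.populate(gyrus_sheet, layer, [m], n_elements=8, seed=4)
        pial = layer_surface(gyrus_sheet, 0.0)
        for pn in placed:
            if pn.placement.status == "failed":
                continue
            offenders, _ = detect_violations(pn, pial)
            assert len(offenders) == 0
        assert sum(pn.placement.status == "ok" for pn in placed) >= 6


def test_placement_rotation_is_orthonormal(gyrus_sheet):
    from neuropolar.placement import _element_outward_normal

    for element in (3, 77, 140):
        n = _element_outward_normal(gyrus_sheet, element)
        p = Placement(element, np.zeros(3), n, azimuth=123.0)
        R = p.rotation()
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.allclose(R @ np.array([0, 0, 1.0]), n, atol=1e-12)
        assert n[2] > 0  # outward normals point away from white matter
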