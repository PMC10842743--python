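"""Shared fixtures: analytic cable morphologies, archetypes, synthetic sheets."""

from __future__ import annotations

import numpy as np
import pytest

import neuropolar as npl
from neuropolar.morphology import Compartment, Morphology, SectionKind, ROOT_PARENT


def straight_cable(length_um: float = 1000.0, dx_um: float = 20.0,
                   diameter_um: float = 2.0, axis=(0.0, 0.0, 1.0),
                   kind: SectionKind = SectionKind.AXON) -> Morphology:
    """Symmetric straight cable centered on a small soma at the origin,
    extending ±length/2 along ``axis``. Compartment length dx_um."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    half_soma = 5.0
    comps = [
        Compartment(0, ROOT_PARENT, tuple(-half_soma * axis),
                    tuple(half_soma * axis), diameter_um, SectionKind.SOMA)
    ]
    n_side = int(round(length_um / 2 / dx_um))
    for sign in (+1.0, -1.0):
        parent = 0
        pos = np.zeros(3)
        for _ in range(n_side):
            nxt = pos + sign * dx_um * axis
            comps.append(
                Compartment(len(comps), parent, tuple(pos), tuple(nxt),
                            diameter_um, kind)
            )
            parent = len(comps) - 1
            pos = nxt
    return Morphology(comps)


def params_with_lambda(lambda_mm: float = 0.5, diameter_um: float = 2.0,
                       ra: float = 100.0) -> npl.CableParameters:
    """Cable parameters tuned so the space constant is ``lambda_mm``."""
    lam_cm = lambda_mm / 10.0
    rm = lam_cm**2 * 4.0 * ra / (diameter_um * 1e-4)
    return npl.CableParameters(axial_resistivity=ra, membrane_resistance=rm)


@pytest.fixture(scope="session")
def cable_1mm():
    return straight_cable(1000.0, 20.0)


@pytest.fixture(scope="session")
def lam05_params():
    return params_with_lambda(0.5)


@pytest.fixture(scope="session")
def l5_morph():
    """Discretized myelinated L5 pyramidal archetype, clone seed 1."""
    return npl.discretize(npl.generate_archetype(npl.archetype_spec("L5_PC", seed=1)))


@pytest.fixture(scope="session")
def all_archetypes():
    """One discretized clone of each of the five archetypes."""
    return [
        npl.discretize(npl.generate_archetype(npl.archetype_spec(lbl, seed=1)))
        for lbl in npl.ARCHETYPE_LABELS
    ]


@pytest.fixture(scope="session")
def flat_sheet():
    return npl.flat_slab(extent=4.0, thickness=2.5, n=9)


@pytest.fixture(scope="session")
def gyrus_sheet():
    return npl.folded_sheet(extent=6.0, thickness=2.0, amplitude=1.0,
                            period=4.0, n=17)
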