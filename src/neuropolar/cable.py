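"""Steady-state membrane polarization of a compartmental cable model under an
applied extracellular potential distribution.

The discretized passive cable in the subthreshold regime is a sparse linear
system. Writing u_i = Vi_i − V_rest for the deviation of the intracellular
potential of compartment i and ve_i for the applied extracellular potential at
its midpoint, Kirchhoff's current law at steady state gives

    (L + G_m) u = G_m ve,        ΔVm = u − ve,

where L is the axial-conductance graph Laplacian of the tree (sealed ends are
automatic: leaves simply have no further neighbours) and G_m the diagonal of
membrane conductances. ΔVm is exactly linear in ve, invariant to adding a
constant to ve, and zero for zero field.

The time-stepped path integrates C du/dt = −(L + G_m) u + G_m ve(t) with
backward Euler (default Δt = 0.025 ms over a 500 ms rectangular pulse),
optionally with a generic subthreshold-active channel set (persistent-Na-like
plus slow-K-like, instantaneous activation, handled semi-implicitly). It
exists to verify steady state against the direct solve and to exercise the
linearity-of-polarization check; for passive membranes the direct solve is
the production path.

Myelin internodes use the standard single-cable simplification: membrane
resistance multiplied by ``myelin_scale`` and capacitance divided by it.

Units: geometry μm (converted to cm internally), Ra Ω·cm, Rm Ω·cm²,
Cm μF/cm², conductances μS, capacitances μF, voltages mV, time ms; then
currents come out in nA consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import UniformField, uniform_potential
from .morphology import Morphology, SectionKind, region_index

__all__ = [
    "CableParameters",
    "StimulusWaveform",
    "ActiveChannelSet",
    "PolarizationResult",
    "CableSystem",
    "solve_steady_state_passive",
    "solve_timestepped",
    "peak_polarization",
    "simulate_uniform",
    "space_constant",
]

UM_TO_CM = 1e-4


@dataclass(frozen=True)
class CableParameters:
    """Passive electrical parameters of the membrane and cytoplasm.

    ``membrane_resistance`` may be a single value (Ω·cm²) or a mapping from
    :class:`SectionKind` to values; likewise ``membrane_capacitance``
    (μF/cm²). ``myelin_scale`` multiplies internode membrane resistance and
    divides internode capacitance.
    """

    axial_resistivity: float = 100.0  # Ω·cm
    membrane_resistance: float | Mapping[SectionKind, float] = 30000.0
    membrane_capacitance: float | Mapping[SectionKind, float] = 1.0
    myelin_scale: float = 50.0
    rest_potential: float = -70.0  # mV

    def __post_init__(self) -> None:
        if self.axial_resistivity <= 0:
            raise ValueError("axial resistivity must be positive")
        if self.myelin_scale < 1:
            raise ValueError("myelin_scale must be >= 1")

    def rm_of(self, kind: SectionKind) -> float:
        rm = self.membrane_resistance
        return float(rm[kind]) if isinstance(rm, Mapping) else float(rm)

    def cm_of(self, kind: SectionKind) -> float:
        cm = self.membrane_capacitance
        return float(cm[kind]) if isinstance(cm, Mapping) else float(cm)


def space_constant(params: CableParameters, diameter_um: float,
                   kind: SectionKind = SectionKind.AXON) -> float:
    """Passive space constant λ (mm) of a uniform cylinder.

    λ = sqrt(Rm·d / (4·Ra)) with Rm in Ω·cm², d and the result converted from
    cm. Used as the analytic oracle for the finite-cable solution.
    """
    d_cm = diameter_um * UM_TO_CM
    lam_cm = math.sqrt(params.rm_of(kind) * d_cm / (4.0 * params.axial_resistivity))
    return lam_cm * 10.0  # cm → mm


@dataclass(frozen=True)
class StimulusWaveform:
    """Rectangular DC pulse: duration (ms), time step (ms), amplitude scale."""

    amplitude_scale: float = 1.0
    duration: float = 500.0
    dt: float = 0.025
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if self.shape != "rectangular":
            raise ValueError("only rectangular waveforms are supported")
        if self.duration <= 0 or self.dt <= 0 or self.dt > self.duration:
            raise ValueError("require 0 < dt <= duration")


@dataclass(frozen=True)
class ActiveChannelSet:
    """Generic subthreshold-active channels: persistent-Na-like and
    slow-K-like conductances with instantaneous sigmoidal activation.

    Densities are in S/cm²; defaults are small enough that the subthreshold
    response stays near-linear, which is exactly the regime the
    linearity-of-polarization check probes.
    """

    g_nap: float = 1e-5  # S/cm²
    e_na: float = 50.0  # mV
    nap_vhalf: float = -50.0
    nap_slope: float = 5.0
    g_ks: float = 5e-5  # S/cm²
    e_k: float = -90.0
    ks_vhalf: float = -35.0
    ks_slope: float = 6.0

    def current_density(self, vm: np.ndarray) -> np.ndarray:
        """Outward channel current density g·m∞(Vm)·(Vm − E) for Vm in mV.

        Units are (S/cm²)·mV = mA/cm²; the caller multiplies by compartment
        area (cm²) and converts mA → nA.
        """
        m = 1.0 / (1.0 + np.exp(-(vm - self.nap_vhalf) / self.nap_slope))
        n = 1.0 / (1.0 + np.exp(-(vm - self.ks_vhalf) / self.ks_slope))
        return self.g_nap * m * (vm - self.e_na) + self.g_ks * n * (vm - self.e_k)


@dataclass
class PolarizationResult:
    """Per-compartment steady-state polarization and signed regional peaks."""

    delta_vm: np.ndarray  # mV, one per compartment
    peak_by_region: dict[str, float]
    argmax_by_region: dict[str, int]


class CableSystem:
    """Assembled sparse operators for one discretized morphology.

    Factorizes (L + G_m) once so that many extracellular-potential vectors
    (e.g. the 266 direction-grid fields) can be solved as a single batched
    right-hand side.
    """

    def __init__(self, m: Morphology, params: CableParameters):
        m.validate()
        self.morphology = m
        self.params = params
        n = m.n
        lengths_cm = m.lengths() * UM_TO_CM
        diam_cm = m.diameters() * UM_TO_CM
        kinds = m.kinds()
        myel = np.array([c.myelinated for c in m.compartments])

        area = math.pi * diam_cm * lengths_cm  # lateral cylinder area, cm²
        rm = np.array([params.rm_of(k) for k in kinds])
        cm = np.array([params.cm_of(k) for k in kinds])
        rm = np.where(myel, rm * params.myelin_scale, rm)
        cm = np.where(myel, cm / params.myelin_scale, cm)
        # μS: (cm²/Ω·cm²) = S → ×1e6
        self.g_m = area / rm * 1e6
        # μF
        self.c_m = area * cm
        self.area_cm2 = area

        # axial resistance of each compartment, Ω
        r_axial = params.axial_resistivity * lengths_cm / (math.pi * (diam_cm / 2) ** 2)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        for c in m.compartments:
            if c.parent_id < 0:
                continue
            g = 1e6 / (0.5 * r_axial[c.id] + 0.5 * r_axial[c.parent_id])  # μS
            i, j = c.id, c.parent_id
            rows += [i, j]
            cols += [j, i]
            vals += [-g, -g]
            diag[i] += g
            diag[j] += g
        L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        L += sp.diags(diag)
        self.laplacian = L
        self.system = (L + sp.diags(self.g_m)).tocsc()
        self._lu = None

        # Terminal (sealed-end) evaluation: polarization of a leaf compartment
        # is read at its distal tip, where dVi/dx = 0 in the continuum, so
        # Vm(tip) = Vi − Ve(tip). Ve at the tip is linearly extrapolated from
        # the midpoint values along the parent link (exact for uniform
        # fields); this recovers the continuum sealed-end value to O(dx²)
        # instead of undershooting it by half a compartment length.
        mids = m.midpoints()
        leaf_rows, leaf_coeffs, leaf_parents = [], [], []
        for i in m.leaves():
            j = m.compartments[i].parent_id
            ref = m.soma_center if j == m.root.id else mids[j]
            dist = float(np.linalg.norm(mids[i] - ref))
            if dist > 0:
                leaf_rows.append(int(i))
                leaf_parents.append(int(j))
                leaf_coeffs.append(0.5 * m.compartments[i].length / dist)
        self._leaf_rows = np.array(leaf_rows, dtype=int)
        self._leaf_parents = np.array(leaf_parents, dtype=int)
        self._leaf_coeffs = np.array(leaf_coeffs)

    def effective_ve(self, ve: np.ndarray) -> np.ndarray:
        """``ve`` with terminal rows replaced by the extrapolated tip value."""
        out = np.array(ve, float, copy=True)
        if self._leaf_rows.size:
            i, j = self._leaf_rows, self._leaf_parents
            c = self._leaf_coeffs if out.ndim == 1 else self._leaf_coeffs[:, None]
            out[i] = out[i] + c * (out[i] - out[j])
        return out

    @property
    def lu(self):
        if self._lu is None:
            self._lu = spla.splu(self.system)
        return self._lu

    def solve(self, ve: np.ndarray) -> np.ndarray:
        """ΔVm (mV) for extracellular potentials ``ve`` (mV, per compartment
        or a (n, k) batch of k fields)."""
        ve = np.asarray(ve, float)
        rhs = self.g_m[:, None] * ve if ve.ndim == 2 else self.g_m * ve
        u = self.lu.solve(rhs)
        return u - self.effective_ve(ve)


def _check_ve(m: Morphology, ve: Sequence[float]) -> np.ndarray:
    ve = np.asarray(ve, float)
    if ve.shape != (m.n,):
        raise ValueError(f"ve must have one value per compartment ({m.n}), "
                         f"got shape {ve.shape}")
    return ve


def solve_steady_state_passive(m: Morphology, params: CableParameters,
                               ve: Sequence[float]) -> PolarizationResult:
    """Direct steady-state solve of the passive cable equations.

    ``ve`` is the extracellular potential (mV) at each compartment midpoint.
    The returned ΔVm is exactly linear in ``ve`` and unaffected by adding a
    constant to it (only potential differences along the cable matter).
    """
    ve = _check_ve(m, ve)
    try:
        sysm = CableSystem(m, params)
        dvm = sysm.solve(ve)
    except RuntimeError as exc:  # splu failure on singular systems
        raise ValueError(f"singular cable system (disconnected tree?): {exc}") from exc
    regions = region_index(m)
    peaks, argmax = peak_polarization(dvm, {r: d["all"] for r, d in regions.items()})
    return PolarizationResult(dvm, peaks, argmax)


def solve_timestepped(m: Morphology, params: CableParameters,
                      ve: Sequence[float],
                      waveform: StimulusWaveform | None = None,
                      channels: ActiveChannelSet | None = None,
                      equilibration_tol: float = 1e-9,
                      equilibration_cap: int = 10**6) -> PolarizationResult:
    """Backward-Euler integration of the cable equations over a rectangular
    pulse; ΔVm is read at pulse end relative to the equilibrated pre-stimulus
    state.

    With ``channels=None`` the membrane is passive and the result matches
    :func:`solve_steady_state_passive` to well under 0.1 % at the default
    time step. Active channel currents are treated semi-implicitly (evaluated
    at the previous step's voltage inside the implicit linear update).
    Equilibration runs until max|dVm/dt| < ``equilibration_tol`` (mV/ms) or
    fails after ``equilibration_cap`` steps.
    """
    if waveform is None:
        waveform = StimulusWaveform()
    ve = _check_ve(m, ve) * waveform.amplitude_scale
    sysm = CableSystem(m, params)
    n = m.n
    dt = waveform.dt
    C = sp.diags(sysm.c_m / dt)
    A = (C + sysm.system).tocsc()
    lu = spla.splu(A)
    vrest = params.rest_potential

    def chan_current(u: np.ndarray, ve_t: np.ndarray) -> np.ndarray:
        if channels is None:
            return np.zeros(n)
        vm = vrest + (u - ve_t)  # Vm = Vi − Ve, deviation form
        return channels.current_density(vm) * sysm.area_cm2 * 1e6  # mA → nA

    def step(u: np.ndarray, ve_t: np.ndarray) -> np.ndarray:
        rhs = sysm.c_m / dt * u + sysm.g_m * ve_t - chan_current(u, ve_t)
        return lu.solve(rhs)

    # pre-stimulus equilibration (no field)
    u = np.zeros(n)
    zero = np.zeros(n)
    if channels is not None:
        for it in range(equilibration_cap):
            u_next = step(u, zero)
            if np.max(np.abs(u_next - u)) / dt < equilibration_tol:
                u = u_next
                break
            u = u_next
        else:
            raise RuntimeError("equilibration did not converge within step cap")
    u0 = u.copy()

    n_steps = int(round(waveform.duration / dt))
    for _ in range(n_steps):
        u = step(u, ve)
    # ΔVm relative to the equilibrated pre-stimulus state, with the same
    # sealed-end tip evaluation as the direct solve
    dvm = (u - sysm.effective_ve(ve)) - u0

    regions = region_index(m)
    peaks, argmax = peak_polarization(dvm, {r: d["all"] for r, d in regions.items()})
    return PolarizationResult(dvm, peaks, argmax)


def peak_polarization(delta_vm: np.ndarray,
                      regions: Mapping[str, np.ndarray]
                      ) -> tuple[dict[str, float], dict[str, int]]:
    """Signed peak polarization per region.

    The peak is the ΔVm of maximal absolute value over the region's
    compartments, sign retained; ties are broken by the lowest compartment
    index (np.argmax returns the first maximum). Empty regions are omitted.
    """
    delta_vm = np.asarray(delta_vm, float)
    peaks: dict[str, float] = {}
    argmax: dict[str, int] = {}
    for region, idx in regions.items():
        idx = np.asarray(idx, int)
        if idx.size == 0:
            continue
        k = idx[int(np.argmax(np.abs(delta_vm[idx])))]
        peaks[region] = float(delta_vm[k])
        argmax[region] = int(k)
    return peaks, argmax


def simulate_uniform(m: Morphology, params: CableParameters,
                     field: UniformField,
                     waveform: StimulusWaveform | None = None,
                     channels: ActiveChannelSet | None = None,
                     method: str = "steady_state") -> PolarizationResult:
    """Polarization of ``m`` under a uniform E-field.

    Evaluates the uniform-field potential at every compartment midpoint (cell
    frame, origin at the soma center) and solves. ``method="steady_state"``
    uses the direct passive solve; ``method="timestepped"`` (required when
    ``channels`` is given) runs the backward-Euler pulse.
    """
    origin = m.soma_center
    f = UniformField(field.magnitude, field.direction, tuple(origin))
    ve = np.array([uniform_potential(f, p) for p in m.midpoints()])
    if channels is not None or method == "timestepped":
        return solve_timestepped(m, params, ve, waveform, channels)
    if method != "steady_state":
        raise ValueError(f"unknown method {method!r}")
    return solve_steady_state_passive(m, params, ve)
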