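"""Quasi-uniform estimation of polarization from direction maps, error
quantification against full simulation, and E-field-component regression.

The quasi-uniform estimator treats the extracellular field over a neuron as
locally uniform: take the E-field vector at the soma, rotate it into the
cell-centered frame, look up the per-unit-field polarization for that
direction in the region's polarization–direction map, and scale by |E|:

    ΔVm_est = |E| · ΔVm_U(θ_E, φ_E).

Error against the full compartment-by-compartment simulation is summarized
with the median and mean absolute percent errors (MedAPE, MAPE; true values
of exactly zero are excluded and counted separately, since a percent error is
undefined there) and the mean absolute normalized error (MANE: absolute
errors divided by the 0.975 quantile of |true| over the cell's layer group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cable import CableParameters, solve_steady_state_passive
from .dirmaps import DirectionMap, interpolate
from .fields import FieldDirection, FieldSource, decompose, sample
from .placement import PlacedNeuron

__all__ = [
    "ErrorSummary",
    "RegressionResult",
    "estimate",
    "error_summary",
    "regress",
    "run_full_comparison",
    "ComparisonOutput",
]


@dataclass
class ErrorSummary:
    """MedAPE / MAPE (%) and MANE for one group of paired values."""

    medape: float
    mape: float
    mane: float
    n: int
    n_zero_truth: int = 0  # pairs excluded from APE because true == 0


@dataclass
class RegressionResult:
    """OLS fit of polarization against an E-field predictor."""

    predictor: str
    slopes: np.ndarray
    intercept: float
    r2: float


def estimate(dmap: DirectionMap, E_world: Sequence[float],
             rotation: np.ndarray | None = None) -> float:
    """Quasi-uniform polarization estimate (mV) for somatic E-vector
    ``E_world`` (V/m).

    ``rotation`` is the cell→world rotation matrix (from the placement normal
    and azimuth); its transpose brings the world-frame vector into the cell
    frame where the map's (θ, φ) convention lives. A zero-magnitude field has
    no direction and returns 0 by definition.
    """
    E = np.asarray(E_world, float)
    mag = float(np.linalg.norm(E))
    if mag == 0.0:
        return 0.0
    if rotation is not None:
        E = np.asarray(rotation, float).T @ E
    d = FieldDirection.from_vector(E)
    return mag * interpolate(dmap, d)


def error_summary(estimates: Sequence[float], truths: Sequence[float],
                  groups: Sequence | None = None,
                  quantile: float = 0.975) -> ErrorSummary:
    """Error metrics for paired estimated vs fully simulated polarization.

    APE_i = |est_i − true_i| / |true_i| × 100 with exact-zero truths excluded
    (their count is reported); MANE normalizes absolute errors by the
    ``quantile`` of |true| within each group (the cell's layer group) before
    averaging.
    """
    est = np.asarray(estimates, float)
    tru = np.asarray(truths, float)
    if est.shape != tru.shape or est.ndim != 1:
        raise ValueError("estimates and truths must be equal-length 1-D")
    if est.size == 0:
        raise ValueError("empty input")
    nonzero = tru != 0.0
    ape = np.abs(est[nonzero] - tru[nonzero]) / np.abs(tru[nonzero]) * 100.0
    abs_err = np.abs(est - tru)
    if groups is None:
        groups = np.zeros(est.size, dtype=int)
    groups = np.asarray(groups)
    nane = np.empty(est.size)
    for g in np.unique(groups):
        sel = groups == g
        q = np.quantile(np.abs(tru[sel]), quantile)
        nane[sel] = abs_err[sel] / q if q > 0 else np.nan
    return ErrorSummary(
        medape=float(np.median(ape)) if ape.size else math.nan,
        mape=float(np.mean(ape)) if ape.size else math.nan,
        mane=float(np.nanmean(nane)),
        n=int(est.size),
        n_zero_truth=int((~nonzero).sum()),
    )


_PREDICTORS = ("|E|", "E_n", "E_t", "(E_n,E_t)")


def regress(polarizations: Sequence[float], decompositions: Sequence,
            predictor: str = "E_n") -> RegressionResult:
    """OLS regression of polarization against an E-field component.

    For ``predictor="|E|"`` the response is |polarization| (a magnitude has
    no sign to explain); for ``E_n``, ``E_t`` and the multivariate
    ``(E_n,E_t)`` the signed polarization is used. Returns slope(s),
    intercept and R². A zero-variance predictor raises, since R² is
    undefined there.
    """
    if predictor not in _PREDICTORS:
        raise ValueError(f"predictor must be one of {_PREDICTORS}")
    y = np.asarray(polarizations, float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    en = np.array([d.E_n for d in decompositions])
    et = np.array([d.E_t for d in decompositions])
    mag = np.array([d.magnitude for d in decompositions])
    if predictor == "|E|":
        X = mag[:, None]
        y = np.abs(y)
    elif predictor == "E_n":
        X = en[:, None]
    elif predictor == "E_t":
        X = et[:, None]
    else:
        X = np.column_stack([en, et])
    if np.any(X.std(axis=0) == 0.0):
        raise ValueError("zero-variance predictor: R² undefined")
    A = np.column_stack([X, np.ones(len(y))])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # a (numerically) constant response has no variance to explain
    if ss_tot <= 1e-14 * max(1.0, float(y @ y)):
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return RegressionResult(predictor, coef[:-1], float(coef[-1]), r2)


@dataclass
class ComparisonOutput:
    """Paired estimates/truths plus summary tables from a full comparison."""

    pairs: pd.DataFrame  # columns: region, layer, cell, estimate_mV, truth_mV, ...
    errors: dict[str, ErrorSummary]  # per region
    regressions: dict[str, dict[str, RegressionResult]]  # region -> predictor
    n_out_of_domain: int = 0


def run_full_comparison(population: Sequence[PlacedNeuron],
                        source: FieldSource,
                        maps: Mapping[tuple[str, int], Mapping[str, DirectionMap]],
                        params: CableParameters,
                        reference: str = "soma") -> ComparisonOutput:
    """Full vs quasi-uniform comparison over a placed population.

    For each placed neuron: (a) sample the field source at every compartment
    midpoint and solve the cable system for the true regional peaks; (b)
    sample the E-vector at the reference point (default the soma; "local"
    uses the region's true peak compartment instead) and apply the
    quasi-uniform estimate per region. ``maps`` is keyed by
    (archetype_label, clone_seed). Out-of-domain samples skip the neuron and
    are counted.
    """
    rows = []
    n_ood = 0
    for cell_idx, pn in enumerate(population):
        m = pn.morphology
        pts_um = pn.world_midpoints_um()
        samples = sample(source, pts_um)
        if not all(s.in_domain for s in samples):
            n_ood += 1
            continue
        ve = np.array([s.potential for s in samples])
        truth = solve_steady_state_passive(m, params, ve)
        cell_maps = maps[(m.archetype_label, m.clone_seed)]
        R = pn.placement.rotation()
        soma_idx = truth.argmax_by_region.get("soma", 0)
        dec = decompose(samples[soma_idx].E, pn.placement.normal)
        for region, dmap in cell_maps.items():
            if region not in truth.peak_by_region:
                continue
            if reference == "soma":
                ref_idx = soma_idx
            elif reference == "local":
                ref_idx = truth.argmax_by_region[region]
            else:
                raise ValueError("reference must be 'soma' or 'local'")
            est = estimate(dmap, samples[ref_idx].E, R)
            rows.append(
                dict(region=region, layer=pn.placement.layer, cell=cell_idx,
                     archetype=m.archetype_label, clone_seed=m.clone_seed,
                     estimate_mV=est, truth_mV=truth.peak_by_region[region],
                     E_mag=dec.magnitude, E_n=dec.E_n, E_t=dec.E_t)
            )
    if not rows:
        raise ValueError("no in-domain neurons to compare")
    pairs = pd.DataFrame(rows)
    errors: dict[str, ErrorSummary] = {}
    regressions: dict[str, dict[str, RegressionResult]] = {}
    for region, sub in pairs.groupby("region"):
        groups = list(zip(sub["layer"], sub["archetype"], sub["clone_seed"]))
        errors[region] = error_summary(
            sub["estimate_mV"].to_numpy(), sub["truth_mV"].to_numpy(),
            groups=pd.factorize(pd.Series(groups).astype(str))[0],
        )
        decs = [
            decompose(np.array([0.0, et, -en]), np.array([0.0, 0.0, 1.0]))
            for en, et in zip(sub["E_n"], sub["E_t"])
        ]
        regs: dict[str, RegressionResult] = {}
        for pred in _PREDICTORS:
            try:
                regs[pred] = regress(sub["truth_mV"].to_numpy(), decs, pred)
            except ValueError:
                continue
        regressions[region] = regs
    return ComparisonOutput(pairs, errors, regressions, n_ood)
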