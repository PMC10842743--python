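# Methods

## Scope and model structure

`neuropolar` simulates the subthreshold, steady-state membrane polarization
that weak DC extracellular fields induce in multi-compartment cortical neuron
models, and evaluates the quasi-uniform estimator built on
polarization–direction maps. It deliberately stops short of the two ends of
the full multi-scale pipeline: it consumes field distributions (analytic, or
FEM-exported node potentials on a mesh) rather than solving the volume
conductor problem, and it models membranes as passive by default rather than
reproducing any specific conductance-based channel library. Both choices keep
the package self-contained and the physics it does claim testable against
closed forms.

## Cable model

Each compartment is an isopotential cylinder; discretization splits segments
to at most 20 μm (default), which keeps the passive solution within ~0.3 % of
the analytic finite-cable profile on the oracle fixture. Writing
u = Vi − V_rest and ve for the applied extracellular potential at compartment
midpoints, current balance at steady state gives

    (L + G_m) u = G_m ve,    ΔVm = u − ve_eff,

with L the tree's axial-conductance Laplacian (axial conductance between
midpoints of adjacent compartments: reciprocal of the two half-segment
resistances, Ra·l/(π r²)) and G_m the diagonal of membrane conductances
(lateral area / Rm). Sealed ends need no explicit boundary term — leaves
simply lack further neighbours.

**Terminal evaluation.** At a sealed end the continuum solution has
dVi/dx = 0, so Vm at the tip is Vi − Ve(tip), not Vi − Ve(midpoint). The
solver therefore reads terminal compartments' polarization at the distal tip,
with Ve(tip) linearly extrapolated along the parent link (exact for uniform
fields). Without this correction the terminal value undershoots the continuum
sealed-end value by half a compartment length (~3 % at 20 μm on the oracle
cable); with it the error is ~0.3 %.

Consequences that hold exactly in the linear solver and are tested: ΔVm is
linear in ve (superposition, field-reversal antisymmetry), invariant to
adding any constant to ve, and zero for zero field.

**Time stepping.** The backward-Euler path integrates
C du/dt = −(L+G_m)u + G_m ve(t) over a rectangular pulse (defaults 500 ms,
Δt = 25 μs; the system matrix is factorized once). It exists to validate the
steady-state solve (agreement ≪ 0.1 %) and to host the optional active
channels. Pre-stimulus equilibration iterates to max|dVm/dt| < 1e-9 mV/ms
(capped at 10⁶ steps); for the passive membrane the rest state is the exact
equilibrium, so equilibration is a no-op.

**Active channels.** The optional set is a generic persistent-Na-like and
slow-K-like pair with instantaneous sigmoidal activation, treated
semi-implicitly (channel current at the previous step's voltage inside the
implicit linear update). Densities (1e-5 and 5e-5 S/cm²) are small enough
that polarization stays near-linear over a 1–6× field range — which is the
point: the machinery for testing linearity of polarization needs a
nonlinearity to exercise. In linearity tests, compartments sitting at the
polarization zero-crossing (<1 % of the cell's peak response) are excluded
from the per-compartment R² check: their response has no linear term to fit,
so R² there measures noise about zero, not nonlinearity.

**Myelin.** Internodes multiply membrane resistance by `myelin_scale`
(default 50) and divide capacitance by it — the standard single-cable
simplification. The myelination rule (axonal segments with diameter ≥ 0.5 μm
beyond a 50 μm path distance from the soma; terminals and branch points stay
bare) is a documented stand-in: published geometric rules for specific
reconstructions are not restated in a reusable form, so the rule here is
chosen to produce the qualitative effect that matters — myelin extends the
axonal space constant and raises terminal polarization, and stripping it
(`rule="none"`) lowers the axonal peak, by ~16 % on the default L5 archetype.

**Default passive parameters.** Ra = 100 Ω·cm, Rm = 30 000 Ω·cm²,
Cm = 1 μF/cm², rest −70 mV — ordinary cortical-neuron values; the space
constant λ = √(Rm·d/4Ra) of a 2 μm process is then ~0.6 mm, so
fixture-scale morphologies (0.5–1.5 mm extent) are electrotonically compact
but not degenerate.

## Synthetic archetypes

The five archetypes (L1_NGC, L23_PC, L4_LBC, L5_PC, L6_PC) are stylized:
straight apical trunks with distal tufts, radiating basal dendrites
(downward/lateral for pyramidal cells, isotropic for interneurons), a
descending axon with oblique collaterals, stochastic branch angles per clone
seed. They emulate what matters for field coupling — somatodendritic
asymmetry, terminal-rich arbors, layer-scaled extents — and nothing
cytoarchitecturally finer. Basal branches that bifurcate do so with two
daughters, so every branch point is a genuine bifurcation and terminal
compartments are the only free ends; polarization maxima then sit at
terminals for every archetype and direction, which matches the behaviour of
morphologically detailed models. Trunk lengths (120–700 μm) scale with layer
so the package runs at desk scale; they are several-fold smaller than real
cortical cells, which lowers absolute polarization values (the default L5
archetype peaks at ~0.12 mV/(V/m) somatic vs ~0.16–0.22 reported for
full-size reconstructions) but preserves the orderings the tests assert:
pyramidal somas polarize more than interneuron somas, terminals more than
somas, inward fields depolarize pyramidal somas.

What passing tests therefore show about real data: the *machinery* —
coupling, solver, maps, estimator, error metrics — behaves correctly on
morphologies with the right qualitative structure. They do not certify
absolute polarization magnitudes for any real cell type.

## Fields and units

Geometry is μm for morphologies and mm for meshes/sources, converted once at
sampling time; potentials are returned in mV, E-vectors in V/m. Uniform
fields evaluate the linear potential exactly. Point sources superpose
V = I/(4πσr) in an infinite homogeneous medium (default σ = 0.275 S/m,
isotropic gray matter) — an analytic stand-in for a non-uniform field whose
gradient scale is set by source distance. Mesh fields interpolate node
potentials with the element's first-order basis, so E is constant per element
(the element containing the soma supplies the somatic E-vector; node-averaged
alternatives would smooth gradients and are not implemented). Out-of-mesh
points are flagged, never extrapolated. The normal/tangential decomposition
is inward-positive: E_n = −E·n̂ with n̂ the outward cortical normal.

## Direction maps

The direction grid is θ-major with poles sampled once: for step s,
2 + (180/s − 1)(360/s) unique directions (266 at 15°). Maps are built at
1 V/m — one sparse LU factorization per morphology, all directions solved as
a single multi-column right-hand side — and store the signed regional peak
(maximum-absolute ΔVm, sign kept, ties to the lowest compartment index).
Interpolation is bilinear on the (θ, φ) lattice with periodic wrap in φ and
pole rows replicated across φ, which keeps the interpolant rectangular and
exact at grid nodes; whether to interpolate in (θ, φ) or in projected
coordinates was an open choice, and (θ, φ) was picked for its separable
lattice. The Mollweide projection (latitude 90° − θ) solves
2α + sin 2α = π sin(lat) by bracketed Newton with bisection fallback — the
derivative vanishes at the poles, where plain Newton started from α = lat
diverges — giving round-trip errors ~1e-13 degrees away from the immediate
pole neighbourhood.

## Placement

Synthetic cortical sheets (flat slab; sinusoidally folded "gyrus" with
analytic normals) stand in for MRI-derived surfaces; both are generated
clean, so mesh repair is out of scope. Layer surfaces interpolate vertex-wise
between pial (depth 0) and white (depth 1) at the standard normalized depths
(boundaries 0.0993 / 0.466 / 0.524 / 0.753; placement depths 0.01 / 0.4 /
0.5 / 0.75 / 0.95). Cells sit at triangle centroids, somatodendritic axis
along the element's outward normal, azimuth drawn from the seeded generator.

"Outside the pial surface" is operationalized as ray-parity for watertight
meshes and, for open patches (all fixtures), a signed-distance test against
the nearest triangle's outward normal; compartments are tested at midpoints.
Repair searches inward translation along the column by binary search
(tolerance 1 μm) jointly over 36 seeded azimuth candidates, returning the
minimal translation (ties to the smallest azimuth change); translation is
capped by the distance from the placement depth to the layer's lower
boundary, so somas never leave their layer. Candidates that still violate
just below the incumbent best translation are pruned after two checks, which
is what makes the 36-candidate search affordable. Elements with no admissible
configuration are reported as failures and left unpopulated.

## Estimator and error metrics

The quasi-uniform estimate rotates the world-frame somatic E-vector into the
cell frame with the placement rotation (align ẑ to the normal, then spin by
the azimuth), converts to (θ, φ), interpolates the region's map and scales by
|E⃗|; zero-magnitude fields return 0 (no direction). A config option
(`reference="local"`) samples the E-vector at the region's true peak
compartment instead of the soma, for studying whether local sampling reduces
error.

APE_i = |est−true|/|true| × 100 with exact-zero truths excluded and counted
(a percent error is undefined there, and near-zero truths are the known
outlier driver for MAPE). MANE divides absolute errors by the 0.975 quantile
of |true| within the cell's layer group — implemented per clone-within-layer,
since the pooled alternative is ambiguous; the grouping is switchable via the
`groups` argument. Regression uses SVD least squares (numpy lstsq) with an
intercept; responses are |ΔVm| for the |E| predictor and signed ΔVm for E_n,
E_t and the multivariate pair; a numerically constant response is reported as
R² = 0, a zero-variance predictor as an error. The independent test oracle is
the closed-form normal-equations solution.

## Problem sizes and numerical defaults

Test and acceptance fixtures are sized for a single desk-class core:
morphologies of 120–320 compartments, sheets of 128–512 triangles,
populations of 8–10 cells, 10⁴ ray–triangle instances, 1000 Mollweide
round-trip directions, three point-source distances (40 / 10 / 2 mm). The
direction sweep over 5 archetypes × 266 directions runs as batched linear
solves in seconds. Key tolerances: solver linearity at machine precision;
time-stepped vs direct steady state < 0.1 %; cable oracle < 1 % at 20 μm
discretization; binary-search translation 1 μm; Mollweide round trip < 1e-9.

## Known limitations

- Archetypes are stylized; absolute polarization magnitudes are not
  calibrated to any reconstruction, only orderings and scalings are.
- The myelination rule is a stand-in (documented above).
- Mesh-field sampling uses brute-force point location — adequate for fixture
  meshes, not for million-element FEM exports.
- The violation test samples compartment midpoints, so a compartment longer
  than the local protrusion could in principle straddle the surface
  undetected; fixture discretizations are fine enough that this does not
  occur in the shipped tests.
- Suprathreshold activation, synaptic effects and ephaptic feedback are out
  of scope.
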