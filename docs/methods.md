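# Methods

`tdcsflow` predicts the interstitial water exchange produced by transcranial
direct current stimulation (tDCS), on the hypothesis that the only induced
flow is electroosmosis through the tight junctions (TJs) of the blood-brain
barrier (BBB). The pipeline is linear at every stage, so its end product is
a single scaling factor k (m² A⁻¹ min⁻¹) that converts any brain
current-density map, for any montage or current, into a voxelwise fluid
exchange map. This note documents the model at each scale, the parameters
that matter, the numerical choices, and the limits of what the synthetic
stand-ins can show.

## 1. Electroosmosis in the tight-junction slit

The TJ is idealized as a slit of width 2h = 2 nm between two smooth walls at
zeta potential ζ = −21.1 mV. With a Debye length κ⁻¹ = 0.905 nm the double
layers on the two walls overlap, and the equilibrium potential is taken as
the superposition of the two single-wall Gouy–Chapman profiles:

    ψ(y) = (4kT/ze)·[atanh(tanh(zeζ/4kT)·e^(−κy)) + atanh(tanh(zeζ/4kT)·e^(−κ(2h−y)))]

The electroosmotic velocity under an axial field E follows from the
thin-channel Stokes balance,

    u(y) = −(εζE/μ)·(1 − ψ(y)/ζ),

with ε = 7.08×10⁻¹⁰ F/m and μ = 7.8×10⁻⁴ Pa·s. In the thin-double-layer
limit this recovers the Helmholtz–Smoluchowski slip |εζ/μ| = 1.92×10⁻⁸ m/s
per V/m; the overlap in the 2 nm slit suppresses the channel average to
3.85×10⁻⁹ m/s per V/m (the value the package computes with converged
quadrature; coarser discretizations give values nearer 3.82×10⁻⁹).

**Validity.** The superposition is a weak-overlap approximation. Two visible
artifacts at the default geometry (κh ≈ 1.1): |ψ| overshoots |ζ| by ~11%
at the walls, so the velocity dips slightly negative in a thin near-wall
band; and for κ⁻¹/h ≳ 1.27 the approximation predicts net flow reversal and
should not be used. Within κ⁻¹/h ≲ 1.2 the signed channel average decreases
monotonically with overlap, as expected physically.

**Quadrature.** Composite trapezoid on a uniform grid over [0, 2h], starting
at 1001 points and doubling until successive refinements agree to 0.1%. The
integrand is smooth and finite at the walls; endpoints are evaluated
directly. Because u is exactly linear in E, the velocity coefficients are
evaluated at E = 1 V/m rather than fitted over a sweep.

Multiplying the average-velocity coefficient by the TJ opening (2 nm) and
the junction length per unit vessel area (L_TJ = 150 000 m/m²) gives the
volumetric flux coefficient, QA/E_TJ ≈ 1.15×10⁻¹² m³ s⁻¹ m⁻² per V/m.

## 2. TEER and membrane conductivities

TEER (areal resistance of the vessel wall) is the experimentally anchored
parameter; 1000 Ω·cm² is the reference in vivo BBB value and 5000 Ω·cm² an
upper bound. TEER inputs carry an explicit unit tag (default Ω·cm², the
experimental convention; 1 Ω·cm² = 10⁻⁴ Ω·m²). Two attributions are used:

* wall scale: σ_wall = ℓ_wall/TEER with ℓ_wall = 1 μm
  (10⁻⁵ and 2×10⁻⁶ S/m at 1000 and 5000 Ω·cm²);
* TJ scale: all wall resistance assigned to the TJ constriction,
  σ_TJ = ℓ_TJ/(TEER·2h·L_TJ) with ℓ_TJ = 11 nm
  (3.67×10⁻⁴ and 7.34×10⁻⁵ S/m).

The per-compartment conductivity table (scalp 0.465, skull 0.01, CSF 0.8,
gray matter/parenchyma 0.276, white matter 0.126, lumen 0.7 S/m, etc.) is
shipped as package data (`data/conductivities.yaml`) and overridable.

## 3. Wall-current → TJ-field coupling

A current density J crossing the capillary wall concentrates a field
E_TJ = C·J in the TJ. The constants from the full 3D ultrastructure field
solution — C = 2.73×10⁶ V·m/A at 1000 Ω·cm² and 3.83×10⁶ at 5000, single
TJ — are the default (`mode="lookup"`).

`mode="model"` exposes a reduced-order series–parallel conductance network:
the paracellular branch is the series chain glycocalyx → cleft (luminal
side, 105 nm) → TJ → cleft (abluminal side, 584 nm) → basement membrane →
astrocytic channel, each with per-vessel-area conductance
σ·(open-area fraction)/length; cleft-like channels use the open fraction
20 nm × L_TJ = 3×10⁻³, and the TJ term is exactly 1/TEER by construction.
The transcellular branch is the insulating membrane, σ 10⁻⁵ S/m over 1 μm.
With f the paracellular current fraction,

    C = f · TEER / (ℓ_TJ · a),

where a = 2.04 is the parenchyma-to-astro-endothelial surface ratio (the
printed ratio of areas is arithmetically 2.36; the stated 2.04 is used and
is config-overridable). The glycocalyx thickness, basement-membrane
thickness and astrocytic channel length are not tightly constrained; the
defaults (100 nm, 100 nm, 1 μm) contribute resistances orders of magnitude
below the TJ's, so C is insensitive to them. The model reproduces the
lookup constants to −19% (1000) and −3% (5000), and shows the expected
monotonicities (more transcellular shunting → lower C; more TJs → higher
paracellular fraction). `n_tight_junctions > 1` scales the paracellular
branch proportionally and is an extrapolation beyond the single-TJ
reference.

## 4. Capillary network and the voxel current solve

**Geometry.** The reference geometry is a corrosion-cast-derived capillary
network inside a 0.15 × 0.16 × 0.43 mm voxel with length density
557 mm/mm³, 8–10 μm outer diameters and 1 μm walls. That CAD network is not
distributable, so a seeded generator stands in: a persistent branching
random walk (step ≤ 12 μm, branch probability 0.18 per step, anastomosis
capture radius 0.45 step) grown from a single tip until the target length
density is met; tips terminate (seal) at voxel faces; sprouting from
existing nodes keeps the graph connected; deterministic per seed. At the
default target the generator achieves ~558 mm/mm³ and lumen volume fraction
~0.022, matching the reference 557 and 0.021. The reference surface density
(22.5 mm²/mm³) is mutually inconsistent with the printed diameters (it
implies d ≈ 13 μm); the generator prioritizes length density and diameter
range and reports achieved values (~15.8 mm²/mm³).

**Physics.** Steady current flow solves ∇·(σ∇V) = 0 with a uniform inward
current density on the top face (0.082 A/m² per mA — the peak brain current
density from the head-scale model), ground on the bottom face, insulated
sides. Discretization: cell-centered finite differences for the parenchyma
(σ = 0.276 S/m; default grid 48×52×140, ~3 μm spacing, chosen so several
cells span inter-vessel gaps; config-overridable); each vessel segment is a
1D axial lumen conductor (σ = 0.7 S/m × lumen cross-section) subdivided at
the grid scale; each lumen piece couples to the grid cells whose centers
lie within one grid spacing of it through a membrane conductance per area
of 1/TEER (thin-wall approximation σ_wall/ℓ_wall), with the piece's lateral
area split equally among those cells. Because the coupling conductance is
proportional to the area share, the reported wall-normal current density
J = (1/TEER)·(V_cell − V_lumen) is independent of the apportionment.

Boundary variants: `closed` — no lumen ground, so all current entering the
blood exits elsewhere in the same network (verified: net lumen current
< 10⁻⁶ of gross); `open` — the lumen of the 4 largest-diameter segments is
additionally grounded, standing in for collection by larger vessels (the
choice of grounded surfaces in the reference model is not enumerated; the
largest-diameter rule is deterministic given the seeded diameters).

**Linear algebra.** The system is a symmetric positive-definite conductance
Laplacian (grid + lumen DOFs, Dirichlet rows eliminated), solved by
Jacobi-preconditioned conjugate gradients to a relative residual of 10⁻¹⁰
(direct sparse LU below 6000 unknowns). Conservation is checked on every
solve: interior Kirchhoff residual and global in/out balance are reported
on the solution object and sit at ~10⁻¹² of the applied current.

**Behaviour vs the reference network.** At the default grid the synthetic
closed/1000 peak wall current density is ~4.2×10⁻⁴ A/m² (reference
3.2×10⁻⁴, factor 1.3); raising TEER to 5000 lowers it to ~1.1×10⁻⁴
(reference 9.1×10⁻⁵), and the open variant exceeds the closed one, both as
in the reference. Peak values are geometry-sensitive, which is why all
network-stage comparisons are tolerance-based (factor of 3) rather than
exact.

## 5. Flux conversion and aggregation

Combining the constants, QA = J_norm · (1.15×10⁻¹²) · C, signed like
J_norm. Net interstitial exchange per tissue volume sums |QA|·area over all
wall elements and divides by the voxel volume (×60 → per minute). Both flow
directions are counted — water leaving the interstitium at one element
returns at another — matching the reference convention; a
`convention="half"` flag gives the in-only alternative since the
double-counting question is not resolved experimentally. True per-element
areas from the solver are used rather than assuming equal node areas.

Dividing the exchange rate by the driving brain current density (0.082
A/m² per mA) yields the scaling factor k. Reference values for the four
conditions (1000/5000 TEER × closed/open) are 1.9, 4.6, 7.0, 3.5 ×10⁻³
m²/(A·min); the synthetic network at the default grid gives k ≈ 3.9×10⁻³
for closed/1000 — same order, larger by the same factor as its peak
current density.

## 6. Brain-wide maps and the synthetic head field

The head-scale FEM is out of scope; `synthetic_brain_field` provides a
smooth surrogate — Gaussian lobes under configurable electrode centers plus
5% seeded noise, rescaled so the peak is exactly 0.082 A/m² per mA. It
emulates the magnitude and smoothness of a real current-density map, not
anatomy: no tissue boundaries, CSF channeling, or montage-specific
focality. Exchange maps are produced by voxelwise multiplication with k and
inherit the map's per-mA linearity: montage and intensity permutations are
pure rescalings. NIfTI I/O (via nibabel) is supported for real
current-density maps from external head-modelling tools.

## 7. What the synthetic stand-ins do and do not show

Passing tests demonstrate: the electroosmotic constants and the TEER/
coupling arithmetic to printed precision; exact linearity of the full chain
in the applied current; current conservation and the correct orderings
(TEER up → wall currents down; open ≥ closed); and that a network matching
the in vivo morphometric densities lands within a small factor of the
reference peak currents and exchange rates. They do not validate the
anatomical specifics of any real capillary bed, the true distribution of
wall current density (only its scale), or the physiological correctness of
the underlying parameters (ζ, TEER, L_TJ), which are inputs taken from
experiments.

## 8. Default problem sizes

Default runs use the 48×52×140 grid (~360k unknowns, ~10 s per solve on one
core) with the full 557 mm/mm³ network (~500 segments). Unit and property
tests use the same voxel at coarser grids (24×26×70 and 32×36×96), where
the peak wall current density differs from the default grid by well under
10%; the reduced sizes are a deliberate accuracy/runtime trade-off for
routine testing, with the default grid exercised in the acceptance tests.

## 9. Known limitations

* No pressure-driven (hydraulic) lumen flow, hematocrit, or red-cell
  effects; no solute transport or clearance kinetics; DC steady state only.
* The weak-overlap slit model excludes protruding junction proteins and
  breaks down for κ⁻¹/h ≳ 1.2 (see §1).
* The reduced-order coupling model is a 1D caricature of a 3D field
  problem; it is for sensitivity exploration, not for replacing the lookup
  constants.
* The embedded-membrane discretization does not resolve the vessel wall
  geometrically; sub-grid accuracy of individual wall elements is limited,
  and only network-scale statistics (peaks, sums) should be interpreted.
* Endogenous interstitial flow is not modelled; computed exchange rates are
  additive to background flow.
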