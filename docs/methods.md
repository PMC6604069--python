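# Methods

## The GHz water process and its model family

The main dielectric relaxation of liquid water near 20 GHz is treated as a
rate process of cooperative hydrogen-bond exchange. Spectra are modelled
with the Havriliak–Negami family

ε\*(ω) = ε∞ + Σ_k Δε_k / [1 + (jωτ_k)^β_k]^α_k + σ_dc/(jωε_vac),

with the sign convention ε\* = ε′ − jε″, ε″ ≥ 0, and the principal branch
of the complex power. **Exponent naming:** β is the *symmetric*
relaxation-time-distribution exponent and α the *asymmetric* one (Debye:
α = β = 1; Cole–Cole: α = 1; Cole–Davidson: β = 1). A large part of the
literature swaps these two symbols; all serialized output therefore labels
them `symmetric_beta` / `asymmetric_alpha`. The conductivity term is
optional (default σ_dc = 0) and exists because slower processes overlap
the GHz band from the low-frequency side in conductive samples. The vacuum
permittivity is fixed at 8.8541878128 × 10⁻¹² F/m. Two literature values
of the pure-water relaxation time at 25 °C are in circulation (8.2 ps and
8.3 ps); both are exposed as constants and 8.3 ps is used as the τ–β
diagram anchor and for GHz-process selection in multi-process fits.

### Fitting

`fit_spectrum` minimises Σ w_i |ε\*_model(f_i) − ε\*_data(f_i)|² with
relative weights w_i = 1/|ε\*_data(f_i)|² by default (TDR loss spectra
span decades; uniform weighting is available). The search runs on
log₁₀ τ and log₁₀ Δε with box bounds on the raw exponents
(10⁻³ ≤ α, β ≤ 1) under a trust-region-reflective solver: the Debye limit
β = 1 is an *attainable bound*, so a single-Debye spectrum fitted in
Cole–Cole mode returns β = 1 exactly rather than asymptotically. τ is
bounded to [10⁻¹⁴, 10⁻⁶] s. Two starts are used — the loss-peak
initialisation and a broadened-exponent variant (free exponents at 0.7) —
because the Debye corner is a local optimum for strongly asymmetric data.
One-sigma parameter uncertainties come from the Jacobian at the optimum
(s²(JᵀJ)⁻¹, pseudo-inverse), mapped through the log transforms. Processes
are reported sorted by ascending τ (ties broken by larger Δε), and with no
explicit index the "GHz process" is the one with τ closest to 8.3 ps in
log distance.

Noise-free round trips recover all four special cases to ≤ 10⁻⁶ relative
error on 100-point grids; at 1 % relative noise, τ and β of a Cole–Cole
process are recovered within 5 % across seeds.

## The τ–β trajectory and the fractal dimension

The Ryabov relation β(τ) = (D/2)·ln(τω_S)/ln(τ/τ₀) links the Cole–Cole
exponent to the mean relaxation time through three parameters: the fractal
dimension D of the set of relaxing units (the horizontal asymptote is
D/2), the self-diffusion frequency ω_S (the zero crossing is at
τ = 1/ω_S), and the time-scaling cutoff τ₀ (the vertical asymptote). Two
distinct reference times appear in the analysis and are named separately:
the diagram normalisation constant (pure-water τ, 8.3 ps) and the scaling
cutoff τ₀ inside the relation.

`eval`uation applies no clamping — β values outside (0, 1] are returned
so the caller can detect a wrong branch. β → D/2 holds asymptotically;
quantitatively the deviation at τ = 10⁶ τ₀ is |ln(τ₀ω_S)|/ln 10⁶, i.e.
below 1 % exactly when τ₀ω_S is of order one, which is the physically
relevant regime (both are microscopic cutoffs of the same scaling; the
pure-water-anchored coupling below gives τ₀ω_S → 1 as D → 2).

### Trajectory fitting

The three parameters are weakly identifiable from the short arcs real
composition series provide. The fit therefore runs on
(D, L = ln(τ₀ω_S), ln(τ₀/min τ)) with bounds D ∈ (0, 4],
L ∈ [0, 14], τ₀ ∈ [0.01, 1]·min τ, from a small grid of starts, keeping
the best optimum. The D uncertainty is the curvature-based one-sigma value
computed with a pseudo-inverse, which inflates appropriately when the
(D, L) degeneracy near the vertical part of the curve leaves D poorly
determined. Classification uses the one-sigma interval with strict
inequalities: solution iff D − u > 1, dispersion iff D + u < 1, otherwise
indeterminate (the classes genuinely overlap near D = 1, so the boundary
case D = 1, u = 0 is indeterminate by design).

### Synthetic trajectory generator

`make_trajectory` encodes the study conditions used throughout the tests:

- every trajectory passes the pure-water anchor: ω_S is coupled to D by
  τ₀ω_S = 2^(2/D−1) with τ₀ = 4.15 ps, which makes β(2τ₀ = 8.3 ps) = 1
  exactly;
- points are sampled on a fixed **β window** (from ≈ 0.95 down to
  max(0.40, D/2 + 0.02)), as experiments observe a β range rather than a
  τ range, with Gaussian β-noise (default studies use σ = 0.02) clipped
  into (0, 1];
- 12 points per trajectory by default.

This reproduces the experimentally observed asymmetry: solution-type
trajectories (large D) sweep several decades of τ and pin their asymptote,
while dispersion-type ones cover a short, nearly vertical arc, so their
fitted D is an extrapolation with a several-fold larger uncertainty at
equal noise. Monte-Carlo recovery over D ∈ [0.2, 1.9] at σ_β = 0.02 gives
a median |D_est − D_true| of ≈ 0.03 (well inside the ±0.1 working
precision of the method). What the generator does **not** emulate:
correlated (τ, β) errors from a shared spectrum fit, multiple relaxation
processes leaking into the GHz window, or temperature drift — passing
tests therefore validate the trajectory analysis, not the spectroscopy
pipeline upstream of it.

Bulk-solvent normalisation for gels divides each gel τ by the bulk-solvent
τ at the same composition (linear interpolation on the bulk grid; no
extrapolation — out-of-range points yield per-point error records). This
removes reentrant solvent-mixture behaviour and leaves only the
restriction imposed by the polymer network.

## Box counting and regime segmentation

`box_count` tiles the raster from the array origin into s-cell boxes
(partial boxes at the far edges included; implemented as an OR-reduction
per axis) and counts boxes containing foreground. Default sizes are the
dyadic ladder 1, 2, 4, … stopping strictly below the largest grid
dimension (a box covering the whole grid always counts 1 and carries no
scaling information). Offset-averaged counting is available as an option
for robustness studies; the default is deterministic anchored counting.
Counting is verified against an explicit-loop oracle on random 2-D/3-D
grids.

Real objects scale differently above and below their structural lengths,
so `segment_regimes` reports two regime dimensions and the characteristic
box size between them. The default **plateau estimator** measures each
regime on its stable scaling window: local slopes between consecutive
sizes are grown from the smallest (and, separately, largest) sizes for as
long as they agree with the running mean within a tolerance (0.25 of a
dimension unit), each arm is fitted by OLS, and the breakpoint is the
intersection of the two arm lines, clamped into the analysed range. The
classic exhaustive two-segment least-squares search over shared interior
breakpoints is available as `method="grid"` and is also used for the
single-regime decision (two-segment improvement < 5 % of the single-line
residual, or indistinguishable arm slopes). The plateau default exists
because broad crossovers — e.g. the sphere chain, whose 3-D→1-D crossover
spans two octaves around the rod diameter — bias any estimator that forces
every point into one of two straight segments; slopes fitted on the stable
windows recover the asymptotic dimensions (2.93/1.00 for the chain, with
the breakpoint at ≈ 34 model units, near the rod diameter of 40) where the
plain two-piece fit reports 2.79/2.01.

Degenerate and edge behaviour: empty grids, zero sizes and sizes beyond
the grid are input errors; counts are validated non-increasing; arms of
two points are allowed (the thin-line model *needs* a two-point small-box
arm, sizes {1, 2}, to measure D = 2 below a 2-pixel width).

Binarization of grayscale micrographs uses a fixed threshold or Otsu's
between-class-variance criterion, with dark-foreground polarity by default
(stained fibrous tissue on a bright background).

### Geometric reference models

The sphere chain (n spheres, spacing d, radius R, centres on a line)
rasterises by voxel-centre inclusion — fast, deterministic, and with
volume error well below 1 % at R/h ≥ 20 (halving the voxel size at least
halves the error). The grid is padded by one radius on every side; a
memory guard rejects grids beyond 10⁸ voxels. With R < d the chain is 100
disjoint blobs ("dotted line"): between the sphere size and the spacing
the count is pinned near the number of spheres, giving the near-zero
intermediate dimension characteristic of a fragmented network. The 2-D
models are exact rasters: full box, half box (left half), and an
axis-aligned solid line through the centre (orientation configurable;
the regime structure is orientation-invariant).

## Probe electrostatics

The open-ended coaxial probe is modelled quasi-statically:
∇·(ε∇V) = 0 on the (r, z) half-plane with the inner conductor (r ≤ a,
z ≤ 0) at 0.2 V, the outer conductor (r ≥ b, z ≤ 0) at 0 V, PTFE
(ε_r = 2.1) in the annulus, the sample half-space above the aperture, a
symmetry condition on the axis, 0 V on the far boundaries, and the
analytic TEM profile V(r) = 0.2·ln(b/r)/ln(b/a) imposed at the deep-cable
cross-section. Conductor radii follow from the characteristic impedance:
b/a = exp(Z√ε_r/59.96) (≈ 3.35 for a 50 Ω PTFE line), with b set by the
outer diameter minus a configurable wall (default 0.3 mm; the true wall is
not standardised). The discretisation is a finite-volume 5-point stencil
with harmonic-mean face permittivities, solved by sparse LU — direct
rather than iterative, since the grids involved (≈ 10⁵ nodes at the
default cell size a/8, domain three outer diameters beyond the aperture)
factor in well under a second and the solve is then exact to machine
precision. Solutions satisfy the discrete maximum principle and match the
TEM profile within 1 % deep in the cable; halving the cell size changes
the reported depths by < 3 %.

Penetration depth is extracted from the on-axis potential above the
aperture two ways: (i) a least-squares single-exponential fit of the near
region (down to 20 % of the surface value), and (ii) the 54 %-of-surface-
potential distance, interpolated between grid nodes. The 54 % figure is an
empirical calibration constant and is implemented as a defined constant,
not re-derived. For an exact exponential the two are tied by
depth₅₄ = −ln(0.54)·δ ≈ 0.616 δ. The electrostatic treatment is a fidelity
limitation: no frequency-dependent admittance, no wave effects, so
absolute depths are indicative while the scaling with probe size (depths
∝ probe dimensions; 2.2 < 3.6 < 6.3 mm ordering) is robust. The electric
length of the stock cable (γd = 0.17 mm) is an instrument parameter and is
not used by the solver.

## Problem sizes and determinism

Default study sizes: 100-point spectra, 12-point trajectories (100-trial
recovery studies), 512² images, the 100-sphere chain at voxel 0.5
(≈ 1.2 × 10⁷ voxels), and probe grids at cell size a/8. All generators are
seeded; the geometric models are fully deterministic, and repeated runs of
the CLI `demo` with one seed produce byte-identical reports (reports carry
no timestamps).

## Known limitations

- The exponent-placement convention is pinned to the symmetric-β /
  asymmetric-α form; data fitted elsewhere with the opposite convention
  must be relabelled before comparison.
- Absolute fractal dimensions are observation-scale dependent; every
  regime fit reports its size window and reported D values should be
  quoted with it.
- No Kramers–Kronig consistency machinery, no electrode-polarisation
  correction, no multi-temperature fitting.
- Lacunarity, multifractal spectra and grayscale box counting are out of
  scope.
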