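# Methods

## The model

`thickfil` models the half thick filament of resting vertebrate (frog)
skeletal muscle as a set of scattering spheres in cylindrical coordinates
and predicts its cylindrically averaged x-ray layer-line intensities.

**Crossbridge lattice.** Myosin crossbridges (two-headed S1 pairs) emerge in
*crowns* of three, every 14.3 nm along the backbone, on three co-axial 9/1
helical strands of pitch 129 nm (basic repeat c = 42.9 nm). Two regions are
built separately and summed coherently in reciprocal space:

- the **regular region** (distal ~215 nm) obeys the exact screw symmetry:
  40° of azimuth per 14.3 nm of rise, three-fold strand symmetry;
- the **perturbed region** (proximal ~516 nm, ~70% of the crossbridge-bearing
  length) replaces the three equal crown steps of each 42.9-nm repeat with
  axial separations (10.84, 14.94, 17.24) nm and absolute crown azimuths
  (φ₁, φ₂, φ₃) = (3°, 50°, 123°); successive repeats are stacked with +120°
  so each strand stays continuous. The consecutive azimuthal steps (47°,
  73°) are near 60°, which is what produces the pseudo-six-fold projected
  symmetry of the filament seen on the equator.

**Heads.** One head is a rigid cloud of 68 spheres of radius 0.72 nm.  A
crossbridge mounts two heads at a junction; each head may rotate by its own
angle ε about the axial direction through the junction, the pair's centre of
mass sits at helical radius r_h (9.8 nm regular, 12.7 nm perturbed by
default) at crown azimuth φ.  The head reference frame (ε = 0) has the
head's long axis tangential to the helix with the motor domain distal; this
frame is a documented convention — the fitted ε values are reproducible
conventions of this package, not absolute orientations.

**C-protein (MyBP-C).** Eleven 4-nm domains per molecule: three anchored
axially on the backbone surface (radius 7 nm), eight projecting radially
with a single 90° elbow after the fifth projecting bead, which places the
arm tip at 27 nm radius (beyond the myosin crowns, as EM tomography places
the C-protein's actin-contacting density). Three molecules per level
(three-fold symmetry), levels every 45.33 nm anchored at crown-1 levels of
the perturbed region. Each domain bead carries weight 68/11 of a head bead
so that one molecule scatters like one head (comparable molecular weight).
Projecting beads carry an axial-disorder temperature factor
exp(−4π²σ²Z²) with 2σ = 2 nm by default.

The backbone is a featureless cylinder: it is excluded from the transform
(it contributes almost nothing to the layer lines) and only enforces that
no bead sits below r = 7 nm.

## Layer-line intensities

For layer line l at Z = l/c the complex Bessel-order amplitudes are

    G_n(R) = Σ_j w_j f_j(s) exp(−4π²σ_j²Z²) J_n(2πR r_j)
             exp(i(−n φ_j + 2πZ z_j)),          s = √(R² + Z²),

with f the uniform-sphere form factor 3[sin x − x cos x]/x³, x = 2πsa, and
I_l(R) = Σ_n |G_n(R)|².  Regions are summed amplitude-wise per n before
squaring.  Numerical choices:

- Bessel truncation n_max = ⌈2πR_max r_max⌉ + 12; the discarded orders are
  verified against a direct azimuthal-average oracle to contribute < 1e-6.
- The form factor uses the full reciprocal magnitude s (beads are 3-D),
  while the temperature factor depends on Z only, as printed in the source
  formula.
- Phase convention: F(R, ψ) = Σ_n G_n i^n e^{inψ}; intensities are
  convention-independent.
- Beads sharing (r, a, σ) are grouped so each Bessel table is computed once
  per unique radius; this is what makes full-filament transforms (~21 000
  beads) take seconds.

Because the intensity is cylindrically averaged it is exactly invariant
under a global rotation of all bead azimuths.  Consequently only azimuth
*differences* between crowns are identifiable from a pattern; fits report
azimuths in the gauge of their search grid.

**Superlattice sampling.** Frog muscle packs filaments in a statistical
"no three-alike" hexagonal superlattice. One coherent unit cell (~100 nm,
matching the observed coherent diffracting length) is realised minimally as
three filaments at hexagonal sites, two at azimuthal setting 0° and one at
60°, at nearest-neighbour spacing d (43.2 nm full-overlap, 34.4 nm
overstretched). The cell transform is summed coherently over filaments and
averaged numerically over cell orientation (720 samples by default).

**Component decomposition.** With myosin amplitudes F_Mn and C-protein
amplitudes F_Cn on a common frame, I = I_M + I_C + I_cross with
I_cross = Σ_n 2 Re(F_Mn F_Cn*); the identity against the union transform
holds pointwise and |I_cross| ≤ 2√(I_M I_C).  On the default model the
C-protein share of off-meridional intensity (R > 0.0254 nm⁻¹) is ~0.01 —
small, of the order reported for the real filament, though the exact value
depends on the stand-in head shape.

## Difference-Patterson desampling

ΔQ(r,z) = Σ_{l≥1} 2 cos(2πZ_l z) ∫ I_l(R) J₀(2πRr) 2πR dR is the
cylindrically averaged autocorrelation of the deviation from the axially
averaged density; the equator is always excluded (in muscle it is dominated
by crystalline thin/thick-filament interference). Inter-filament vectors
are at least d_nn − ρ_max long, so the default borderline is the constant
r = d_nn − ρ_max (user-overridable as a polyline; the original analysis
drew this curve from a prior study and its exact coordinates are not
published — the default is a principled stand-in, flagged in metadata).
Zeroing ΔQ outside the border and back-transforming (orthogonal cosine
projection per layer line on z ∈ [0, c/2], then the self-inverse J₀ Hankel
transform) returns desampled single-filament intensities; negative outputs
are clipped at zero and the clipped fraction is reported.

Quadrature is trapezoidal throughout. Default real-space grids use 0.25-nm
steps (the pixel scale of the source data); the transform-pair identity
(round trip without cut-off ≤ 1% error) requires finer steps (0.0625 nm)
and a real-space range (60 nm) extending past the autocorrelation support,
because truncating I(R) at R_max rings in real space. The residual
"face-to-face" interference at R < 0.0254 nm⁻¹ is *not* corrected — that
region is flagged and excluded from all fitting, as in the original
analysis.

A peak at (r, z) in ΔQ maps to the crossbridge helical radius through
r = 2 r_h sin[π(z/C + 1/3)] with C = 129 nm.

## RDI and the orientation search

RDI = Σ_i ∫|I_ref,i − s_c I_obj,i| dR / Σ_i ∫ I_ref,i dR, with s_c chosen
to minimise the numerator and R < 0.0254 nm⁻¹ excluded. The source prints
the definition only as an image; the implemented form is the normalized L1
residual its text describes ("residual deviation of intensity"), recorded
here prominently because a squared-residual variant would differ. s_c is
found by golden-section search on [0, max(I_ref/I_obj)] (the L1 objective
is convex; tolerance 1e-6 relative). Zero layer lines in the reference are
dropped from both sums with a warning.

The orientation search is an exhaustive, deterministic grid product over
the configured parameter grids (ties go to the first point encountered),
honouring two constraints: (a) no bead below the backbone radius; (b) the
crown-azimuth triplet must have an equal pair or span φ₃ − φ₁ ≥ 120°
(enforcing the observed pseudo-six-fold, not nine-fold, projected
symmetry). An optional coarse-to-fine pass rebuilds the grids around the
optimum at a fraction (default 0.2) of the previous step. Results objects
carry the full score table and per-parameter 1-D sensitivity traces. Axial
head tilt is fitted separately by a bounded ±15° scan against a meridional
profile.

## Meridional cluster analysis

Reflections of a zone with repeat p appear at Z = k/p; the two mirrored
zones of the A-band (distance D apart) split each into fringes spaced 1/D.
The pipeline: (1) calibrate Z against the resting third-order myosin
meridional (14.34 nm) using the baseline-subtracted window centroid (robust
to fringe splitting of the reference itself); (2) fit each cluster window
with n Gaussians (default 3) plus a linear baseline by least squares
(`lmfit`, TRF solver), seeded at the largest local maxima with centers
tethered near their seeds and the baseline bounded to physical values —
both guards against the broad-component/sunken-baseline degeneracy of
low-noise windows; (3) per-order spacing = order / (intensity-weighted mean
peak position), averaged over orders (and replicates) with its sd; (4)
D = 1 / mean adjacent-peak separation, where components broader than 3× the
cluster's median width (envelope/baseline artefacts) are ignored and
components closer than their own widths are merged — a resolution
criterion, without which an unresolved doublet masquerades as a 1/ΔZ → ∞
fringe pair.

Default windows bracket k/p ± 0.004 nm⁻¹, clipped at the midpoint toward
the other species' same order. At order 2 the C-protein and myosin clusters
genuinely blend (their separation is comparable to the fringe spacing), so
C2-inclusive averages carry an ~1% upward bias on the mixed default
profile; on isolated single-species profiles the estimator's bias is
< 0.1%. This mirrors the original analysis' caution about the overlapping
C1/M1 region and its preference for higher orders.

## Synthetic data

No experimental intensities are distributed, so generators provide every
input with truth records:

- `synth_head`: deterministic 68-sphere kinked-pear head (motor lobe +
  lever arm), ~15 nm long, radius of gyration ~4.25 nm (within the 4–5 nm
  band of the real S1 models), mounted so the paired heads of one
  crossbridge are staggered axially — the motor lobes sit ~8 nm apart,
  reproducing the characteristic near-axial autocorrelation lobe.
- `synth_layer_lines`: forward transform (optionally superlattice-sampled)
  with multiplicative Gaussian noise (default 1%, the photon-rich
  imaging-plate regime).
- `synth_meridional`: fringe combs at the cos²(πDZ) maxima m/D, weighted by
  the |sinc|² envelope of the finite zone, each fringe a Gaussian line of
  instrumental width 2.5e-4 nm⁻¹, damped by exp(−4π²σ²Z²) with σ = 1.5 nm.
  Rendering the fringes as a comb at the cos² maxima (rather than as the
  continuous envelope × cos² product) makes adjacent intra-cluster peaks
  exactly 1/D apart in the noiseless limit; in the product form the
  envelope slope shifts the product maxima by up to ~10% of the fringe
  spacing — an effect worth noting when comparing measured interference
  distances (660 ± 70 nm) with anatomical zone separations (710–730 nm).
  Defaults are the study conditions: C-protein repeat 45.33 nm, 7 repeats
  per C-zone, two-C-zone distance 660 nm; myosin repeat 42.96 nm, 16
  repeats per half array, two-array distance 890 nm (half-filament centres
  ~445 nm either side of the M-line); amplitude ratio M:C = 3.

What the generators do *not* emulate: detector point spread, polarization
and absorption corrections, actin-based layer lines (which contaminate the
observed first myosin layer line beyond R ≈ 0.08 nm⁻¹), sampling of the
meridional reflections by the fibre tilt, and the real head shape. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated geometry and noise model, not performance on raw detector data.

## Problem sizes

Tests and the acceptance script run at desk scale by construction: reduced
bead-count heads (8–12 spheres) and 1–3 repeat filaments for search and
symmetry tests, the full 68-sphere default filament (~21 000 beads) for the
component-ratio and Patterson checks, four replicate meridional profiles
for the periodicity recoveries, and a shortened (4-repeat + 5-crown)
filament for the two-spacing superlattice comparison. These sizes are the
package's own defaults for its validation suite; all full-scale
computations remain available through the same interfaces.

## Known limitations

- The packaged head is a synthetic stand-in; all head-shape-dependent
  numbers (component ratios, Patterson peak positions, the two-spacing RDI)
  are approximate by design.
- Absolute intensity scale is arbitrary; only relative intensities enter
  RDI.
- Crown azimuths are identifiable only up to a global rotation (gauge).
- The borderline geometry is a principled constant-radius default, not the
  original hand-drawn curve.
- Meridional order-2 windows of the two species overlap; period estimates
  including order 2 on mixed profiles carry a small systematic bias.
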