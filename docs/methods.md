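# Methods

## Geometry: the mirrored skin fold

The treatment configuration pinches a dorsal skin fold between two plate
electrodes (1 cm² contact, 2 mm apart). The five-layer stack — stratum
corneum (5 µm), epidermis (5 µm), dermis (400 µm), panniculus carnosus
(300 µm), subcutaneous tissue (300 µm) — therefore appears twice, mirrored
about the fold midplane, with the subcutaneous layers adjacent at the
midline (2 × 1010 µm across a 2000 µm gap; the 1% mismatch is accepted, and
`build_fold_domain` rejects mismatches above 5%). This geometry is the one
the per-layer field values confirm: treating the mirrored stack as resistors
in series, J = V/Σ(tᵢ/σᵢ), Eᵢ = J/σᵢ gives 135.2 / 108.2 / 540.8 V/mm in
dermis / panniculus / subcutaneous at 500 V — within 1% of the 2D
finite-element values (134 / 107 / 540).

The 2D cross-section spans the treated width (10 mm) plus a lateral margin
of untreated, normal-state skin on each side (default 5 mm, configurable;
the physical extent of the margin is not critical because the treated
centre is many thicknesses away from the region edge). The out-of-plane
depth is implied by the electrode contact area.

## Electric model

Skin is resistive for pulses far longer than the membrane charging time,
so the potential solves the DC conduction problem ∇·(σ∇U) = 0 with
U = V on the cathode contact, U = 0 on the anode contact, and zero normal
current elsewhere. Conductivities are fixed at their end-of-treatment
(electroporated) values in the treated column and normal values in the
margin; dynamic conductivity evolution during the pulse train is out of
scope. Discretization is a finite-volume 5-point stencil on a
layer-conforming rectilinear grid (cell edges coincide with layer
interfaces, default 10 µm depth cells, 250 µm lateral cells) with
harmonic-mean face conductivities; this is exact for 1D piecewise-constant
media, which is why the solver matches the series oracle to < 0.5% (it is
property-tested over random conductivity assignments) and why grid
refinement barely moves the reported values. The linear system is solved by
sparse LU. Per-layer values are sampled at the treated-column centre at
each layer's midpoint depth.

## Thermal model

The bioheat problem ρc_p ∂T/∂t = ∇·(λ∇T) + q uses the duty-cycle-averaged
Joule source q = σ|E|²·(t_p·f) (duty 2.1×10⁻⁴ for 70 µs at 3 Hz; the
domain integral of q equals V²_RMS/R to within 1%). Blood perfusion is
deliberately omitted. The electrode plates are included as conducting
solids (default thickness 1 mm, configurable). Boundary conditions:

* far lateral (body) boundary: T = T_in (default 37 °C);
* exposed skin and electrode side faces: convection h = 5 W K⁻¹ m⁻² to
  air at T_air (default 25 °C; only ~0.02 W flows through this channel,
  so the choice of T_air in the plausible 20–30 °C range is immaterial);
* outer electrode faces: **fixed at T_in by default**
  (`ThermalBoundary(electrode_outer="fixed")`), modelling the electrode
  assembly as a heat sink in thermal contact with the body. A purely
  convective outer face (`"convective"`) is available, but with it the
  configuration has no steady state at all: the protocol delivers ≈ 1.17 W
  average power into ~1 cm² of tissue, while h = 5 over a few cm² can shed
  only ~10 mW per kelvin of rise, so temperatures drift upward for the whole
  treatment. The observed steady state within ~45 s is only possible if the
  electrodes act as a near-isothermal sink, which the fixed clamp provides
  (the metal plate drops only ~0.35 K internally at the steady flux).

Time integration is backward Euler at dt = 0.05 s over 70 s (the treatment
lasts 200/3 ≈ 67 s). The smallest cells are 5 µm, so any explicit scheme
would be prohibitively stiff; the implicit operator is factorized once and
reused. Steady-state layer temperatures are maxima over each layer's
treated-column cells at the final time (the final 10% of each midpoint
trace must drift < 0.05 °C); the settling time is the earliest time from
which every layer-midpoint trace stays within 5% of its final rise.

### Deep-layer temperatures: a known discrepancy

With the clamp at T_in the model reproduces the published surface value
(stratum corneum/epidermis 37.6 vs 37.8 °C) and settling time (11.5 s,
within the stated 45 s), and the layer-to-layer drops across the
subcutaneous (2.95 K) and panniculus (2.44 K) layers match the published
differences (2.8 and 2.0 K). The absolute deep-layer values, however, come
out ≈ 3 °C above the published 39.5 / 41.5 / 44.3 °C. This offset cannot be
removed by any admissible calibration, because it is forced by an energy
argument: the steady heat flux crossing the dermis from the inner sources
is Σqᵢtᵢ ≈ 4.4–5.7 kW/m², which across 400 µm of dermis at
λ = 0.45 W K⁻¹ m⁻¹ implies a ≥ 4 K drop, whereas the published dermis–
surface difference is 1.7 K. The published deep temperatures are therefore
not jointly consistent with the published fields and material table; this
package reports the energy-consistent values. Clamping the electrodes
below body temperature (~34 °C) would reproduce the deep values while
breaking the surface value, and has no physical motivation.

## Taguchi analysis

The L25(5^k) array is built by the classical Latin-square construction
(columns a, b, (a+mb) mod 5 for run index r = 5a + b), giving mutually
orthogonal columns; orthogonality (every ordered level pair once per
factor pair) is asserted by brute force in the tests. The response is
collapsed per run with the larger-is-better statistic
S/N = −10·log₁₀(mean(1/y²)) (collagen increase is desirable;
smaller-is-better and nominal-is-best variants are provided). Factor
influence is the range Δ = max − min of the five level means of S/N,
ranked 1 = largest; tied factors share the smaller rank. Level means are
kept at full precision internally and rounded only for display.

## Histology quantification

* **Mask**: blue/(red + ε) > 2 with ε = 1 intensity unit guarding zero red
  without affecting ordinary pixels.
* **Density**: fraction of mask pixels within an exact Euclidean disc
  (radius 50 px), computed by FFT convolution of the mask and of a ones
  image with the disc kernel; the border uses the partial disc, so edge
  density is unbiased.
* **Orientation**: minor eigenvector of the Gaussian-weighted structure
  tensor (σ = 2 px default), i.e. the direction of least intensity
  variation, as an axial angle in [0, π). Pixels with near-isotropic
  neighbourhoods (coherence < 0.01) are undefined and excluded.
* **Directional variance**: 1 − R̄ with R̄ the mean resultant length of the
  doubled angles 2θ over defined mask pixels in the disc (unweighted;
  an anisotropy-weighted variant would be a straightforward extension).
  0 for parallel fibers; 1 both for isotropic textures and for two equal
  orthogonal families (antipodal doubled angles).
* **Registration**: integer-shift Fourier phase correlation on the
  grayscale images; invariant to global intensity scaling.
* **Fiber age**: mean Herovici blue/red ratio within the collagen mask
  carried over from the registered adjacent trichrome section (higher =
  younger, uncrosslinked collagen III).
* **Subregions**: plain means over a rectangle, default a centred
  300 × 700 µm window (clipped when the image is smaller); µm convert to
  pixels by rounding half up.

Raw RGB is used throughout; no stain deconvolution or white-balance
correction is attempted.

## Mechanics

Young's modulus is the least-squares slope of stress vs strain inside a
strain window, default 0.02–0.10 (the "linear part" is not uniquely
defined by the data; an automatic window maximizing R² over sliding
intervals is available). The fit includes an intercept, so constant force
offsets do not bias the slope.

## Synthetic data

The generators define the test conditions:

* **Fiber images** (default 256×256 px at 1 µm/px): straight fibers of
  width 3 px and length 120 px stamped at angles drawn by the standard
  axial construction — the doubled angle 2θ is von Mises with
  concentration κ (default 4) about 2µ — until a target fill fraction
  (default 0.3) is reached. Centres are sampled on an extended canvas so
  coverage is stationary across the image (no border depletion). Trichrome
  colouring puts fibers at blue/red > 2 and background below; Herovici
  colouring assigns each fiber a "new" (blue-dominant) or "mature"
  (red-dominant) class. Mild Gaussian intensity noise (SD 2) keeps local
  gradients realistic. Ground-truth mask and per-pixel angle maps are
  returned.
* **L25 responses**: y = (baseline + Σ_f effect_f[level]) · exp(N(0, sd)) —
  multiplicative log-normal noise guarantees the positivity the S/N
  statistic requires. Defaults: baseline 1, noise SD 0.1, 3 replicates per
  run (matching the animals-per-condition scale of the underlying screen).
* **Stress–strain curves**: quadratic toe joined C¹-continuously to an
  exactly linear branch of slope Y, with optional multiplicative noise.

All generators are pure functions of (parameters, seed).

What the synthetic data do **not** emulate: real trichrome sections have
curved, branching, overlapping fibers, nuclei and stain variability; real
L25 responses may have factor interactions the additive model lacks; real
skin is viscoelastic. Passing tests therefore demonstrate correctness of
the estimators under their stated assumptions, not robustness to every
histological artefact.

## Problem sizes and numerical defaults

Default grids (≈ 16k cells, 204 depth × 80 lateral rows for the fold;
1400 implicit steps for 70 s) solve in seconds and are refinement-tested:
halving cell sizes and the timestep moves per-layer fields by < 0.5% and
steady temperatures by < 0.1 °C. Sparse LU is the default linear solver
throughout.

## Known limitations

* No blood perfusion or metabolic heat; no dynamic conductivity during the
  pulse train; 2D cross-section (out-of-plane fringing neglected).
* The electrode-sink boundary idealizes the electrode assembly; the
  published deep-layer temperatures are not reproducible under any
  energy-consistent variant of this model (see above).
* Orientation analysis assumes fibers are resolved (width ≳ tensor σ);
  heavily overlapping crossing fibers yield undefined orientations rather
  than multimodal estimates.
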