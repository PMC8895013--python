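# Methods

## Model overview

`gridhar` refines crystal-structure models against single-crystal X-ray
intensities using aspherical atomic form factors obtained from a
Hirshfeld-partitioned unit-cell electron density sampled on a rectangular
periodic grid. Every atom is split into a frozen spherical core and an
aspherical valence part:

* **Core**: a radial density ρ_c(r) tabulated on an exponential grid,
  transformed once per refinement by the Fourier–Bessel integral
  f_c(s) = ∫ 4πr²ρ_c(r)·sin(Qr)/(Qr) dr with Q = 4πs. The core is fully
  assigned to its atom and excluded from the stockholder weights.
* **Valence**: the cell's valence density is divided at every grid point
  by the stockholder shares w_A = ρ_A^pro/Σ_B ρ_B^pro of spherical
  valence-only pro-atoms, then each atomic grid is Fourier transformed
  (crystallographic convention, kernel e^{+2πi h·r}) with the FFT and
  recentred by e^{−2πi h·x_A}.

Structure factors sum the P1 expansion of the asymmetric unit. A symmetry
image generated by (R, t) contributes its generator's displacement and
Gram–Charlier tensors contracted with the rotated index h_s = Rᵀh and the
phase e^{2πi h·t}; the image's form factors come from its own partitioned
grid, which is equivalent to evaluating the generator's set at h_s when
the density respects the symmetry.

## Least squares

The objective is Σ w (Fo² − k·Fc²)² with fixed weights w = 1/σ² — the
same minimizer as wR2(F²); no weighting scheme is ever refined. The scale
k is eliminated in closed form at every evaluation
(k = Σw·Fo²·Fc² / Σw·(Fc²)²), which removes the scale–U_iso degeneracy
direction from the optimizer and, by the envelope theorem, contributes
nothing to the gradient. Gradients of every parameter class — positions,
isotropic/anisotropic U, third/fourth-order Gram–Charlier components,
extinction — are analytic; the test suite verifies them against 5-point
central finite differences (step 3·10⁻⁶, which keeps both truncation and
round-off below 10⁻⁵ relative for the steep quartic Gram–Charlier terms).

Optimization uses BFGS (scipy) with convergence declared when the maximum
absolute parameter shift falls below 10⁻⁶ (fractional coordinates and Å²
share this scale, matching the shift conventions of standard refinement
software). Site-symmetry constraints are linear reparameterizations: for
each atom the refinable subspace is the null space of (T − I) where T is
the site group's averaged representation on the block (positions, the six
U components via the contravariant N·U·N transform, the 10/15 unique
Gram–Charlier components). An atom on an inversion centre therefore has
no positional parameters at all, and its odd (third-order) tensor is
identically zero; the parameter count stays honest, with no penalty terms.

The outer HAR loop regenerates the density, partition, and form factors
from the current geometry, then re-runs the least squares; form factors
are held fixed *within* each inner refinement while the recentring phases
always use current positions. The loop stops when the largest parameter
shift between outer cycles drops below 10⁻⁵, and flags oscillation when
shifts grow over three consecutive cycles. `max_har_cycles = 0` degrades
to an IAM refinement using the source's spherical core+valence radial
transforms directly — the reduction path used to cross-check against
plain spherical refinement.

Extinction uses the squared-intensity form of the SHELXL Fc* convention,
Fc²_corr = Fc²·[1 + 0.001·x·Fc²·λ³/sin 2θ]^{−1/2}, refined on the
intensity scale together with k; reflections at zero scattering angle are
left uncorrected.

In P1 the objective is invariant under rigid translation of the whole
model (|Fc| is origin-free), so polar-cell refinements pin the origin by
fixing one atom's coordinates (`fixed_position_atoms`); centrosymmetric
test cells need no anchor.

## Grids and numerics

* **Spacing ladder**: a nominal wavefunction-level spacing h (default
  0.2 Å) places the valence-density grid at h/2; the form-factor FFT runs
  on a grid Fourier-interpolated ×2 from it (h/4). Fourier interpolation
  zero-pads the spectrum, so the grid integral is preserved exactly and
  band-limited fields are reproduced exactly at the new points.
  Partitioning happens at the finest (form-factor) grid.
* **Nyquist guard**: requesting a reflection beyond the FFT Nyquist index
  of the grid raises an error naming the offending index.
* **Radial quadrature**: exponential grid r ∈ [10⁻⁶, 30] Å with 2¹³+1
  points by default, integrated by composite Simpson; this reproduces the
  hydrogenic 1s form factor to ~10⁻¹² absolute, far inside the 10⁻⁶
  target, without needing the much denser grids a trapezoid rule would
  require. The range and point count are configurable.
* **Promolecule lattice sums**: periodic images of a pro-atom are added
  until its radial density falls below 10⁻¹⁰ e·Å⁻³; images up to
  ceil(r_cut·a*_i) beyond minimal image are scanned per axis, which covers
  skew cells, and each image is pruned to its bounding sub-box before the
  metric is evaluated. The truncation leaves a relative form-factor floor
  of order 10⁻¹¹, far below grid discretization error.
* **Stockholder floor**: grid points where the promolecule falls below
  10⁻³⁰ e·Å⁻³ are assigned to no atom (the density there is numerically
  zero anyway).

## Synthetic density sources

The generator stands in for a periodic electronic-structure engine and
defines the study conditions of every test:

* **Element shells**: per-element Gaussian shells (electrons, exponent) —
  H: 1e⁻ valence (α = 2.2 Å⁻²); C/N/O: a 2-electron tight core
  (α = 60–100 Å⁻²) plus two valence shells (α ≈ 0.5–2.0 Å⁻²). These are
  documented modelling constants with realistic length scales, not fitted
  atomic densities; their closed-form transforms f(Q) = Σnᵢe^{−Q²/4αᵢ}
  make every Fourier stage exactly checkable.
* **Spherical promolecule source**: valence grid = superposition of the
  valence shells; with this source the aspherical machinery must
  reproduce spherical results (recentred valence form factors real to
  10⁻⁶).
* **Dipolar deformation source**: per flagged bond, adds
  δρ(r) = p·(û·d)·(β/π)^{3/2}e^{−β|d|²} to the donor atom (d = r − x_A,
  û the unit bond vector, defaults β = 4 Å⁻², p ≈ 1 e·Å⁻¹). The term
  integrates to zero (electron count conserved) and shifts the atom's
  density centroid by p/(2β·n_val) Å along the bond — 0.125 Å at the
  defaults, the scale of real X–H foreshortening. Densities driven
  negative beyond tolerance trigger a warning.
* **Simulated data**: Fo² = k_true·Fc²·(1+η·ξ), ξ ~ N(0,1) seeded,
  σ = η·k_true·Fc² + 0.01·median(Fo²). The σ floor intentionally deflates
  (Fo²−kFc²)/σ for the weakest reflections; the multiplicative part is
  calibrated to unit variance. Toy structures (diatomic and bent
  triatomic in P1, an N–H pair in P-1, and a centrosymmetric cell with an
  atom pinned on the inversion centre) use cells of 6–12 Å, resolution
  limits of 0.75–0.9 Å, and ADPs of 0.01–0.03 Å² — ordinary small-molecule
  low-temperature values. All generators are pure functions of
  (spec, seed).

What the synthetic sources do **not** emulate: self-consistent response
of the density to the crystal field, core polarization, absorption,
thermal diffuse scattering, or counting-statistics error models. Passing
tests therefore demonstrate the correctness of the partition/FFT/least-
squares machinery and the *mechanism* of the aspherical H correction, not
the physics of any particular density functional.

## Validation metrics

Reference (e.g. neutron) ADPs are corrected before comparison by the
one-scale-one-offset fit U_x ≈ q·U_n + ΔU over paired non-H atoms,
solved as a linear least squares in the Cartesian frame with Frobenius
weighting (off-diagonals √2); q absorbs temperature differences, ΔU
common offsets. At least three pairs are required (7 unknowns); the fit
is exact on exactly-related inputs. The Cartesian frame is a deliberate
choice — the fit is frame-dependent and the convention is stated rather
than implied.

S12 = 100·[1 − 2^{3/2}(det U₁⁻¹ det U₂⁻¹)^{1/4}/det(U₁⁻¹+U₂⁻¹)^{1/2}]
is the percent dissimilarity of the two Gaussian probability densities;
it is symmetric, zero iff the matrices coincide, rotation invariant, and
matches direct 3-D quadrature of 100·(1−∫√(p₁p₂)dV) to the tested 10⁻⁴.

Hydrogen atoms are grouped into C–H and intra-/inter-fragment X–H⋯Y
classes (X, Y ∈ {N, O}) using configurable geometric cutoffs — H⋯Y <
2.5 Å and X–H⋯Y angle > 120°, with the covalent partner the nearest
non-H atom within 1.3 Å. These cutoffs are modelling choices, logged and
overridable. Fragments default to connected covalent components within
the cell; callers with chemically meaningful fragments (the usual case in
periodic work) pass them explicitly. N/O-bound hydrogens that donate no
classical hydrogen bond fit none of the three classes and are excluded
with a warning rather than misfiled. Class summaries report medians and
quartiles in the inclusive (median-unbiased) convention with 1.5×IQR
whisker bounds, plus the mean of σ-scaled absolute deviations when
reference uncertainties are supplied.

## Design choices and limitations

* Reflections are refined exactly as given — no merging of symmetry
  equivalents (an inverse-variance merge utility exists but is opt-in),
  and the F/σ(F) significance cut (applied as Fo²/σ(Fo²) ≥ t² on
  intensity data, with non-positive Fo² removed at t > 0) is applied once,
  before refinement.
* Γ-point semantics only: the density source contract has no k-point
  mesh; a Brillouin-zone-integrated density can still be supplied through
  the same grid interface by the engine adapter.
* No estimated standard deviations on refined parameters yet
  (inverse-Hessian s.u.'s are a natural extension), no twinning,
  disorder, anomalous dispersion, restraints, or absorption handling.
* Gram–Charlier refinement does not police the positivity of the
  resulting probability density function; strongly negative regions show
  up only through the warning on non-PSD U matrices.
* The CIF layer reads explicit symmetry operator lists only — no
  Hall/Hermann–Mauguin symbol interpretation.
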