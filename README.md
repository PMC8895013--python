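# gridhar

Hirshfeld atom refinement (HAR) driven by unit-cell electron densities on
rectangular periodic grids — for quantum crystallographers who want
aspherical atomic form factors from *any* density source that can deliver a
valence density on a grid, and for method developers who need every stage
of the pipeline testable without an electronic-structure engine.

## What it does

Conventional X-ray refinement uses the independent atom model (IAM):
spherical, isolated-atom form factors. That systematically mislocates
hydrogen atoms, because the bonding density shifts the electron-density
centroid of H away from the proton. HAR fixes this by partitioning a
theoretical crystal density into aspherical atomic densities and refining
against form factors derived from them, iterating as the geometry moves.

`gridhar` implements the grid variant of the scheme:

1. **Partition** — the unit-cell *valence* density ρ(r), sampled at the
   points (i/n₁, j/n₂, k/n₃), is divided among atoms by Hirshfeld
   stockholder weights w_A = ρ_A^pro / Σ_B ρ_B^pro built from spherical
   pro-atom densities. Frozen-core densities stay out of both the
   partitioned density and the weights; each atom keeps its core in full.
2. **Form factors** — per-atom valence densities go through the FFT,
   f_A(h) = V·IFFT[ρ_A](h)·e^(−2πi h·x_A), the phase shift giving
   atom-centred values; core form factors come from a Fourier–Bessel
   transform of the radial core density on an exponential grid.
3. **Refinement** — structure factors
   Fc(h) = Σ occ·f(h)·T(h)·GC(h)·e^(2πi h·x) (harmonic temperature factor
   T, optional third/fourth-order Gram–Charlier multiplier GC, optional
   SHELXL-convention extinction) are fitted to Fo² by minimizing
   wR2(F²) = √[Σw(Fo²−k·Fc²)²/Σw(Fo²)²], w = 1/σ², with analytic
   gradients, BFGS, and linear site-symmetry constraints. The density and
   form factors are refreshed each outer cycle.
4. **Validation** — H-atom quality indicators against a reference
   structure: signed/absolute X–H bond-length differences Δr, ΔU_ij after
   Blessing scaling U_x ≈ q·U_n + ΔU of the reference ADPs, the percent
   ellipsoid dissimilarity S12, and aggregation into C–H / intra / inter
   X–H⋯Y bond classes.

A synthetic density source (spherical promolecule, optionally with
bond-directed dipolar deformations that shift an atom's density centroid
by a closed-form amount) replaces the external periodic-DFT engine, so the
whole pipeline runs self-contained; plugging in a real engine only
requires implementing the three-method `DensitySource` contract.

## Worked example

`examples/03_har_vs_iam.py` simulates a C–H crystal whose H valence
density carries a dipolar bonding deformation (centroid pulled 0.125 Å
toward C), adds 2 % noise, and refines the same data twice:

```
959 reflections, 2% multiplicative noise
HAR (aspherical source):  wR2 = 1.96%  |Δr(H)| = 0.0033 Å
spherical refinement:     wR2 = 2.59%  |Δr(H)| = 0.2584 Å
closed-form centroid shift of the deformed H density: 0.1250 Å
```

The spherical model parks the proton near the density centroid — off by
roughly twice the centroid shift once the least squares balances the whole
deformation — while iterative HAR with the matching source recovers the
generating position to a few mÅ. The other examples cover the form-factor
oracle, plain IAM recovery, and the validation metrics.

## Command line

```sh
gridhar simulate --kind diatomic_P1 --dmin 0.9 --out-prefix toy
gridhar refine   --cif toy.cif --hkl toy.hkl --out-prefix iam
gridhar har      --cif toy.cif --hkl toy.hkl --source aspherical --out-prefix har
gridhar validate --refined har.cif --reference toy.cif
```

Input formats: CIF (cell, explicit symmetry operators, atom sites, aniso
U, Gram–Charlier loops) and SHELX HKLF4 `.hkl` (h k l Fo² σ, fixed width);
outputs are refined CIF, fcf-style reflection listing, and a JSON log.

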