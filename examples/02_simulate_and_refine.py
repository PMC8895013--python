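"""Simulate diffraction data and refine the model back (IAM route).

Builds a centrosymmetric N-H toy crystal, simulates noise-free intensities
from the spherical synthetic density source, displaces the model, and runs
the constrained least-squares refinement.
"""

import numpy as np

from gridhar import RefinementSettings, refine_lsq
from gridhar.crystal import frac_to_cart
from gridhar.density import SphericalPromoleculeSource, form_factors_from_source
from gridhar.synthetic import SimulationSpec, make_toy_structure, simulate_reflections

structure = make_toy_structure("inversion_pair_P-1")
source = SphericalPromoleculeSource()
spec = SimulationSpec(kind="inversion_pair_P-1", d_min=0.9)
reflections = simulate_reflections(structure, source, spec)
print(f"simulated {len(reflections)} reflections to d_min = {spec.d_min} Å")

start = structure.copy()
start.atom("N1").frac_pos = start.atom("N1").frac_pos + [0.004, -0.003, 0.005]
start.atom("H1").frac_pos = start.atom("H1").frac_pos + [-0.005, 0.004, 0.003]

ff = form_factors_from_source(structure, source, reflections.hkl)
result = refine_lsq(start, reflections, ff, RefinementSettings())

print(f"wR2(F²) after refinement: {result.wr2:.2e}  (scale k = {result.scale:.4f})")
for atom, truth in zip(result.structure.atoms, structure.atoms):
    d = np.linalg.norm(frac_to_cart(atom.frac_pos - truth.frac_pos, structure.cell))
    print(f"  {atom.label}: distance to generating position {d:.2e} Å")
print("\nNoise-free data plus an exact model: the refinement returns to the")
print("generating parameters and the weighted residual vanishes.")
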