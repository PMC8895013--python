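"""Iterative HAR against a spherical-atom refinement of the same data.

The simulated C-H crystal carries a dipolar bonding deformation on the H
valence density (its centroid is pulled toward C).  Refining with the
matching aspherical source recovers the true proton position; the
spherical model instead parks H near the density centroid — the classic
X-H foreshortening that aspherical form factors remove.
"""

import numpy as np

from gridhar import RefinementSettings, har_iterate
from gridhar.crystal import expand_to_p1, frac_to_cart
from gridhar.density import (
    AsphericalDeformationSource,
    BondDeformation,
    SphericalPromoleculeSource,
)
from gridhar.synthetic import SimulationSpec, make_toy_structure, simulate_reflections

structure = make_toy_structure("diatomic_P1")
aspherical = AsphericalDeformationSource([BondDeformation("H1", "C1", p=1.0)])
spherical = SphericalPromoleculeSource()

spec = SimulationSpec(kind="diatomic_P1", d_min=0.9, noise=0.02, seed=1)
reflections = simulate_reflections(structure, aspherical, spec)

start = structure.copy()
start.atom("H1").frac_pos = start.atom("H1").frac_pos + [0.003, -0.002, 0.002]
settings = RefinementSettings(fixed_position_atoms=("C1",), max_har_cycles=5)

res_har = har_iterate(start, reflections, aspherical, settings)
res_sph = har_iterate(start, reflections, spherical, settings)

cell = structure.cell
truth = structure.atom("H1").frac_pos
d_har = np.linalg.norm(frac_to_cart(res_har.structure.atom("H1").frac_pos - truth, cell))
d_sph = np.linalg.norm(frac_to_cart(res_sph.structure.atom("H1").frac_pos - truth, cell))
p1 = [a for a, _ in expand_to_p1(structure)]
shift = aspherical.centroid_shifts(p1, cell)["H1"]

print(f"{len(reflections)} reflections, 2% multiplicative noise")
print(f"HAR (aspherical source):  wR2 = {100*res_har.wr2:.2f}%  |Δr(H)| = {d_har:.4f} Å")
print(f"spherical refinement:     wR2 = {100*res_sph.wr2:.2f}%  |Δr(H)| = {d_sph:.4f} Å")
print(f"closed-form centroid shift of the deformed H density: {np.linalg.norm(shift):.4f} Å")
print("\nThe spherical model mislocates H by roughly the centroid shift of")
print("its bonding density; the iterative aspherical refinement does not.")
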