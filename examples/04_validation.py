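"""H-atom quality indicators between two structure models.

Compares a 'refined' structure against a reference copy with a displaced
hydrogen and rescaled displacement parameters: Δr per X-H bond, the
Blessing (q, ΔU) scaling of the reference ADPs, and the S12 ellipsoid
dissimilarity.
"""

import numpy as np

from gridhar.crystal import Atom, CrystalStructure, SymmetryOp, UnitCell
from gridhar.validation import quality_report

cell = UnitCell(9, 9, 9)
o1 = np.array([0.30, 0.50, 0.50])
atoms = [
    Atom("O1", "O", o1, adp=np.array([0.010, 0.012, 0.011, 0.001, -0.001, 0.002])),
    Atom("C1", "C", [0.50, 0.72, 0.50], adp=np.array([0.013, 0.009, 0.012, -0.002, 0.001, 0.001])),
    # N1 accepts a near-linear O1-H1...N1 hydrogen bond (H...N ≈ 2.0 Å)
    Atom("N1", "N", [0.62, 0.45, 0.50], adp=np.array([0.011, 0.011, 0.010, 0.002, 0.002, -0.001])),
    Atom("H1", "H", o1 + [0.96 / 9, 0, 0],
         adp=np.array([0.030, 0.025, 0.028, 0.002, 0.001, -0.001])),
]
refined = CrystalStructure(cell, [SymmetryOp.identity()], atoms)

# reference: H shifted 8 mÅ along the bond, all ADPs scaled by 1/1.05
reference = refined.copy()
reference.atom("H1").frac_pos = reference.atom("H1").frac_pos + [0.008 / 9, 0, 0]
for atom in reference.atoms:
    atom.adp = atom.adp / 1.05

report = quality_report(refined, reference)
print(report.to_text())
print(f"\nrecovered ADP scale q = {report.adp_fit.q:.4f} (constructed: 1.05)")
print("Δr is the signed X-H bond-length difference refined − reference;")
print("S12 = 0 means identical displacement ellipsoids after q/ΔU scaling.")
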