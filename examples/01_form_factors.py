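"""Grid-based atomic form factors against their closed form.

Places a Gaussian model atom in a cubic cell, samples its density on a
periodic grid, Fourier-interpolates to the form-factor grid, and compares
the FFT + phase-shift form factors with the analytic Gaussian transform.
"""

import numpy as np

from gridhar import UnitCell
from gridhar.density import (
    DensityGrid,
    GaussianShellDensity,
    atom_on_grid,
    grid_form_factor,
    interpolate_grid,
    shape_for_spacing,
)
from gridhar.reflections import resolution

cell = UnitCell(10, 10, 10)
shells = GaussianShellDensity([(6.0, 10.0)])  # 6 electrons, α = 10 Å⁻²
pos = np.array([0.25, 0.60, 0.10])

shape = shape_for_spacing(cell, 0.2)  # density grid
rho = atom_on_grid(shells, pos, cell, shape)
grid = interpolate_grid(DensityGrid(rho, cell), 2)  # form-factor grid

hkl = np.array([(h, 0, 0) for h in range(1, 13)] + [(3, 4, 1), (5, 5, 2)])
f = grid_form_factor(grid, pos, hkl)
f_exact = shells.form_factor(resolution(hkl, cell))

print(f"density grid {shape} -> form-factor grid {grid.shape}")
print(f"electrons on grid: {grid.integral():.6f} (exact: 6)")
print(" h  k  l    f_grid      f_exact     rel.err")
for h, fg, fe in zip(hkl, f.real, f_exact):
    print(f"{h[0]:2d} {h[1]:2d} {h[2]:2d}  {fg:9.6f}  {fe:9.6f}  {abs(fg-fe)/fe:.2e}")
print("\nThe FFT pathway reproduces the analytic transform to the grid's")
print("aliasing limit; the remaining error shrinks with finer spacing.")
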