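"""Radial transforms, grids, Hirshfeld partitioning, synthetic sources."""

import numpy as np
import pytest

import gridhar.density as gd
from gridhar.crystal import Atom, CrystalStructure, SymmetryOp, UnitCell, frac_to_cart
from gridhar.density import (
    AsphericalDeformationSource,
    BondDeformation,
    DensityGrid,
    GaussianShellDensity,
    SphericalDensity,
    SphericalPromoleculeSource,
    fourier_bessel_ff,
    grid_form_factor,
    hirshfeld_partition,
    interpolate_grid,
    make_radial_grid,
    promolecule_on_grid,
    shape_for_spacing,
)
from gridhar.reflections import resolution


class TestFourierBessel:
    def test_f_at_zero_is_electron_count(self):
        sd = GaussianShellDensity([(6.0, 1.2), (2.0, 40.0)]).tabulate()
        assert fourier_bessel_ff(sd, 0.0) == pytest.approx(8.0, abs=1e-8)

    def test_gaussian_closed_form(self):
        shells = GaussianShellDensity([(5.0, 2.0)])
        sd = shells.tabulate()
        s = np.linspace(0.0, 1.2, 25)
        assert np.allclose(
            fourier_bessel_ff(sd, s), shells.form_factor(s), atol=1e-8
        )

    def test_hydrogenic_1s(self):
        zeta = 2.3  # Å⁻¹
        r = make_radial_grid()
        sd = SphericalDensity(r, zeta**3 / np.pi * np.exp(-2 * zeta * r), 1.0)
        s = np.linspace(0.0, 1.5, 31)
        q = 4 * np.pi * s
        exact = (1 + (q / (2 * zeta)) ** 2) ** -2
        assert np.max(np.abs(fourier_bessel_ff(sd, s) - exact)) < 1e-6

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            SphericalDensity(np.array([1.0, 0.5, 2.0]), np.zeros(3), 1.0)


class TestPromolecule:
    def test_single_atom_integral(self):
        cell = UnitCell(10, 10, 10)
        shells = GaussianShellDensity([(6.0, 1.2)])
        shape = shape_for_spacing(cell, 0.1)
        total, per_atom = promolecule_on_grid(
            [Atom("C1", "C", [0.3, 0.4, 0.5])], {"C": shells}, cell, shape
        )
        assert total.integral() == pytest.approx(6.0, rel=1e-3)
        assert len(per_atom) == 1

    def test_lattice_translation_periodicity(self):
        cell = UnitCell(6, 7, 8)
        shells = GaussianShellDensity([(1.0, 2.2)])
        shape = (24, 28, 32)
        a = promolecule_on_grid([Atom("H1", "H", [0.2, 0.3, 0.4])], {"H": shells}, cell, shape)[0]
        b = promolecule_on_grid([Atom("H1", "H", [1.2, -0.7, 0.4])], {"H": shells}, cell, shape)[0]
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_additivity(self):
        cell = UnitCell(8, 8, 8)
        shells = {"C": GaussianShellDensity([(4.0, 1.2)]), "O": GaussianShellDensity([(6.0, 2.0)])}
        shape = (32, 32, 32)
        atoms = [Atom("C1", "C", [0.2, 0.2, 0.2]), Atom("O1", "O", [0.6, 0.6, 0.6])]
        total, per_atom = promolecule_on_grid(atoms, shells, cell, shape)
        assert np.allclose(total.values, per_atom[0] + per_atom[1], atol=1e-14)
        single = promolecule_on_grid(atoms[:1], shells, cell, shape)[0]
        assert np.allclose(per_atom[0], single.values, atol=1e-14)

    def test_missing_element_errors(self):
        with pytest.raises(KeyError):
            promolecule_on_grid(
                [Atom("N1", "N", [0, 0, 0])], {"C": GaussianShellDensity([(4, 1)])},
                UnitCell(6, 6, 6), (12, 12, 12),
            )


class TestHirshfeldPartition:
    def _setup(self):
        cell = UnitCell(8, 8, 8)
        shells = {"C": GaussianShellDensity([(4.0, 1.2)]), "O": GaussianShellDensity([(6.0, 2.0)])}
        atoms = [Atom("C1", "C", [0.25, 0.25, 0.25]), Atom("O1", "O", [0.65, 0.65, 0.65])]
        total, per_atom = promolecule_on_grid(atoms, shells, cell, (30, 30, 30))
        return total, per_atom

    def test_partition_of_promolecule_recovers_proatoms(self):
        total, per_atom = self._setup()
        parts = hirshfeld_partition(total, per_atom)
        for part, pro in zip(parts, per_atom):
            assert np.allclose(part.values, pro, atol=1e-12)

    def test_conservation(self):
        total, per_atom = self._setup()
        valence = DensityGrid(total.values * 1.17, total.cell)  # arbitrary field
        parts = hirshfeld_partition(valence, per_atom)
        live = np.sum(per_atom, axis=0) > gd.HIRSHFELD_EPS
        reconstructed = np.sum([p.values for p in parts], axis=0)
        assert np.max(np.abs(reconstructed - valence.values)[live]) < 1e-10

    def test_single_atom_cell_gets_everything(self):
        cell = UnitCell(8, 8, 8)
        atoms = [Atom("O1", "O", [0.5, 0.5, 0.5])]
        shells = {"O": GaussianShellDensity([(6.0, 2.0)])}
        total, per_atom = promolecule_on_grid(atoms, shells, cell, (30, 30, 30))
        parts = hirshfeld_partition(total, per_atom)
        assert np.allclose(parts[0].values, total.values, atol=1e-14)

    def test_shape_mismatch_errors(self):
        total, per_atom = self._setup()
        with pytest.raises(ValueError):
            hirshfeld_partition(total, [np.zeros((4, 4, 4))])


class TestGridFormFactor:
    def test_f000_is_electron_count(self):
        cell = UnitCell(9, 9, 9)
        shells = GaussianShellDensity([(6.0, 1.5)])
        shape = shape_for_spacing(cell, 0.15)
        rho = gd.atom_on_grid(shells, [0.4, 0.1, 0.7], cell, shape)
        f = grid_form_factor(DensityGrid(rho, cell), [0.4, 0.1, 0.7], [(0, 0, 0)])
        assert f[0].real == pytest.approx(6.0, rel=1e-4)
        assert abs(f[0].imag) < 1e-12

    def test_gaussian_atom_matches_analytic_transform(self):
        cell = UnitCell(10, 10, 10)
        shells = GaussianShellDensity([(6.0, 10.0)])
        pos = np.array([0.23, 0.57, 0.11])
        shape = shape_for_spacing(cell, 0.1)
        rho = gd.atom_on_grid(shells, pos, cell, shape)
        grid = DensityGrid(rho, cell)
        hkl = np.array([(h, k, l) for h in range(-12, 13) for k in (0, 3, 7) for l in (0, 2)])
        hkl = hkl[np.any(hkl != 0, axis=1)]
        s = resolution(hkl, cell)
        keep = s <= 0.8
        f = grid_form_factor(grid, pos, hkl[keep])
        fa = shells.form_factor(s[keep])
        assert np.max(np.abs(f - fa) / np.abs(fa)) < 1e-3
        assert np.max(np.abs(f.imag)) < 1e-6

    def test_translation_covariance(self):
        cell = UnitCell(8, 8, 8)
        shells = GaussianShellDensity([(4.0, 3.0)])
        hkl = [(1, 0, 0), (2, 3, 1), (-4, 2, 2)]
        shape = (40, 40, 40)
        f_ref = None
        for pos in ([0.1, 0.2, 0.3], [0.475, 0.85, 0.05]):
            rho = gd.atom_on_grid(shells, pos, cell, shape)
            f = grid_form_factor(DensityGrid(rho, cell), pos, hkl)
            if f_ref is None:
                f_ref = f
            else:
                assert np.allclose(f, f_ref, atol=1e-10)

    def test_nyquist_violation_names_index(self):
        grid = DensityGrid(np.ones((8, 8, 8)), UnitCell(5, 5, 5))
        with pytest.raises(ValueError, match=r"\(5, 0, 0\)"):
            grid_form_factor(grid, [0, 0, 0], [(5, 0, 0)])


class TestInterpolation:
    def test_factor_one_identity(self):
        grid = DensityGrid(np.random.default_rng(0).random((6, 6, 6)), UnitCell(5, 5, 5))
        out = interpolate_grid(grid, 1)
        assert np.array_equal(out.values, grid.values)

    def test_integral_preserved(self):
        grid = DensityGrid(np.random.default_rng(1).random((10, 12, 8)), UnitCell(5, 6, 7))
        out = interpolate_grid(grid, 3)
        assert out.integral() == pytest.approx(grid.integral(), abs=1e-12)

    def test_band_limited_field_reproduced_exactly(self):
        cell = UnitCell(5, 5, 5)
        n = 12
        idx = np.arange(n) / n
        x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
        field = 1.0 + np.cos(2 * np.pi * (2 * x + y)) + np.sin(2 * np.pi * (z - x))
        out = interpolate_grid(DensityGrid(field, cell), 2)
        m = np.arange(2 * n) / (2 * n)
        xf, yf, zf = np.meshgrid(m, m, m, indexing="ij")
        want = 1.0 + np.cos(2 * np.pi * (2 * xf + yf)) + np.sin(2 * np.pi * (zf - xf))
        assert np.allclose(out.values, want, atol=1e-12)


class TestSyntheticSources:
    def test_spherical_source_gives_real_recentred_f(self, sph_source, diatomic):
        structure, reflections = diatomic
        ff = gd.form_factors_from_source(structure, sph_source, reflections.hkl[:50])
        assert np.max(np.abs(ff.f_valence.imag)) < 1e-6

    def test_zero_deformation_matches_spherical(self, sph_source):
        structure_atoms = [
            Atom("C1", "C", [0.3, 0.4, 0.35]),
            Atom("H1", "H", [0.48, 0.4, 0.35]),
        ]
        cell = UnitCell(6, 7, 8)
        shape = (24, 28, 32)
        src0 = AsphericalDeformationSource([BondDeformation("H1", "C1", p=0.0)])
        a = src0.valence_grid(structure_atoms, cell, shape)
        b = sph_source.valence_grid(structure_atoms, cell, shape)
        assert np.allclose(a.values, b.values, atol=1e-14)

    def test_deformation_conserves_electrons_and_shifts_centroid(self):
        # quadrature oracle: centroid of the deformed atom density vs the
        # closed-form first moment p/(2β·n_val)
        cell = UnitCell(10, 10, 10)
        atoms = [Atom("H1", "H", [0.5, 0.5, 0.5]), Atom("C1", "C", [0.5 + 2.5 / 10, 0.5, 0.5])]
        src = AsphericalDeformationSource([BondDeformation("H1", "C1", p=0.8)])
        shape = shape_for_spacing(cell, 0.08)
        sph = SphericalPromoleculeSource()
        grid_def = src.valence_grid(atoms, cell, shape)
        grid_sph = sph.valence_grid(atoms, cell, shape)
        assert grid_def.integral() == pytest.approx(grid_sph.integral(), abs=1e-8)
        # isolate the H deformation and integrate its first moment
        delta = grid_def.values - grid_sph.values
        axes = [np.arange(n) / n for n in shape]
        xg, yg, zg = np.meshgrid(*axes, indexing="ij")
        dv = cell.volume / np.prod(shape)
        moment_x = np.sum(delta * (xg - 0.5) * 10.0) * dv  # Cartesian x, Å
        n_val = 1.0
        want = src.centroid_shifts(atoms, cell)["H1"]
        assert want[0] == pytest.approx(0.8 / (2 * 4.0 * n_val))
        assert moment_x / n_val == pytest.approx(want[0], rel=0.01)

    def test_excessive_deformation_warns(self):
        cell = UnitCell(8, 8, 8)
        atoms = [Atom("H1", "H", [0.5, 0.5, 0.5]), Atom("C1", "C", [0.7, 0.5, 0.5])]
        src = AsphericalDeformationSource([BondDeformation("H1", "C1", p=8.0)])
        with pytest.warns(UserWarning, match="density"):
            src.valence_grid(atoms, cell, (32, 32, 32))


class TestGridSerialization:
    def test_hdf5_round_trip(self, tmp_path):
        grid = DensityGrid(
            np.random.default_rng(3).random((8, 10, 12)),
            UnitCell(6, 7, 8, 85, 92, 100),
        )
        path = tmp_path / "grid.h5"
        gd.save_grid(path, grid)
        back = gd.load_grid(path)
        assert np.array_equal(back.values, grid.values)
        assert back.cell == grid.cell


class TestFormFactorAssembly:
    def test_f000_sums_to_cell_electron_count(self, sph_source, diatomic):
        structure, _ = diatomic
        ff = gd.form_factors_from_source(structure, sph_source, [(0, 0, 0), (1, 0, 0)])
        total = np.sum(ff.total[:, ff.column((0, 0, 0))])
        assert total.real == pytest.approx(7.0, rel=1e-3)  # C (6) + H (1)
        assert abs(total.imag) < 1e-10

    def test_spherical_grid_route_matches_radial_route(self, sph_source, diatomic):
        # assembled grid form factors against a single Fourier–Bessel
        # transform of the same core+valence radial density
        structure, reflections = diatomic
        hkl = reflections.hkl[:40]
        ff_grid = gd.form_factors_from_source(structure, sph_source, hkl)
        ff_rad = gd.spherical_form_factors(structure, sph_source, hkl)
        assert np.allclose(ff_grid.total, ff_rad.total, rtol=2e-3, atol=2e-3)
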