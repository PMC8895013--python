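"""CIF reading and writing for crystal structures (built on gemmi).

Core items only: cell constants, symmetry operators as xyz triplets,
fractional atom sites with occupancies, isotropic or anisotropic U, and —
beyond the standard tags — Gram–Charlier tensors in package-specific loops
``_gridhar_gc3_*`` / ``_gridhar_gc4_*`` whose component columns follow the
lexicographic unique-index order documented in :mod:`gridhar.crystal`
(111, 112, 113, 122, 123, 133, 222, ... for third order).  Space-group
symbols are never interpreted; operators must be listed explicitly.
"""

from __future__ import annotations

import numpy as np

from .crystal import Atom, CrystalStructure, SymmetryOp, UnitCell

__all__ = ["read_cif", "write_cif"]

_GC3_TAGS = ["c111", "c112", "c113", "c122", "c123", "c133",
             "c222", "c223", "c233", "c333"]
_GC4_TAGS = ["d1111", "d1112", "d1113", "d1122", "d1123", "d1133",
             "d1222", "d1223", "d1233", "d1333", "d2222", "d2223",
             "d2233", "d2333", "d3333"]


def _as_float(text: str) -> float:
    """CIF number, stripping a parenthesised standard uncertainty."""
    return float(text.split("(")[0])


def read_cif(path) -> CrystalStructure:
    import gemmi

    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def item(tag, default=None):
        val = block.find_value(tag)
        if val is None:
            if default is None:
                raise KeyError(f"{path}: missing CIF item {tag}")
            return default
        return val

    cell = UnitCell(
        _as_float(item("_cell_length_a")),
        _as_float(item("_cell_length_b")),
        _as_float(item("_cell_length_c")),
        _as_float(item("_cell_angle_alpha", "90")),
        _as_float(item("_cell_angle_beta", "90")),
        _as_float(item("_cell_angle_gamma", "90")),
    )
    wavelength = _as_float(item("_diffrn_radiation_wavelength", "0.71073"))

    symmetry = []
    for tag in ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz"):
        col = block.find_loop(tag)
        triplets = [gemmi.cif.as_string(v) for v in col]
        if triplets:
            symmetry = [SymmetryOp.from_triplet(t) for t in triplets]
            break
    if not symmetry:
        symmetry = [SymmetryOp.identity()]

    site_cols = [
        "_atom_site_label", "_atom_site_type_symbol",
        "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z",
    ]
    table = block.find(site_cols)
    if not table:
        raise KeyError(f"{path}: no _atom_site loop")
    occ_col = block.find_loop("_atom_site_occupancy")
    occs = [_as_float(gemmi.cif.as_string(v)) for v in occ_col] or None
    uiso_col = block.find_loop("_atom_site_U_iso_or_equiv")
    uisos = [_as_float(gemmi.cif.as_string(v)) for v in uiso_col] or None

    atoms = []
    for i, row in enumerate(table):
        atoms.append(
            Atom(
                label=row.str(0),
                element=row.str(1),
                frac_pos=[_as_float(row[2]), _as_float(row[3]), _as_float(row[4])],
                occupancy=occs[i] if occs else 1.0,
                adp=uisos[i] if uisos else 0.0,
            )
        )
    by_label = {a.label: a for a in atoms}

    aniso_cols = ["_atom_site_aniso_label"] + [
        f"_atom_site_aniso_U_{ij}" for ij in ("11", "22", "33", "12", "13", "23")
    ]
    for row in block.find(aniso_cols):
        by_label[row.str(0)].adp = np.array([_as_float(row[j]) for j in range(1, 7)])

    for rank, tags, n in (("gc3", _GC3_TAGS, 10), ("gc4", _GC4_TAGS, 15)):
        cols = [f"_gridhar_{rank}_label"] + [f"_gridhar_{rank}_{t}" for t in tags]
        for row in block.find(cols):
            setattr(
                by_label[row.str(0)],
                rank,
                np.array([_as_float(row[j]) for j in range(1, n + 1)]),
            )

    return CrystalStructure(cell, symmetry, atoms, wavelength)


def write_cif(path, structure: CrystalStructure, data_name: str = "gridhar") -> None:
    import gemmi

    doc = gemmi.cif.Document()
    block = doc.add_new_block(data_name)
    cell = structure.cell
    for tag, val in (
        ("_cell_length_a", cell.a), ("_cell_length_b", cell.b),
        ("_cell_length_c", cell.c), ("_cell_angle_alpha", cell.alpha),
        ("_cell_angle_beta", cell.beta), ("_cell_angle_gamma", cell.gamma),
        ("_cell_volume", cell.volume),
        ("_diffrn_radiation_wavelength", structure.wavelength),
    ):
        block.set_pair(tag, f"{val:.6f}")

    sym_loop = block.init_loop("_space_group_symop_", ["operation_xyz"])
    for op in structure.symmetry:
        sym_loop.add_row([gemmi.cif.quote(op.to_triplet())])

    site_loop = block.init_loop(
        "_atom_site_",
        ["label", "type_symbol", "fract_x", "fract_y", "fract_z",
         "occupancy", "U_iso_or_equiv", "adp_type"],
    )
    from .crystal import u_equiv

    for atom in structure.atoms:
        if atom.is_anisotropic:
            uiso = u_equiv(atom.adp, cell)
            adp_type = "Uani"
        else:
            uiso = float(atom.adp)
            adp_type = "Uiso"
        site_loop.add_row(
            [atom.label, atom.element]
            + [f"{v:.8f}" for v in atom.frac_pos]
            + [f"{atom.occupancy:.4f}", f"{uiso:.8f}", adp_type]
        )

    aniso_atoms = [a for a in structure.atoms if a.is_anisotropic]
    if aniso_atoms:
        loop = block.init_loop(
            "_atom_site_aniso_",
            ["label", "U_11", "U_22", "U_33", "U_12", "U_13", "U_23"],
        )
        for atom in aniso_atoms:
            loop.add_row([atom.label] + [f"{v:.8f}" for v in atom.adp])

    for rank, tags, attr in (("gc3", _GC3_TAGS, "gc3"), ("gc4", _GC4_TAGS, "gc4")):
        members = [a for a in structure.atoms if getattr(a, attr) is not None]
        if members:
            loop = block.init_loop(f"_gridhar_{rank}_", ["label"] + tags)
            for atom in members:
                loop.add_row(
                    [atom.label] + [f"{v:.10e}" for v in getattr(atom, attr)]
                )

    doc.write_file(str(path))
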