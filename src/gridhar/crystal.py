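"""Unit-cell geometry, symmetry, and displacement-parameter conventions.

Conventions used throughout the package:

* Orthogonalization: the ``a`` axis lies along Cartesian ``x`` and ``b`` in
  the ``x``–``y`` plane (the standard crystallographic choice).  The
  orthogonalization matrix ``A`` has the basis vectors as columns, so
  ``r_cart = A @ r_frac``.
* Anisotropic displacement parameters are stored as the six unique CIF
  components ``(U11, U22, U33, U12, U13, U23)`` in Å².  Conversion to the
  Cartesian frame is ``U_cart = A N U_cif N Aᵀ`` with
  ``N = diag(a*, b*, c*)``.
* Gram–Charlier tensors are stored as unique components in lexicographic
  index order (see :data:`GC3_INDICES` / :data:`GC4_INDICES`); they are
  contravariant in the reciprocal-lattice basis, i.e. they contract
  directly with the Miller indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement, permutations
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "ELEMENT_Z",
    "UnitCell",
    "SymmetryOp",
    "Atom",
    "CrystalStructure",
    "SiteConstraints",
    "metric_tensors",
    "frac_to_cart",
    "cart_to_frac",
    "u_cif_to_cart",
    "u_cart_to_cif",
    "u_equiv",
    "expand_to_p1",
    "site_constraints",
    "gc3_contract",
    "gc4_contract",
    "GC3_INDICES",
    "GC4_INDICES",
    "GC3_MULTIPLICITY",
    "GC4_MULTIPLICITY",
]

#: Atomic numbers for the elements the synthetic density tables cover, plus
#: a few neighbours so CIF files with heavier atoms still parse.
ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

# Unique symmetric tensor components, lexicographic, with permutation counts.
GC3_INDICES = tuple(combinations_with_replacement(range(3), 3))
GC4_INDICES = tuple(combinations_with_replacement(range(3), 4))
GC3_MULTIPLICITY = np.array(
    [len(set(permutations(idx))) for idx in GC3_INDICES], dtype=float
)
GC4_MULTIPLICITY = np.array(
    [len(set(permutations(idx))) for idx in GC4_INDICES], dtype=float
)

# CIF component order for the six unique U^ij.
_U6_IJ = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


class InvalidCellError(ValueError):
    """Raised when cell constants do not describe a proper parallelepiped."""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180)")
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 0.0:
            raise InvalidCellError("cell angles give non-positive volume")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    @property
    def orthogonalization(self) -> np.ndarray:
        """Matrix ``A`` with the direct basis vectors as columns (Å)."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(abs(np.linalg.det(self.orthogonalization)))

    @property
    def reciprocal_lengths(self) -> np.ndarray:
        """(a*, b*, c*) in Å⁻¹."""
        _, gstar = metric_tensors(self)
        return np.sqrt(np.diag(gstar))


def metric_tensors(cell: UnitCell) -> tuple[np.ndarray, np.ndarray]:
    """Direct metric ``G = AᵀA`` (Å²) and reciprocal metric ``G* = G⁻¹`` (Å⁻²)."""
    a_mat = cell.orthogonalization
    g = a_mat.T @ a_mat
    try:
        gstar = np.linalg.inv(g)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by UnitCell
        raise InvalidCellError("degenerate cell: singular metric") from exc
    # enforce exact symmetry against round-off
    return 0.5 * (g + g.T), 0.5 * (gstar + gstar.T)


def frac_to_cart(x, cell: UnitCell) -> np.ndarray:
    """Map fractional coordinates to Cartesian Å (works on (..., 3) arrays)."""
    return np.asarray(x) @ cell.orthogonalization.T


def cart_to_frac(r, cell: UnitCell) -> np.ndarray:
    return np.asarray(r) @ np.linalg.inv(cell.orthogonalization).T


def u6_to_matrix(u6) -> np.ndarray:
    """Six unique components (CIF order) to a symmetric 3×3 matrix."""
    u6 = np.asarray(u6, dtype=float)
    m = np.empty((3, 3))
    for comp, (i, j) in zip(u6, _U6_IJ):
        m[i, j] = comp
        m[j, i] = comp
    return m


def matrix_to_u6(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.array([m[i, j] for i, j in _U6_IJ])


def u_cif_to_cart(u6, cell: UnitCell) -> np.ndarray:
    """CIF ``U^ij`` to the Cartesian-frame displacement matrix (Å²)."""
    n = np.diag(cell.reciprocal_lengths)
    a_mat = cell.orthogonalization
    m = a_mat @ n @ u6_to_matrix(u6) @ n @ a_mat.T
    return 0.5 * (m + m.T)


def u_cart_to_cif(u_cart, cell: UnitCell) -> np.ndarray:
    """Inverse of :func:`u_cif_to_cart`; returns the six CIF components."""
    n_inv = np.diag(1.0 / cell.reciprocal_lengths)
    a_inv = np.linalg.inv(cell.orthogonalization)
    m = n_inv @ a_inv @ np.asarray(u_cart) @ a_inv.T @ n_inv
    return matrix_to_u6(0.5 * (m + m.T))


def u_equiv(u6, cell: UnitCell) -> float:
    """Isotropic-equivalent U (one third of the Cartesian trace), Å²."""
    return float(np.trace(u_cif_to_cart(u6, cell)) / 3.0)


def gc3_contract(c10, h) -> np.ndarray:
    """Σ C^{jkl} h_j h_k h_l over the full tensor, from unique components.

    ``h`` may be a single triple or an (n, 3) array.
    """
    c10 = np.asarray(c10, dtype=float)
    h = np.atleast_2d(np.asarray(h, dtype=float))
    out = np.zeros(h.shape[0])
    for comp, mult, (j, k, l) in zip(c10, GC3_MULTIPLICITY, GC3_INDICES):
        out += mult * comp * h[:, j] * h[:, k] * h[:, l]
    return out


def gc4_contract(d15, h) -> np.ndarray:
    """Σ D^{jklm} h_j h_k h_l h_m from unique components."""
    d15 = np.asarray(d15, dtype=float)
    h = np.atleast_2d(np.asarray(h, dtype=float))
    out = np.zeros(h.shape[0])
    for comp, mult, (j, k, l, m) in zip(d15, GC4_MULTIPLICITY, GC4_INDICES):
        out += mult * comp * h[:, j] * h[:, k] * h[:, l] * h[:, m]
    return out


@dataclass(frozen=True)
class SymmetryOp:
    """Symmetry operation on fractional coordinates: ``x' = R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tran = np.mod(np.asarray(self.translation, dtype=float).reshape(3), 1.0)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tran)
        det = np.linalg.det(rot)
        if not np.isclose(abs(det), 1.0, atol=1e-9):
            raise ValueError(f"symmetry rotation must have det ±1, got {det}")

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOp":
        import gemmi

        op = gemmi.Op(triplet)
        den = float(gemmi.Op.DEN)
        return cls(np.array(op.rot) / den, np.array(op.tran) / den)

    def to_triplet(self) -> str:
        import gemmi

        op = gemmi.Op()
        den = gemmi.Op.DEN
        op.rot = [[int(round(v * den)) for v in row] for row in self.rotation]
        op.tran = [int(round(v * den)) for v in self.translation]
        return op.triplet()

    def apply(self, x) -> np.ndarray:
        return np.asarray(x) @ self.rotation.T + self.translation

    def compose(self, other: "SymmetryOp") -> "SymmetryOp":
        return SymmetryOp(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )


@dataclass
class Atom:
    """An atom of the asymmetric unit.

    ``adp`` is either a scalar isotropic U (Å²) or six CIF components;
    ``gc3``/``gc4`` hold the unique Gram–Charlier components (may be None).
    """

    label: str
    element: str
    frac_pos: np.ndarray
    occupancy: float = 1.0
    adp: object = 0.0
    gc3: Optional[np.ndarray] = None
    gc4: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frac_pos = np.asarray(self.frac_pos, dtype=float).reshape(3)
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy of {self.label} outside (0, 1]")
        if self.element not in ELEMENT_Z:
            raise ValueError(f"unknown element {self.element!r}")
        if self.adp is not None and np.ndim(self.adp) > 0:
            self.adp = np.asarray(self.adp, dtype=float).reshape(6)
        if self.gc3 is not None:
            self.gc3 = np.asarray(self.gc3, dtype=float).reshape(10)
        if self.gc4 is not None:
            self.gc4 = np.asarray(self.gc4, dtype=float).reshape(15)

    @property
    def is_anisotropic(self) -> bool:
        return self.adp is not None and np.ndim(self.adp) > 0

    @property
    def z(self) -> int:
        return ELEMENT_Z[self.element]

    def copy(self) -> "Atom":
        return Atom(
            self.label,
            self.element,
            self.frac_pos.copy(),
            self.occupancy,
            None if self.adp is None else (np.array(self.adp) if self.is_anisotropic else float(self.adp)),
            None if self.gc3 is None else self.gc3.copy(),
            None if self.gc4 is None else self.gc4.copy(),
        )


@dataclass
class CrystalStructure:
    """Cell + symmetry + asymmetric-unit atoms (+ radiation wavelength, Å)."""

    cell: UnitCell
    symmetry: list
    atoms: list
    wavelength: float = 0.71073

    def __post_init__(self):
        if not self.symmetry:
            self.symmetry = [SymmetryOp.identity()]
        if not any(op.is_identity() for op in self.symmetry):
            raise ValueError("symmetry list must contain the identity")
        labels = [a.label for a in self.atoms]
        if len(labels) != len(set(labels)):
            raise ValueError("atom labels must be unique")

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            self.cell,
            list(self.symmetry),
            [a.copy() for a in self.atoms],
            self.wavelength,
        )

    def atom(self, label: str) -> Atom:
        for a in self.atoms:
            if a.label == label:
                return a
        raise KeyError(label)


# ---------------------------------------------------------------------------
# symmetry transforms of displacement / Gram-Charlier tensors


def transform_u6(op: SymmetryOp, u6, cell: UnitCell) -> np.ndarray:
    """Transform CIF U^ij to the symmetry image.

    The dimensionless tensor ``M = N U N`` (N = diag(a*, b*, c*)) is
    contravariant, ``M' = R M Rᵀ``.
    """
    n = cell.reciprocal_lengths
    m = n[:, None] * u6_to_matrix(u6) * n[None, :]
    m2 = op.rotation @ m @ op.rotation.T
    return matrix_to_u6(m2 / n[:, None] / n[None, :])


def _sym_tensor_transform(rot: np.ndarray, comps, indices, rank: int) -> np.ndarray:
    """Transform unique symmetric contravariant tensor components by ``rot``."""
    comps = np.asarray(comps, dtype=float)
    full = np.zeros((3,) * rank)
    for comp, idx in zip(comps, indices):
        for perm in set(permutations(idx)):
            full[perm] = comp
    for axis in range(rank):
        full = np.tensordot(rot, full, axes=(1, axis))
        full = np.moveaxis(full, 0, axis)
    return np.array([full[idx] for idx in indices])


def transform_gc3(op: SymmetryOp, c10) -> np.ndarray:
    return _sym_tensor_transform(op.rotation, c10, GC3_INDICES, 3)


def transform_gc4(op: SymmetryOp, d15) -> np.ndarray:
    return _sym_tensor_transform(op.rotation, d15, GC4_INDICES, 4)


def _transform_atom(atom: Atom, op: SymmetryOp, cell: UnitCell) -> Atom:
    out = atom.copy()
    out.frac_pos = np.mod(op.apply(atom.frac_pos), 1.0)
    if atom.is_anisotropic:
        out.adp = transform_u6(op, atom.adp, cell)
    if atom.gc3 is not None:
        out.gc3 = transform_gc3(op, atom.gc3)
    if atom.gc4 is not None:
        out.gc4 = transform_gc4(op, atom.gc4)
    return out


def _frac_close(x, y, tol: float) -> bool:
    d = np.asarray(x) - np.asarray(y)
    d -= np.round(d)
    return bool(np.all(np.abs(d) < tol))


def expand_to_p1(
    structure: CrystalStructure, merge_tol: float = 1e-6
) -> list[tuple[Atom, SymmetryOp]]:
    """Expand the asymmetric unit over the symmetry group.

    Returns one ``(atom copy, generating op)`` per distinct site in the
    cell; images coinciding within ``merge_tol`` (fractional, periodic)
    are merged, so atoms on special positions appear once.
    """
    out: list[tuple[Atom, SymmetryOp]] = []
    for atom in structure.atoms:
        seen: list[np.ndarray] = []
        for op in structure.symmetry:
            pos = np.mod(op.apply(atom.frac_pos), 1.0)
            if any(_frac_close(pos, p, merge_tol) for p in seen):
                continue
            seen.append(pos)
            img = _transform_atom(atom, op, structure.cell)
            img.label = atom.label if op.is_identity() else f"{atom.label}#{len(seen)}"
            out.append((img, op))
    return out


def site_symmetry_ops(
    atom: Atom, symmetry: Sequence[SymmetryOp], tol: float = 1e-6
) -> list[SymmetryOp]:
    """Operations of the group that fix the atom's site (mod lattice)."""
    return [
        op
        for op in symmetry
        if _frac_close(op.apply(atom.frac_pos), atom.frac_pos, tol)
    ]


@dataclass
class SiteConstraints:
    """Linear reparameterization of one atom's refinable blocks.

    Each block is expressed as ``full = offset + basis @ free``; an empty
    basis (0 columns) means the block is entirely fixed by symmetry.
    """

    pos_offset: np.ndarray
    pos_basis: np.ndarray
    u6_basis: np.ndarray
    gc3_basis: np.ndarray
    gc4_basis: np.ndarray
    site_order: int = 1

    @property
    def is_general(self) -> bool:
        return self.site_order == 1


def _invariant_basis(rep_matrices: list[np.ndarray]) -> np.ndarray:
    """Orthonormal basis of the subspace invariant under all matrices."""
    dim = rep_matrices[0].shape[0]
    mean = sum(rep_matrices) / len(rep_matrices)
    basis = null_space(mean - np.eye(dim), rcond=1e-8)
    return basis if basis.size else np.zeros((dim, 0))


def site_constraints(
    atom: Atom,
    symmetry: Sequence[SymmetryOp],
    cell: UnitCell,
    tol: float = 1e-6,
) -> SiteConstraints:
    """Constraints restricting refinement to the site-invariant subspace.

    On a general position every block gets an identity basis.  On a special
    position the free positional directions are the displacements invariant
    under the site group; U and Gram–Charlier components are restricted by
    group-averaging their transformation representations (odd tensors on a
    centre of inversion average to zero, eliminating all GC3 freedom).
    """
    site_ops = site_symmetry_ops(atom, symmetry, tol)
    if len(site_ops) == 1:
        return SiteConstraints(
            pos_offset=atom.frac_pos.copy(),
            pos_basis=np.eye(3),
            u6_basis=np.eye(6),
            gc3_basis=np.eye(10),
            gc4_basis=np.eye(15),
            site_order=1,
        )

    # exact special position: affine group average, unwrapped near the atom
    images = []
    for op in site_ops:
        img = op.apply(atom.frac_pos)
        img -= np.round(img - atom.frac_pos)
        images.append(img)
    pos_offset = np.mean(images, axis=0)

    pos_rep = [op.rotation for op in site_ops]
    u_rep, g3_rep, g4_rep = [], [], []
    for op in site_ops:
        u_cols = [transform_u6(op, e, cell) for e in np.eye(6)]
        u_rep.append(np.column_stack(u_cols))
        g3_rep.append(np.column_stack([transform_gc3(op, e) for e in np.eye(10)]))
        g4_rep.append(np.column_stack([transform_gc4(op, e) for e in np.eye(15)]))

    return SiteConstraints(
        pos_offset=pos_offset,
        pos_basis=_invariant_basis(pos_rep),
        u6_basis=_invariant_basis(u_rep),
        gc3_basis=_invariant_basis(g3_rep),
        gc4_basis=_invariant_basis(g4_rep),
        site_order=len(site_ops),
    )


def symmetrize_u6(atom: Atom, symmetry: Sequence[SymmetryOp], cell: UnitCell) -> np.ndarray:
    """Average the atom's U^ij over its site-symmetry group."""
    site_ops = site_symmetry_ops(atom, symmetry)
    return np.mean([transform_u6(op, atom.adp, cell) for op in site_ops], axis=0)


def cell_electron_count(structure: CrystalStructure) -> float:
    """Σ multiplicity · occupancy · Z over the P1-expanded cell."""
    return float(
        sum(atom.occupancy * atom.z for atom, _ in expand_to_p1(structure))
    )
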