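"""Reflection data: SHELX HKLF4 I/O, resolution bookkeeping, filtering.

The HKLF4 record layout is fixed-width ``3I4,2F8`` — three 4-column integer
Miller indices followed by Fo² and σ(Fo²) in 8-column floats — terminated by
an all-zero record or end of file.  Data are kept as given: symmetry
equivalents are not merged unless :func:`merge_equivalents` is called
explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal import UnitCell, metric_tensors

__all__ = [
    "Reflection",
    "ReflectionSet",
    "read_hkl",
    "write_hkl",
    "resolution",
    "filter_significance",
    "merge_equivalents",
    "write_fcf",
    "read_fcf",
]


class HklParseError(ValueError):
    pass


class EmptyReflectionSetError(ValueError):
    pass


@dataclass(frozen=True)
class Reflection:
    hkl: tuple
    fo2: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if tuple(self.hkl) == (0, 0, 0):
            raise ValueError("observed reflection cannot be (0,0,0)")


@dataclass
class ReflectionSet:
    """A list of observed reflections plus the radiation wavelength (Å)."""

    reflections: list
    wavelength: float = 0.71073

    def __post_init__(self):
        if not self.reflections:
            raise EmptyReflectionSetError("reflection set is empty")

    def __len__(self) -> int:
        return len(self.reflections)

    @property
    def hkl(self) -> np.ndarray:
        return np.array([r.hkl for r in self.reflections], dtype=int)

    @property
    def fo2(self) -> np.ndarray:
        return np.array([r.fo2 for r in self.reflections])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([r.sigma for r in self.reflections])


def read_hkl(path, wavelength: float = 0.71073) -> ReflectionSet:
    """Read a SHELX HKLF4 file (``3I4,2F8``; all-zero record terminates)."""
    refs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])
                fo2 = float(line[12:20])
                sigma = float(line[20:28])
            except (ValueError, IndexError) as exc:
                raise HklParseError(f"{path}: malformed record at line {lineno}") from exc
            if (h, k, l) == (0, 0, 0):
                break
            if sigma <= 0:
                warnings.warn(
                    f"{path}: rejecting reflection {h} {k} {l} with σ={sigma} "
                    f"at line {lineno}"
                )
                continue
            refs.append(Reflection((h, k, l), fo2, sigma))
    return ReflectionSet(refs, wavelength=wavelength)


def write_hkl(path, rs: ReflectionSet) -> None:
    """Write HKLF4 fixed-width records with a terminating all-zero line."""
    with open(path, "w") as fh:
        for r in rs.reflections:
            fh.write(
                "%4d%4d%4d%8.2f%8.2f\n" % (r.hkl[0], r.hkl[1], r.hkl[2], r.fo2, r.sigma)
            )
        fh.write("%4d%4d%4d%8.2f%8.2f\n" % (0, 0, 0, 0.0, 0.0))


def resolution(hkl, cell: UnitCell) -> np.ndarray:
    """sinθ/λ in Å⁻¹: ``½·√(hᵀ G* h)``; accepts a triple or an (n, 3) array."""
    _, gstar = metric_tensors(cell)
    h = np.atleast_2d(np.asarray(hkl, dtype=float))
    s = 0.5 * np.sqrt(np.einsum("ni,ij,nj->n", h, gstar, h))
    return s if np.ndim(hkl) == 2 else float(s[0])


def filter_significance(rs: ReflectionSet, threshold: float) -> ReflectionSet:
    """Keep reflections with F/σ(F) at or above ``threshold``.

    The data carry intensities, so the rule is applied as
    ``Fo² / σ(Fo²) ≥ threshold²`` for positive Fo²; non-positive Fo² is
    always removed at a positive threshold.  ``threshold = 0`` returns the
    input unchanged (negative intensities are retained for weighted least
    squares).
    """
    if threshold < 0:
        raise ValueError("significance threshold must be non-negative")
    if threshold == 0:
        return rs
    t2 = threshold * threshold
    kept = [r for r in rs.reflections if r.fo2 > 0 and r.fo2 / r.sigma >= t2]
    if not kept:
        raise EmptyReflectionSetError(
            f"no reflections pass F/σ(F) ≥ {threshold}; nothing to refine"
        )
    return ReflectionSet(kept, wavelength=rs.wavelength)


def merge_equivalents(rs: ReflectionSet, symmetry) -> ReflectionSet:
    """Optional utility: inverse-variance average of symmetry equivalents.

    Reflections are grouped under ``h → Rᵀh`` over the given operations and
    Friedel inversion; the representative index is the lexicographic
    maximum of the orbit.
    """
    groups: dict = {}
    rots = [np.asarray(op.rotation).round().astype(int) for op in symmetry]
    for r in rs.reflections:
        h = np.array(r.hkl, dtype=int)
        orbit = []
        for rot in rots:
            for sign in (1, -1):
                orbit.append(tuple(sign * (h @ rot)))
        key = max(orbit)
        groups.setdefault(key, []).append(r)
    merged = []
    for key, members in sorted(groups.items()):
        w = np.array([1.0 / m.sigma**2 for m in members])
        fo2 = float(np.sum(w * [m.fo2 for m in members]) / np.sum(w))
        sigma = float(1.0 / np.sqrt(np.sum(w)))
        merged.append(Reflection(key, fo2, sigma))
    return ReflectionSet(merged, wavelength=rs.wavelength)


def write_fcf(path, structure, rs: ReflectionSet, fc, scale: float = 1.0) -> None:
    """Write a CIF-style reflection loop with observed and calculated data.

    ``fc`` holds the complex structure factors on the model scale; the
    calculated intensity column is ``k·|Fc|²`` and the phase is in degrees.
    """
    fc = np.asarray(fc)
    fc2 = scale * np.abs(fc) ** 2
    phases = np.degrees(np.angle(fc))
    # snap numerically-zero imaginary parts so centric phases print 0/180
    phases = np.where(np.abs(fc.imag) < 1e-10 * np.maximum(np.abs(fc.real), 1e-30),
                      np.where(fc.real >= 0, 0.0, 180.0), phases)
    lines = [
        "data_refined",
        "_cell_length_a %.6f" % structure.cell.a,
        "_cell_length_b %.6f" % structure.cell.b,
        "_cell_length_c %.6f" % structure.cell.c,
        "_cell_angle_alpha %.4f" % structure.cell.alpha,
        "_cell_angle_beta %.4f" % structure.cell.beta,
        "_cell_angle_gamma %.4f" % structure.cell.gamma,
        "loop_",
        " _refln_index_h",
        " _refln_index_k",
        " _refln_index_l",
        " _refln_F_squared_meas",
        " _refln_F_squared_sigma",
        " _refln_F_squared_calc",
        " _refln_phase_calc",
    ]
    for r, f2, ph in zip(rs.reflections, fc2, phases):
        lines.append(
            "%4d %4d %4d %12.4f %10.4f %12.4f %8.2f"
            % (r.hkl[0], r.hkl[1], r.hkl[2], r.fo2, r.sigma, f2, ph)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fcf(path):
    """Parse a reflection loop written by :func:`write_fcf`.

    Returns ``(hkl, fo2, sigma, fc2, phase_deg)`` arrays.
    """
    import gemmi

    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    cols = [
        "_refln_index_h", "_refln_index_k", "_refln_index_l",
        "_refln_F_squared_meas", "_refln_F_squared_sigma",
        "_refln_F_squared_calc", "_refln_phase_calc",
    ]
    table = block.find(cols)
    rows = [[float(row[i]) for i in range(7)] for row in table]
    arr = np.array(rows)
    return arr[:, :3].astype(int), arr[:, 3], arr[:, 4], arr[:, 5], arr[:, 6]
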