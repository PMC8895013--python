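"""Structure factors, displacement factors, extinction, and agreement stats.

``Fc(h) = Σ_sites occ · f(h) · T(h) · GC(h) · e^{2πi h·x}`` where the sum
runs over the P1 expansion of the asymmetric unit; each symmetry image
contributes with its generator's tensors contracted against the rotated
index ``h_s = Rᵀ h``, which is equivalent to transforming the tensors and
keeps the aspherical form factors consistent with the operator.
"""

from __future__ import annotations

import numpy as np

from .crystal import (
    CrystalStructure,
    UnitCell,
    gc3_contract,
    gc4_contract,
    u6_to_matrix,
)
from .reflections import resolution

__all__ = [
    "debye_waller",
    "gram_charlier",
    "calc_structure_factors",
    "apply_extinction",
    "extinction_geometry",
    "optimal_scale",
    "wr2",
]

_GC3_COEF = (2j * np.pi) ** 3 / 6.0  # purely imaginary
_GC4_COEF = (2j * np.pi) ** 4 / 24.0  # real


def adp_beta(adp, cell: UnitCell) -> np.ndarray:
    """Dimensionless exponent tensor: ``T = exp(−hᵀ β h)``, β = 2π² N U N."""
    n = cell.reciprocal_lengths
    u = u6_to_matrix(adp) if np.ndim(adp) > 0 else np.eye(3) * float(adp)
    if np.ndim(adp) == 0:
        # isotropic U is defined in the Cartesian frame: U_cart = U·I, so
        # β = 2π² Aᵀ⁻¹... reduces to 2π² U G* (G* = N·N for orthogonal cells
        # only); use the exact reciprocal metric
        from .crystal import metric_tensors

        _, gstar = metric_tensors(cell)
        return 2.0 * np.pi**2 * float(adp) * gstar
    return 2.0 * np.pi**2 * (n[:, None] * u * n[None, :])


def debye_waller(hkl, adp, cell: UnitCell) -> np.ndarray:
    """Harmonic temperature factor ``T ∈ (0, 1]``.

    Anisotropic: ``exp(−2π² Σ h_i h_j a*_i a*_j U^ij)``;
    isotropic: ``exp(−8π² U (sinθ/λ)²)`` — the two agree for U^ij = U·δ_ij
    in orthogonal cells and in general through β = 2π²·U·G*.
    """
    h = np.atleast_2d(np.asarray(hkl, dtype=float))
    if np.ndim(adp) == 0:
        s = np.atleast_1d(resolution(h, cell))
        t = np.exp(-8.0 * np.pi**2 * float(adp) * s**2)
    else:
        beta = adp_beta(adp, cell)
        t = np.exp(-np.einsum("ni,ij,nj->n", h, beta, h))
    return t if np.ndim(hkl) == 2 else float(t[0])


def gram_charlier(hkl, gc3=None, gc4=None) -> np.ndarray:
    """Anharmonic multiplier ``1 + (2πi)³/3!·Σ C h³ + (2πi)⁴/4!·Σ D h⁴``.

    The third-order term is purely imaginary (i³ = −i), the fourth-order
    term real; indices refer to the reciprocal-lattice basis.
    """
    h = np.atleast_2d(np.asarray(hkl, dtype=float))
    out = np.ones(h.shape[0], dtype=complex)
    if gc3 is not None:
        out = out + _GC3_COEF * gc3_contract(gc3, h)
    if gc4 is not None:
        out = out + _GC4_COEF * gc4_contract(gc4, h)
    return out if np.ndim(hkl) == 2 else complex(out[0])


def calc_structure_factors(structure: CrystalStructure, ff, hkl) -> np.ndarray:
    """Complex Fc per reflection from form factors + displacement model.

    ``ff`` is an :class:`~gridhar.density.AtomicFormFactors` whose sites
    follow the P1 expansion of ``structure``; each site's form factor is
    taken from its own column and the generator atom's ADP/Gram–Charlier
    tensors are contracted with the operator-rotated index.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    cols = np.array([ff.column(h) for h in hkl])
    fc = np.zeros(hkl.shape[0], dtype=complex)
    cell = structure.cell
    for i_site, (asym_i, op) in enumerate(zip(ff.site_index, ff.site_ops)):
        atom = structure.atoms[asym_i]
        h_s = hkl.astype(float) @ op.rotation
        tphase = np.exp(2j * np.pi * (hkl @ op.translation))
        phase = np.exp(2j * np.pi * (h_s @ atom.frac_pos)) * tphase
        if atom.adp is None:
            t = 1.0
        elif np.ndim(atom.adp) == 0:
            s = resolution(hkl, cell)
            t = np.exp(-8.0 * np.pi**2 * float(atom.adp) * np.atleast_1d(s) ** 2)
        else:
            beta = adp_beta(atom.adp, cell)
            t = np.exp(-np.einsum("ni,ij,nj->n", h_s, beta, h_s))
        gc = np.ones(hkl.shape[0], dtype=complex)
        if atom.gc3 is not None:
            gc = gc + _GC3_COEF * gc3_contract(atom.gc3, h_s)
        if atom.gc4 is not None:
            gc = gc + _GC4_COEF * gc4_contract(atom.gc4, h_s)
        f_site = ff.total[i_site, cols]
        fc += atom.occupancy * f_site * t * gc * phase
    return fc


def extinction_geometry(hkl, wavelength: float, cell: UnitCell) -> np.ndarray:
    """Geometry factor ``0.001·λ³/sin(2θ)`` per reflection (0 where 2θ = 0)."""
    s = np.atleast_1d(resolution(np.atleast_2d(hkl), cell))
    sin_theta = np.clip(s * wavelength, 0.0, 1.0)
    sin_2theta = 2.0 * sin_theta * np.sqrt(1.0 - sin_theta**2)
    geom = np.zeros_like(sin_2theta)
    ok = sin_2theta > 1e-12
    geom[ok] = 0.001 * wavelength**3 / sin_2theta[ok]
    return geom


def apply_extinction(fc2, hkl, wavelength: float, cell: UnitCell, x: float) -> np.ndarray:
    """Secondary-extinction damping of calculated intensities.

    Squared form of the SHELXL ``Fc*`` convention:
    ``Fc²_corr = Fc² · [1 + 0.001·x·Fc²·λ³/sin 2θ]^{−1/2}``; ``x = 0`` is
    the identity and reflections at zero scattering angle are left alone.
    """
    fc2 = np.asarray(fc2, dtype=float)
    geom = extinction_geometry(hkl, wavelength, cell)
    u = np.maximum(1.0 + x * geom * fc2, 1e-10)
    return fc2 / np.sqrt(u)


def optimal_scale(fo2, sigma, fc2) -> float:
    """Closed-form minimizer of Σw(Fo² − k·Fc²)², w = 1/σ²."""
    fo2 = np.asarray(fo2, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    w = 1.0 / np.asarray(sigma, dtype=float) ** 2
    denom = np.sum(w * fc2 * fc2)
    if denom <= 0:
        raise ValueError("all calculated intensities vanish; cannot scale")
    return float(np.sum(w * fo2 * fc2) / denom)


def wr2(fo2, sigma, fc2, scale: float) -> float:
    """Weighted residual ``√[Σw(Fo²−kFc²)² / Σw(Fo²)²]`` with w = 1/σ²."""
    fo2 = np.asarray(fo2, dtype=float)
    w = 1.0 / np.asarray(sigma, dtype=float) ** 2
    denom = np.sum(w * fo2 * fo2)
    if denom <= 0:
        raise ValueError("Σw(Fo²)² vanishes; wR2 undefined")
    num = np.sum(w * (fo2 - scale * np.asarray(fc2, dtype=float)) ** 2)
    return float(np.sqrt(num / denom))
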