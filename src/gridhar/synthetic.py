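"""Deterministic toy crystals and simulated diffraction data.

Everything here is a pure function of ``(spec, seed)``: the same inputs
give bit-identical outputs, so refinement tests can compare against exact
generating truths without external data.  The noise model is multiplicative
Gaussian on the intensities with a σ floor — simple and sufficient for
parameter-recovery tests; no counting-statistics realism is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal import Atom, CrystalStructure, SymmetryOp, UnitCell, metric_tensors
from .density import DensitySource, form_factors_from_source
from .reflections import Reflection, ReflectionSet
from .scattering import calc_structure_factors

__all__ = [
    "SimulationSpec",
    "make_toy_structure",
    "enumerate_hkl",
    "simulate_reflections",
]

KINDS = (
    "diatomic_P1",
    "bent_triatomic_P1",
    "inversion_pair_P-1",
    "special_position_toy",
)

#: σ floor as a fraction of the median intensity
SIGMA_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: structure kind, resolution limit, noise, seed."""

    kind: str = "diatomic_P1"
    d_min: float = 0.8
    noise: float = 0.0
    seed: int = 0
    k_true: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}; choose from {KINDS}")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.noise < 0:
            raise ValueError("noise fraction must be non-negative")


def make_toy_structure(kind: str, seed: int = 0) -> CrystalStructure:
    """Small (≤ 12 Å, ≤ 6 atoms) test crystals from {H, C, N, O}.

    ``seed`` applies a reproducible sub-0.005-fractional jitter to atoms on
    general positions so repeated studies do not all share one geometry;
    seed 0 gives the canonical fixture.
    """
    rng = np.random.default_rng(seed)

    def jitter():
        return rng.normal(0.0, 0.002, size=3) if seed else np.zeros(3)

    if kind == "diatomic_P1":
        cell = UnitCell(6.0, 7.0, 8.0)
        # C-H bond of 1.09 Å along a
        atoms = [
            Atom("C1", "C", np.array([0.30, 0.40, 0.35]) + jitter(), 1.0,
                 np.array([0.012, 0.015, 0.010, 0.002, -0.001, 0.001])),
            Atom("H1", "H", np.array([0.30 + 1.09 / 6.0, 0.40, 0.35]) + jitter(),
                 1.0, 0.030),
        ]
        return CrystalStructure(cell, [SymmetryOp.identity()], atoms)

    if kind == "bent_triatomic_P1":
        cell = UnitCell(7.0, 8.0, 9.0)
        # water-like O-H bonds of 0.96 Å, ~104.5 deg apart, in the a-b plane
        o_pos = np.array([0.40, 0.45, 0.50]) + jitter()
        r_oh = 0.96
        half = np.radians(104.5 / 2.0)
        d1 = np.array([r_oh * np.cos(half) / 7.0, r_oh * np.sin(half) / 8.0, 0.0])
        d2 = np.array([r_oh * np.cos(half) / 7.0, -r_oh * np.sin(half) / 8.0, 0.0])
        atoms = [
            Atom("O1", "O", o_pos, 1.0,
                 np.array([0.010, 0.013, 0.011, -0.002, 0.001, 0.002])),
            Atom("H1", "H", o_pos + d1, 1.0, 0.028),
            Atom("H2", "H", o_pos + d2, 1.0, 0.032),
        ]
        return CrystalStructure(cell, [SymmetryOp.identity()], atoms)

    if kind == "inversion_pair_P-1":
        cell = UnitCell(8.0, 6.5, 7.5, 95.0, 90.0, 105.0)
        symmetry = [SymmetryOp.identity(), SymmetryOp(-np.eye(3), np.zeros(3))]
        atoms = [
            Atom("N1", "N", np.array([0.10, 0.20, 0.30]) + jitter(), 1.0,
                 np.array([0.011, 0.014, 0.012, 0.001, 0.002, -0.001])),
            Atom("H1", "H", np.array([0.10, 0.20, 0.30 + 1.01 / 7.5]) + jitter(),
                 1.0, 0.027),
        ]
        return CrystalStructure(cell, symmetry, atoms)

    if kind == "special_position_toy":
        # centrosymmetric cell with one atom pinned on the inversion centre
        cell = UnitCell(7.5, 7.0, 8.5)
        symmetry = [SymmetryOp.identity(), SymmetryOp(-np.eye(3), np.zeros(3))]
        atoms = [
            Atom("N1", "N", np.zeros(3), 1.0,
                 np.array([0.012, 0.010, 0.014, 0.001, -0.002, 0.001])),
            Atom("O1", "O", np.array([0.28, 0.18, 0.36]) + jitter(), 1.0,
                 np.array([0.011, 0.012, 0.010, -0.001, 0.001, 0.002])),
            Atom("H1", "H", np.array([0.28, 0.18, 0.36 + 0.97 / 8.5]) + jitter(),
                 1.0, 0.030),
        ]
        return CrystalStructure(cell, symmetry, atoms)

    raise ValueError(f"unknown structure kind {kind!r}")


def enumerate_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """All reflections of one hemisphere with 0 < sinθ/λ ≤ 1/(2·d_min).

    Friedel mates are excluded by the convention ``h > 0``, or ``h = 0 and
    k > 0``, or ``h = k = 0 and l > 0``; output is sorted lexicographically.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    _, gstar = metric_tensors(cell)
    s_max = 1.0 / (2.0 * d_min)
    lam_min = np.min(np.linalg.eigvalsh(gstar))
    h_max = int(np.floor(2.0 * s_max / np.sqrt(lam_min))) + 1
    out = []
    for h in range(-h_max, h_max + 1):
        for k in range(-h_max, h_max + 1):
            for l in range(-h_max, h_max + 1):
                if not (h > 0 or (h == 0 and k > 0) or (h == 0 and k == 0 and l > 0)):
                    continue
                v = np.array([h, k, l], dtype=float)
                s = 0.5 * np.sqrt(v @ gstar @ v)
                if 0.0 < s <= s_max:
                    out.append((h, k, l))
    out.sort()
    return np.array(out, dtype=int).reshape(-1, 3)


def simulate_reflections(
    structure: CrystalStructure,
    density_source: DensitySource,
    spec: SimulationSpec,
    grid_spacing: float = 0.2,
    interp_factor: int = 2,
    wavelength: float = 0.71073,
) -> ReflectionSet:
    """Simulated Fo², σ(Fo²) records from the full form-factor pipeline.

    ``Fo² = k_true·Fc²·(1 + η·ξ)`` with ξ ~ N(0, 1) from the seeded
    generator and ``σ = k_true·Fc²·η + floor`` where the floor is 1% of the
    median intensity.  Zero noise returns ``Fo² = k_true·Fc²`` exactly, so a
    refinement that regenerates form factors with the same grid settings
    reproduces the data perfectly at the generating parameters.
    """
    hkl = enumerate_hkl(structure.cell, spec.d_min)
    if hkl.size == 0:
        raise ValueError(f"no reflections below d_min = {spec.d_min} Å")
    ff = form_factors_from_source(
        structure, density_source, hkl,
        grid_spacing=grid_spacing, interp_factor=interp_factor,
    )
    fc = calc_structure_factors(structure, ff, hkl)
    fc2 = spec.k_true * np.abs(fc) ** 2

    rng = np.random.default_rng(spec.seed)
    xi = rng.standard_normal(len(fc2))
    floor = SIGMA_FLOOR_FRACTION * float(np.median(fc2))
    sigma = fc2 * spec.noise + floor
    fo2 = fc2 * (1.0 + spec.noise * xi)
    refs = [
        Reflection(tuple(int(v) for v in h), float(f), float(s))
        for h, f, s in zip(hkl, fo2, sigma)
    ]
    return ReflectionSet(refs, wavelength=wavelength)
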