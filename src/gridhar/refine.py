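"""Crystallographic least squares against wR2(F²) and the HAR outer loop.

The inner refinement minimizes ``Σ w (Fo² − k·Fc²)²`` with ``w = 1/σ²`` —
the same argmin as wR2(F²) — over positions, displacement parameters,
optional Gram–Charlier tensors and an optional extinction coefficient.
The scale ``k`` is eliminated in closed form at every evaluation, which
removes the scale/U-isotropic degeneracy direction from the optimizer and
(by the envelope theorem) drops out of the analytic gradient.  A weighting
scheme is never refined.

Site-symmetry constraints enter as a linear reparameterization: every
refinable block of an atom is ``full = offset + basis @ free`` with the
basis spanning the subspace invariant under the site group, so the free
parameter count is honest and an atom on an inversion centre simply has no
positional parameters.

Gradients are analytic for every parameter class and are validated against
central finite differences in the test suite.  Optimization uses BFGS from
``scipy.optimize``; form factors stay fixed within the inner refinement
and are refreshed from the density source once per outer HAR cycle, while
the atom-centring phases always use the current positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .crystal import (
    CrystalStructure,
    GC3_INDICES,
    GC3_MULTIPLICITY,
    GC4_INDICES,
    GC4_MULTIPLICITY,
    metric_tensors,
    site_constraints,
    u6_to_matrix,
)
from .density import (
    AtomicFormFactors,
    DensitySource,
    form_factors_from_source,
    spherical_form_factors,
)
from .reflections import ReflectionSet, filter_significance, resolution
from .scattering import extinction_geometry, optimal_scale, wr2

__all__ = ["RefinementSettings", "RefinementResult", "refine_lsq", "har_iterate"]

_TWO_PI_SQ = 2.0 * np.pi**2
_GC3_COEF = (2j * np.pi) ** 3 / 6.0
_GC4_COEF = (2j * np.pi) ** 4 / 24.0


@dataclass
class RefinementSettings:
    """Knobs of the least-squares and HAR loops.

    ``shift_tol`` is the convergence threshold on the maximum absolute
    parameter shift (fractional coordinates and Å² share the 1e-6 scale of
    standard refinement software); ``har_shift_tol`` plays the same role
    between outer density cycles.
    """

    max_lsq_cycles: int = 200
    max_har_cycles: int = 10
    shift_tol: float = 1e-6
    har_shift_tol: float = 1e-5
    refine_positions: bool = True
    refine_adps: bool = True
    refine_extinction: bool = False
    gc3_atoms: tuple = ()
    gc4_atoms: tuple = ()
    #: labels whose positions are held fixed — pins the floating origin of
    #: polar cells (P1 has no symmetry element to anchor it)
    fixed_position_atoms: tuple = ()
    fsig_cutoff: float = 0.0
    grid_spacing: float = 0.2
    interp_factor: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.shift_tol <= 0 or self.har_shift_tol <= 0:
            raise ValueError("convergence tolerances must be positive")


@dataclass
class RefinementResult:
    structure: CrystalStructure
    scale: float
    extinction: float
    wr2: float
    wr2_history: list
    shift_history: list
    converged: bool
    n_cycles: int
    message: str = ""


class _Block:
    """One refinable parameter block of one atom."""

    def __init__(self, kind, atom_index, offset, basis):
        self.kind = kind  # 'pos' | 'u6' | 'uiso' | 'gc3' | 'gc4'
        self.atom_index = atom_index
        self.offset = np.asarray(offset, dtype=float)
        self.basis = np.asarray(basis, dtype=float)
        self.n_free = self.basis.shape[1] if self.basis.ndim == 2 else 0

    def full(self, free):
        return self.offset + self.basis @ free

    def free_from_full(self, full):
        # bases are orthonormal columns (null_space/identity), so the
        # pseudo-inverse is the transpose
        return self.basis.T @ (np.asarray(full, dtype=float) - self.offset)


class _Model:
    """Structure-factor model with analytic gradients, fixed form factors."""

    def __init__(self, structure, reflections, ff, settings):
        self.base = structure.copy()
        self.cell = structure.cell
        self.settings = settings
        self.hkl = reflections.hkl
        self.fo2 = reflections.fo2
        self.w = 1.0 / reflections.sigma**2
        self.wr2_denom = float(np.sum(self.w * self.fo2**2))
        self.ff = ff
        self.cols = np.array([ff.column(h) for h in self.hkl])
        self.s2 = np.atleast_1d(resolution(self.hkl, self.cell)) ** 2
        _, self.gstar = metric_tensors(self.cell)
        self.nstar = self.cell.reciprocal_lengths
        self.ext_geom = extinction_geometry(
            self.hkl, reflections.wavelength, self.cell
        )

        # per expanded site: rotated indices and translation phases
        self.site_hs = []
        self.site_tphase = []
        hklf = self.hkl.astype(float)
        for op in ff.site_ops:
            self.site_hs.append(hklf @ op.rotation)
            self.site_tphase.append(np.exp(2j * np.pi * (self.hkl @ op.translation)))

        self.blocks = self._build_blocks()
        self.n_free = sum(b.n_free for b in self.blocks)
        self.refine_ext = settings.refine_extinction

    # -- parameter bookkeeping ------------------------------------------
    def _build_blocks(self):
        blocks = []
        st = self.settings
        for i, atom in enumerate(self.base.atoms):
            cons = site_constraints(atom, self.base.symmetry, self.cell)
            if st.refine_positions and atom.label not in st.fixed_position_atoms:
                blocks.append(_Block("pos", i, cons.pos_offset, cons.pos_basis))
            if st.refine_adps and atom.adp is not None:
                if np.ndim(atom.adp) > 0:
                    blocks.append(_Block("u6", i, np.zeros(6), cons.u6_basis))
                else:
                    blocks.append(_Block("uiso", i, np.zeros(1), np.eye(1)))
            if atom.label in st.gc3_atoms:
                if atom.gc3 is None:
                    atom.gc3 = np.zeros(10)
                blocks.append(_Block("gc3", i, np.zeros(10), cons.gc3_basis))
            if atom.label in st.gc4_atoms:
                if atom.gc4 is None:
                    atom.gc4 = np.zeros(15)
                blocks.append(_Block("gc4", i, np.zeros(15), cons.gc4_basis))
        return blocks

    def pack(self, structure, extinction=0.0):
        free = []
        for b in self.blocks:
            atom = structure.atoms[b.atom_index]
            if b.kind == "pos":
                free.append(b.free_from_full(atom.frac_pos))
            elif b.kind == "u6":
                free.append(b.free_from_full(atom.adp))
            elif b.kind == "uiso":
                free.append(b.free_from_full([float(atom.adp)]))
            elif b.kind == "gc3":
                free.append(
                    b.free_from_full(atom.gc3 if atom.gc3 is not None else np.zeros(10))
                )
            elif b.kind == "gc4":
                free.append(
                    b.free_from_full(atom.gc4 if atom.gc4 is not None else np.zeros(15))
                )
        if self.refine_ext:
            free.append([extinction])
        return np.concatenate(free) if free else np.zeros(0)

    def unpack(self, params):
        structure = self.base.copy()
        pos = 0
        for b in self.blocks:
            vals = b.full(params[pos : pos + b.n_free])
            atom = structure.atoms[b.atom_index]
            if b.kind == "pos":
                atom.frac_pos = vals
            elif b.kind == "u6":
                atom.adp = vals
            elif b.kind == "uiso":
                atom.adp = float(vals[0])
            elif b.kind == "gc3":
                atom.gc3 = vals
            elif b.kind == "gc4":
                atom.gc4 = vals
            pos += b.n_free
        extinction = float(params[pos]) if self.refine_ext else 0.0
        return structure, extinction

    # -- structure factors and gradients --------------------------------
    def _site_terms(self, structure, i_site):
        """Per-site factors: (base = occ·f·T·phase, gc, T-exponent pieces)."""
        asym_i = self.ff.site_index[i_site]
        atom = structure.atoms[asym_i]
        hs = self.site_hs[i_site]
        phase = np.exp(2j * np.pi * (hs @ atom.frac_pos)) * self.site_tphase[i_site]
        if atom.adp is None:
            t = np.ones(len(self.hkl))
        elif np.ndim(atom.adp) == 0:
            t = np.exp(-8.0 * np.pi**2 * float(atom.adp) * self.s2)
        else:
            beta = _TWO_PI_SQ * (
                self.nstar[:, None] * u6_to_matrix(atom.adp) * self.nstar[None, :]
            )
            t = np.exp(-np.einsum("ni,ij,nj->n", hs, beta, hs))
        gc = np.ones(len(self.hkl), dtype=complex)
        if atom.gc3 is not None:
            c = np.zeros(len(self.hkl))
            for comp, mult, (j, k, l) in zip(atom.gc3, GC3_MULTIPLICITY, GC3_INDICES):
                c += mult * comp * hs[:, j] * hs[:, k] * hs[:, l]
            gc = gc + _GC3_COEF * c
        if atom.gc4 is not None:
            d = np.zeros(len(self.hkl))
            for comp, mult, (j, k, l, m) in zip(atom.gc4, GC4_MULTIPLICITY, GC4_INDICES):
                d += mult * comp * hs[:, j] * hs[:, k] * hs[:, l] * hs[:, m]
            gc = gc + _GC4_COEF * d
        f_site = self.ff.total[i_site, self.cols]
        base = atom.occupancy * f_site * t * phase
        return atom, hs, base, gc

    def structure_factors(self, structure):
        fc = np.zeros(len(self.hkl), dtype=complex)
        for i_site in range(len(self.ff.site_ops)):
            _, _, base, gc = self._site_terms(structure, i_site)
            fc += base * gc
        return fc

    def objective(self, params, with_grad=True):
        structure, extinction = self.unpack(params)
        n_hkl = len(self.hkl)

        fc = np.zeros(n_hkl, dtype=complex)
        site_cache = []
        for i_site in range(len(self.ff.site_ops)):
            atom, hs, base, gc = self._site_terms(structure, i_site)
            fc += base * gc
            site_cache.append((atom, hs, base, gc))

        fc2 = np.abs(fc) ** 2
        if self.refine_ext:
            u = np.maximum(1.0 + extinction * self.ext_geom * fc2, 1e-10)
            y = fc2 / np.sqrt(u)
        else:
            u = None
            y = fc2

        k = optimal_scale(self.fo2, 1.0 / np.sqrt(self.w), y)
        resid = self.fo2 - k * y
        value = float(np.sum(self.w * resid**2))
        if not np.isfinite(value):
            raise FloatingPointError(
                "non-finite objective; parameter vector: " + np.array2string(params)
            )
        if not with_grad:
            return value, k

        # dR/dFc² chain: R = Σ w (Fo² − k y)², y = Fc²·u^{-1/2}
        dr_dy = -2.0 * k * self.w * resid  # envelope theorem: dk terms vanish
        if self.refine_ext:
            c = extinction * self.ext_geom
            dy_dfc2 = (1.0 + 0.5 * c * fc2) / u**1.5
        else:
            dy_dfc2 = np.ones(n_hkl)
        dr_dfc2 = dr_dy * dy_dfc2

        grad = np.zeros_like(params)
        pos = 0
        # dFc²/dp = 2·Re(conj(Fc)·dFc/dp); accumulate per block over the
        # block atom's expanded sites
        sites_of_atom = {}
        for i_site, asym_i in enumerate(self.ff.site_index):
            sites_of_atom.setdefault(int(asym_i), []).append(i_site)
        fc_conj = np.conj(fc)

        for b in self.blocks:
            if b.n_free == 0:
                continue
            dfull = np.zeros((len(b.offset), n_hkl), dtype=complex)
            for i_site in sites_of_atom.get(b.atom_index, []):
                atom, hs, base, gc = site_cache[i_site]
                if b.kind == "pos":
                    dfull += (2j * np.pi) * (base * gc)[None, :] * hs.T
                elif b.kind == "uiso":
                    dfull += (-8.0 * np.pi**2 * self.s2 * base * gc)[None, :]
                elif b.kind == "u6":
                    for m, (i, j) in enumerate(
                        ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
                    ):
                        mult = 1.0 if i == j else 2.0
                        dq = (
                            _TWO_PI_SQ
                            * mult
                            * self.nstar[i]
                            * self.nstar[j]
                            * hs[:, i]
                            * hs[:, j]
                        )
                        dfull[m] += -dq * base * gc
                elif b.kind == "gc3":
                    for m, (mult, (j, k, l)) in enumerate(
                        zip(GC3_MULTIPLICITY, GC3_INDICES)
                    ):
                        dfull[m] += (
                            _GC3_COEF * mult * hs[:, j] * hs[:, k] * hs[:, l] * base
                        )
                elif b.kind == "gc4":
                    for m, (mult, (j, k, l, q)) in enumerate(
                        zip(GC4_MULTIPLICITY, GC4_INDICES)
                    ):
                        dfull[m] += (
                            _GC4_COEF
                            * mult
                            * hs[:, j]
                            * hs[:, k]
                            * hs[:, l]
                            * hs[:, q]
                            * base
                        )
            dfc2 = 2.0 * np.real(fc_conj[None, :] * dfull)
            grad_full = dfc2 @ dr_dfc2
            grad[pos : pos + b.n_free] = b.basis.T @ grad_full
            pos += b.n_free

        if self.refine_ext:
            dy_dx = -0.5 * fc2**2 * self.ext_geom / u**1.5
            grad[pos] = float(np.sum(dr_dy * dy_dx))
        return value, k, grad

    def wr2_at(self, params) -> float:
        value, _k = self.objective(params, with_grad=False)
        return float(np.sqrt(value / self.wr2_denom))


def refine_lsq(
    structure: CrystalStructure,
    reflections: ReflectionSet,
    ff_provider,
    settings: RefinementSettings | None = None,
    extinction_start: float = 0.0,
) -> RefinementResult:
    """Constrained quasi-Newton least squares with fixed form factors.

    ``ff_provider`` is either an :class:`AtomicFormFactors` or a callable
    ``(structure, hkl) -> AtomicFormFactors`` evaluated once at the start.
    """
    settings = settings or RefinementSettings()
    ff = (
        ff_provider
        if isinstance(ff_provider, AtomicFormFactors)
        else ff_provider(structure, reflections.hkl)
    )
    model = _Model(structure, reflections, ff, settings)
    x0 = model.pack(structure, extinction_start)

    wr2_hist = []
    shift_hist = []
    last = {"x": x0.copy()}

    def fun(x):
        value, _k, grad = model.objective(x)
        return value, grad

    def callback(xk):
        wr2_hist.append(model.wr2_at(xk))
        shift_hist.append(float(np.max(np.abs(xk - last["x"]))) if xk.size else 0.0)
        last["x"] = xk.copy()

    if x0.size:
        res = minimize(
            fun,
            x0,
            jac=True,
            method="BFGS",
            callback=callback,
            options={"maxiter": settings.max_lsq_cycles, "gtol": 1e-14},
        )
        x_final = res.x
        n_cycles = res.nit
        message = res.message
    else:  # nothing refinable (fully constrained model)
        x_final = x0
        n_cycles = 0
        message = "no free parameters"

    refined, extinction = model.unpack(x_final)
    value, k = model.objective(x_final, with_grad=False)
    final_wr2 = float(np.sqrt(value / model.wr2_denom))
    wr2_hist.append(final_wr2)
    converged = (not shift_hist) or shift_hist[-1] < settings.shift_tol or (
        x0.size and n_cycles < settings.max_lsq_cycles
    )
    return RefinementResult(
        structure=refined,
        scale=k,
        extinction=extinction,
        wr2=final_wr2,
        wr2_history=wr2_hist,
        shift_history=shift_hist,
        converged=bool(converged),
        n_cycles=int(n_cycles),
        message=str(message),
    )


def har_iterate(
    structure: CrystalStructure,
    reflections: ReflectionSet,
    density_source: DensitySource,
    settings: RefinementSettings | None = None,
) -> RefinementResult:
    """Outer HAR loop: density → partition → form factors → least squares.

    Repeats until the maximum absolute parameter shift between outer
    cycles drops below ``har_shift_tol`` or ``max_har_cycles`` is reached;
    ``max_har_cycles = 0`` performs a single IAM-style refinement with the
    source's spherical pro-atom form factors.  Growing shifts over three
    consecutive cycles flag oscillation.
    """
    settings = settings or RefinementSettings()
    if settings.fsig_cutoff > 0:
        reflections = filter_significance(reflections, settings.fsig_cutoff)

    if settings.max_har_cycles == 0:
        ff = spherical_form_factors(structure, density_source, reflections.hkl)
        result = refine_lsq(structure, reflections, ff, settings)
        result.message = "IAM (spherical pro-atom form factors); " + result.message
        return result

    current = structure.copy()
    extinction = 0.0
    outer_shifts: list[float] = []
    wr2_per_cycle: list[float] = []
    result = None
    converged = False
    message = ""
    probe = _Model(current, reflections, _dummy_ff(current, reflections), settings)
    prev_params = probe.pack(current, extinction)

    for cycle in range(settings.max_har_cycles):
        ff = form_factors_from_source(
            current,
            density_source,
            reflections.hkl,
            grid_spacing=settings.grid_spacing,
            interp_factor=settings.interp_factor,
        )
        result = refine_lsq(current, reflections, ff, settings, extinction)
        current = result.structure
        extinction = result.extinction
        wr2_per_cycle.append(result.wr2)

        params = _Model(current, reflections, ff, settings).pack(current, extinction)
        shift = float(np.max(np.abs(params - prev_params))) if params.size else 0.0
        outer_shifts.append(shift)
        prev_params = params
        if shift < settings.har_shift_tol:
            converged = True
            break
        if len(outer_shifts) >= 3 and (
            outer_shifts[-1] > outer_shifts[-2] > outer_shifts[-3]
        ):
            message = "oscillating outer loop: shifts grew over 3 cycles"
            break
    else:
        message = "outer cycle cap reached"

    result.converged = converged and result.converged
    result.wr2_history = wr2_per_cycle
    result.shift_history = outer_shifts
    result.n_cycles = len(wr2_per_cycle)
    if message:
        result.message = message
    return result


def _dummy_ff(structure, reflections):
    """Zero-valence form factors used only to size the parameter vector."""
    from .crystal import expand_to_p1
    from .density import assemble_form_factors

    p1 = expand_to_p1(structure)
    hkl = reflections.hkl
    labels = [a.label for a, _ in p1]
    els = [a.element for a, _ in p1]
    zeros = {el: np.zeros(hkl.shape[0]) for el in set(els)}
    asym_labels = [a.label for a in structure.atoms]
    return assemble_form_factors(
        hkl,
        labels,
        zeros,
        els,
        np.zeros((len(labels), hkl.shape[0]), dtype=complex),
        site_index=[asym_labels.index(lbl.split("#")[0]) for lbl in labels],
        site_ops=[op for _, op in p1],
    )
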