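"""H-atom quality indicators against a neutron reference.

Covers the four standard indicators: wR2(F²), signed and absolute X—H
bond-length differences Δr, anisotropic-displacement differences ΔU_ij
against temperature-scaled neutron values, and the percent ellipsoid
dissimilarity S12, plus aggregation of the per-atom numbers into bond
classes (C—H and intra-/inter-fragment X—H⋯Y hydrogen bonds with X, Y ∈
{N, O}).

Neutron displacement parameters are corrected before comparison with the
one-scale-one-offset fit ``U_x ≈ q·U_n + ΔU`` over the non-H atoms in the
Cartesian frame (the Blessing convention): ``q`` absorbs temperature
differences between the two experiments and ``ΔU`` common offsets from
absorption or extinction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal import (
    CrystalStructure,
    frac_to_cart,
    metric_tensors,
    u_cif_to_cart,
)

__all__ = [
    "AdpScalingFit",
    "QualityReport",
    "scale_neutron_adps",
    "delta_r",
    "s12",
    "classify_bonds",
    "quality_report",
]

_U6_IJ = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
#: Frobenius weighting: off-diagonal components appear twice in the matrix
_U6_W = np.array([1.0, 1.0, 1.0, np.sqrt(2.0), np.sqrt(2.0), np.sqrt(2.0)])


@dataclass
class AdpScalingFit:
    """Result of the neutron-ADP scaling fit ``U_x ≈ q·U_n + ΔU``."""

    q: float
    delta_u: np.ndarray  # symmetric 3×3, Cartesian Å²
    residual: float  # RMS over the fitted components

    def apply(self, u_neutron_cart) -> np.ndarray:
        return self.q * np.asarray(u_neutron_cart) + self.delta_u


def scale_neutron_adps(u_xray, u_neutron) -> AdpScalingFit:
    """Least-squares fit of (q, ΔU) over paired non-H Cartesian U matrices.

    Minimizes ``Σ_atoms ‖U_x − (q·U_n + ΔU)‖²_F``; at least three pairs are
    required for the 7 unknowns.  The fit is exact (zero residual) whenever
    the inputs are related exactly.
    """
    u_xray = [np.asarray(u, dtype=float) for u in u_xray]
    u_neutron = [np.asarray(u, dtype=float) for u in u_neutron]
    if len(u_xray) != len(u_neutron):
        raise ValueError("paired U lists must have equal length")
    if len(u_xray) < 3:
        raise ValueError(
            "under-determined ADP scaling fit: need ≥ 3 paired non-H atoms"
        )
    rows, rhs = [], []
    for ux, un in zip(u_xray, u_neutron):
        for wgt, (i, j) in zip(_U6_W, _U6_IJ):
            row = np.zeros(7)
            row[0] = wgt * un[i, j]
            row[1 + _U6_IJ.index((i, j))] = wgt
            rows.append(row)
            rhs.append(wgt * ux[i, j])
    a = np.array(rows)
    b = np.array(rhs)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    q = float(sol[0])
    delta = np.zeros((3, 3))
    for comp, (i, j) in zip(sol[1:], _U6_IJ):
        delta[i, j] = comp
        delta[j, i] = comp
    resid = a @ sol - b
    return AdpScalingFit(q=q, delta_u=delta, residual=float(np.sqrt(np.mean(resid**2))))


def _bond_length(structure: CrystalStructure, label_a: str, label_b: str) -> float:
    g, _ = metric_tensors(structure.cell)
    d = structure.atom(label_b).frac_pos - structure.atom(label_a).frac_pos
    d -= np.round(d)  # nearest periodic image
    return float(np.sqrt(d @ g @ d))


def delta_r(structure_a, structure_b, bonds) -> dict:
    """Signed per-bond length differences ``r_a − r_b`` (Å).

    ``bonds`` is a list of ``(label_x, label_h)`` pairs present in both
    structures; distances are measured in each structure's own metric.
    """
    out = {}
    for lx, lh in bonds:
        try:
            ra = _bond_length(structure_a, lx, lh)
            rb = _bond_length(structure_b, lx, lh)
        except KeyError as exc:
            raise KeyError(f"bond atom {exc} not present in both structures") from exc
        out[(lx, lh)] = ra - rb
    return out


def s12(u1_cart, u2_cart) -> float:
    """Percent dissimilarity of two displacement ellipsoids.

    Overlap of the two trivariate Gaussian probability densities built from
    the inverse Cartesian displacement matrices:
    ``S12 = 100·[1 − 2^{3/2}·(det U1⁻¹ det U2⁻¹)^{1/4} / det(U1⁻¹+U2⁻¹)^{1/2}]``.
    Symmetric, zero iff the matrices coincide, and invariant under a common
    rotation.
    """
    u1 = np.asarray(u1_cart, dtype=float)
    u2 = np.asarray(u2_cart, dtype=float)
    for u in (u1, u2):
        if np.any(np.linalg.eigvalsh(u) <= 0):
            raise ValueError("displacement matrix is not positive definite")
    inv1 = np.linalg.inv(u1)
    inv2 = np.linalg.inv(u2)
    num = 2.0**1.5 * (np.linalg.det(inv1) * np.linalg.det(inv2)) ** 0.25
    den = np.linalg.det(inv1 + inv2) ** 0.5
    return float(100.0 * (1.0 - num / den))


# ---------------------------------------------------------------------------
# bond classification

#: Default geometric criteria: H⋯Y below 2.5 Å with an X—H⋯Y angle above
#: 120° and both X, Y ∈ {N, O} counts as a classical hydrogen bond.
HB_MAX_DIST = 2.5
HB_MIN_ANGLE = 120.0
COVALENT_MAX = 1.3
_HEAVY_BOND_MAX = 1.8


def _periodic_vector(structure, label_a, label_b):
    d = structure.atom(label_b).frac_pos - structure.atom(label_a).frac_pos
    d -= np.round(d)
    return frac_to_cart(d, structure.cell)


def _default_fragments(structure: CrystalStructure) -> dict:
    """Connected components of the covalent network (periodic distances)."""
    labels = [a.label for a in structure.atoms]
    adj = {lbl: set() for lbl in labels}
    for i, a in enumerate(structure.atoms):
        for b in structure.atoms[i + 1 :]:
            cut = COVALENT_MAX if "H" in (a.element, b.element) else _HEAVY_BOND_MAX
            if np.linalg.norm(_periodic_vector(structure, a.label, b.label)) < cut:
                adj[a.label].add(b.label)
                adj[b.label].add(a.label)
    frag, fid = {}, 0
    for lbl in labels:
        if lbl in frag:
            continue
        stack = [lbl]
        while stack:
            cur = stack.pop()
            if cur in frag:
                continue
            frag[cur] = fid
            stack.extend(adj[cur])
        fid += 1
    return frag


def classify_bonds(
    structure: CrystalStructure,
    fragments: dict | None = None,
    hb_max_dist: float = HB_MAX_DIST,
    hb_min_angle: float = HB_MIN_ANGLE,
) -> dict:
    """Partition the H atoms into {C—H, intra X—H⋯Y, inter X—H⋯Y}.

    Each H atom is attached to its nearest non-H neighbour within 1.3 Å
    (H atoms without one are excluded with a warning).  A donor X ∈ {N, O}
    with an acceptor Y ∈ {N, O} satisfying the distance/angle criteria is a
    hydrogen bond, classed intra or inter by the fragment assignment
    (connected covalent components by default); X—H donors without an
    acceptor are excluded with a warning since they match no class of the
    narrow classical criterion.

    Returns ``{class label: [(X label, H label), ...]}``.
    """
    if fragments is None:
        fragments = _default_fragments(structure)
    classes = {"C-H": [], "intra X-H...Y": [], "inter X-H...Y": []}
    for h in structure.atoms:
        if h.element != "H":
            continue
        partners = [
            (np.linalg.norm(_periodic_vector(structure, h.label, a.label)), a)
            for a in structure.atoms
            if a.element != "H" and a.label != h.label
        ]
        partners = [(d, a) for d, a in partners if d < COVALENT_MAX]
        if not partners:
            warnings.warn(f"H atom {h.label} has no covalent partner within 1.3 Å")
            continue
        _, donor = min(partners, key=lambda t: t[0])
        if donor.element not in ("N", "O"):
            classes["C-H"].append((donor.label, h.label))
            continue
        # hydrogen-bond acceptor search
        best = None
        for y in structure.atoms:
            if y.element not in ("N", "O") or y.label in (donor.label, h.label):
                continue
            v_hy = _periodic_vector(structure, h.label, y.label)
            d_hy = np.linalg.norm(v_hy)
            if d_hy >= hb_max_dist:
                continue
            v_hx = _periodic_vector(structure, h.label, donor.label)
            cosang = v_hx @ v_hy / (np.linalg.norm(v_hx) * d_hy)
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle <= hb_min_angle:
                continue
            if best is None or d_hy < best[0]:
                best = (d_hy, y)
        if best is None:
            warnings.warn(
                f"{donor.label}-{h.label} donates no classical hydrogen bond; "
                "excluded from bond-class aggregation"
            )
            continue
        same = fragments.get(donor.label) == fragments.get(best[1].label)
        key = "intra X-H...Y" if same else "inter X-H...Y"
        classes[key].append((donor.label, h.label))
    return classes


# ---------------------------------------------------------------------------
# aggregated report

def _summary(values, sigmas=None):
    """Median/quartile summary with 1.5×IQR whisker bounds.

    Quartiles use the inclusive median-unbiased convention; the σ-scaled
    mean uses per-value reference uncertainties (1 when not supplied).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return {"n": 0}
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="median_unbiased")
    iqr = q3 - q1
    sig = np.ones_like(v) if sigmas is None else np.asarray(sigmas, dtype=float)
    return {
        "n": int(v.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
        "mean_abs": float(np.mean(np.abs(v))),
        "mean_abs_over_sigma": float(np.mean(np.abs(v) / sig)),
    }


@dataclass
class QualityReport:
    wr2: float
    adp_fit: AdpScalingFit
    delta_r: dict  # (X, H) -> signed Å
    delta_u: dict  # H label -> 6-vector of ΔU_ij (Cartesian components, Å²)
    s12: dict  # H label -> percent
    classes: dict  # class label -> list of (X, H)
    class_summaries: dict

    def to_dict(self) -> dict:
        return {
            "wr2": self.wr2,
            "adp_scaling": {
                "q": self.adp_fit.q,
                "delta_u_cart": self.adp_fit.delta_u.tolist(),
                "residual": self.adp_fit.residual,
            },
            "delta_r": {f"{x}-{h}": v for (x, h), v in self.delta_r.items()},
            "delta_u": {k: list(v) for k, v in self.delta_u.items()},
            "s12": dict(self.s12),
            "classes": {k: [f"{x}-{h}" for x, h in v] for k, v in self.classes.items()},
            "class_summaries": self.class_summaries,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"wR2(F^2) = {self.wr2:.4f}",
                 f"neutron ADP scaling: q = {self.adp_fit.q:.4f}, "
                 f"fit RMS = {self.adp_fit.residual:.2e} A^2",
                 "", "bond       class            dr [A]      S12 [%]"]
        class_of = {}
        for cls, members in self.classes.items():
            for pair in members:
                class_of[pair] = cls
        for (x, h), dr in sorted(self.delta_r.items()):
            cls = class_of.get((x, h), "-")
            lines.append(
                f"{x + '-' + h:<10} {cls:<16} {dr:+.4f}     "
                f"{self.s12.get(h, float('nan')):8.3f}"
            )
        return "\n".join(lines)


def quality_report(
    refined: CrystalStructure,
    neutron_ref: CrystalStructure,
    reflections=None,
    fc=None,
    scale: float | None = None,
    sigma_r: dict | None = None,
    sigma_u: dict | None = None,
    fragments: dict | None = None,
) -> QualityReport:
    """Assemble the full indicator set for a refined structure.

    ``sigma_r``/``sigma_u`` optionally carry the neutron-refinement
    standard uncertainties used for σ-scaled aggregation (defaults of 1
    leave the deviations unscaled).
    """
    from .scattering import optimal_scale, wr2 as wr2_fn

    if reflections is not None and fc is not None:
        fc2 = np.abs(np.asarray(fc)) ** 2
        k = optimal_scale(reflections.fo2, reflections.sigma, fc2) if scale is None else scale
        wr2_value = wr2_fn(reflections.fo2, reflections.sigma, fc2, k)
    else:
        wr2_value = float("nan")

    # Blessing scaling over paired non-H atoms with anisotropic ADPs
    pairs = []
    for atom in refined.atoms:
        if atom.element == "H" or not atom.is_anisotropic:
            continue
        try:
            ref_atom = neutron_ref.atom(atom.label)
        except KeyError:
            continue
        if not ref_atom.is_anisotropic:
            continue
        pairs.append(
            (
                u_cif_to_cart(atom.adp, refined.cell),
                u_cif_to_cart(ref_atom.adp, neutron_ref.cell),
            )
        )
    if len(pairs) >= 3:
        fit = scale_neutron_adps([p[0] for p in pairs], [p[1] for p in pairs])
    else:
        warnings.warn(
            "fewer than 3 paired non-H anisotropic atoms: neutron ADPs "
            "compared unscaled (q = 1, ΔU = 0)"
        )
        fit = AdpScalingFit(q=1.0, delta_u=np.zeros((3, 3)), residual=float("nan"))

    classes = classify_bonds(refined, fragments=fragments)
    bonds = [pair for members in classes.values() for pair in members]
    dr = delta_r(refined, neutron_ref, bonds)

    du, s12_vals = {}, {}
    for atom in refined.atoms:
        if atom.element != "H" or not atom.is_anisotropic:
            continue
        try:
            ref_atom = neutron_ref.atom(atom.label)
        except KeyError:
            continue
        if not ref_atom.is_anisotropic:
            continue
        ux = u_cif_to_cart(atom.adp, refined.cell)
        un = fit.apply(u_cif_to_cart(ref_atom.adp, neutron_ref.cell))
        diff = ux - un
        du[atom.label] = np.array([diff[i, j] for i, j in _U6_IJ])
        s12_vals[atom.label] = s12(ux, un)

    class_summaries = {}
    for cls, members in classes.items():
        drs = [dr[pair] for pair in members if pair in dr]
        sig = (
            [sigma_r.get(pair, 1.0) for pair in members if pair in dr]
            if sigma_r
            else None
        )
        class_summaries[cls] = {"delta_r": _summary(drs, sig)}
        dus = np.concatenate(
            [du[h] for _x, h in members if h in du]
        ) if any(h in du for _x, h in members) else np.array([])
        sig_u = (
            np.concatenate([np.full(6, sigma_u.get(h, 1.0)) for _x, h in members if h in du])
            if sigma_u and dus.size
            else None
        )
        class_summaries[cls]["delta_u"] = _summary(dus, sig_u)

    return QualityReport(
        wr2=wr2_value,
        adp_fit=fit,
        delta_r=dr,
        delta_u=du,
        s12=s12_vals,
        classes=classes,
        class_summaries=class_summaries,
    )
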