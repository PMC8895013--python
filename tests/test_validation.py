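"""Neutron-comparison metrics: Blessing fit, Δr, S12, bond classes."""

import numpy as np
import pytest

from gridhar.crystal import Atom, CrystalStructure, SymmetryOp, UnitCell, u_cart_to_cif
from gridhar.validation import (
    classify_bonds,
    delta_r,
    quality_report,
    s12,
    scale_neutron_adps,
)


def _random_spd(rng, scale=0.02):
    a = rng.normal(0, scale, (3, 3))
    return a @ a.T + scale * np.eye(3)


class TestAdpScaling:
    def test_identity_inputs(self):
        rng = np.random.default_rng(0)
        us = [_random_spd(rng) for _ in range(4)]
        fit = scale_neutron_adps(us, us)
        assert fit.q == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.delta_u, 0.0, atol=1e-12)
        assert fit.residual < 1e-14

    def test_exact_recovery_of_constructed_relation(self):
        rng = np.random.default_rng(1)
        u_n = [_random_spd(rng) for _ in range(5)]
        delta = np.diag([0.002, 0.001, 0.003])
        u_x = [1.07 * u + delta for u in u_n]
        fit = scale_neutron_adps(u_x, u_n)
        assert fit.q == pytest.approx(1.07, abs=1e-12)
        assert np.allclose(fit.delta_u, delta, atol=1e-12)
        assert fit.residual < 1e-14
        assert np.allclose(fit.apply(u_n[0]), u_x[0], atol=1e-12)

    def test_underdetermined_errors(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="under-determined"):
            scale_neutron_adps([_random_spd(rng)], [_random_spd(rng)])

    def test_q_recovery_unbiased_on_noisy_inputs(self):
        # 100 seeded replicates: mean q within 2 standard errors of truth
        rng = np.random.default_rng(3)
        q_true = 1.05
        qs = []
        for _ in range(100):
            u_n = [_random_spd(rng) for _ in range(6)]
            u_x = [
                q_true * u + np.diag([0.001, 0.002, 0.0015])
                + 1e-4 * rng.normal(size=(3, 3))
                for u in u_n
            ]
            u_x = [0.5 * (u + u.T) for u in u_x]
            qs.append(scale_neutron_adps(u_x, u_n).q)
        se = np.std(qs) / 10.0
        assert abs(np.mean(qs) - q_true) < 2 * se + 1e-4


class TestDeltaR:
    def _pair(self):
        cell = UnitCell(8, 8, 8)
        a = CrystalStructure(
            cell, [SymmetryOp.identity()],
            [Atom("O1", "O", [0.2, 0.2, 0.2]), Atom("H1", "H", [0.2 + 0.96 / 8, 0.2, 0.2])],
        )
        b = a.copy()
        return a, b

    def test_identical_structures_zero(self):
        a, b = self._pair()
        assert delta_r(a, b, [("O1", "H1")])[("O1", "H1")] == pytest.approx(0.0)

    def test_displacement_along_bond(self):
        a, b = self._pair()
        a.atom("H1").frac_pos = a.atom("H1").frac_pos + [0.01 / 8, 0, 0]
        assert delta_r(a, b, [("O1", "H1")])[("O1", "H1")] == pytest.approx(0.01)

    def test_antisymmetric_and_triclinic_metric_oracle(self):
        cell = UnitCell(6.2, 7.1, 8.3, 82, 95, 101)
        x, h = np.array([0.11, 0.52, 0.33]), np.array([0.19, 0.48, 0.40])
        a = CrystalStructure(cell, [SymmetryOp.identity()],
                             [Atom("N1", "N", x), Atom("H1", "H", h)])
        b = a.copy()
        b.atom("H1").frac_pos = h + np.array([0.004, -0.003, 0.002])
        d_ab = delta_r(a, b, [("N1", "H1")])[("N1", "H1")]
        d_ba = delta_r(b, a, [("N1", "H1")])[("N1", "H1")]
        assert d_ab == pytest.approx(-d_ba, abs=1e-14)
        from gridhar.crystal import frac_to_cart

        want = np.linalg.norm(frac_to_cart(h - x, cell)) - np.linalg.norm(
            frac_to_cart(b.atom("H1").frac_pos - x, cell)
        )
        assert d_ab == pytest.approx(want, abs=1e-10)

    def test_unmatched_label_errors(self):
        a, b = self._pair()
        with pytest.raises(KeyError):
            delta_r(a, b, [("O1", "H9")])


class TestS12:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(5)
        u1, u2 = _random_spd(rng), _random_spd(rng)
        assert s12(u1, u1) == pytest.approx(0.0, abs=1e-10)
        assert s12(u1, u2) == pytest.approx(s12(u2, u1), abs=1e-12)
        assert s12(u1, u2) > 0

    def test_rotation_invariance(self):
        from scipy.stats import special_ortho_group

        rng = np.random.default_rng(6)
        u1, u2 = _random_spd(rng), _random_spd(rng)
        r = special_ortho_group.rvs(3, random_state=7)
        assert s12(r @ u1 @ r.T, r @ u2 @ r.T) == pytest.approx(s12(u1, u2), abs=1e-10)

    def test_matches_numeric_gaussian_overlap(self):
        # 3-D quadrature oracle: S12 = 100·(1 − ∫√(p1·p2) dV) for the
        # normal densities N(0, U1), N(0, U2)
        u1 = np.diag([0.02, 0.015, 0.025])
        u2 = 1.6 * u1
        lim = 6 * np.sqrt(0.04)
        n = 101
        x = np.linspace(-lim, lim, n)
        xg, yg, zg = np.meshgrid(x, x, x, indexing="ij")
        pts = np.stack([xg, yg, zg], axis=-1)

        def gauss(u):
            inv = np.linalg.inv(u)
            norm = (2 * np.pi) ** -1.5 * np.linalg.det(u) ** -0.5
            expo = np.einsum("...i,ij,...j->...", pts, inv, pts)
            return norm * np.exp(-0.5 * expo)

        integrand = np.sqrt(gauss(u1) * gauss(u2))
        dv = (x[1] - x[0]) ** 3
        overlap = integrand.sum() * dv
        assert s12(u1, u2) == pytest.approx(100 * (1 - overlap), abs=1e-4)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            s12(np.diag([0.01, -0.01, 0.01]), np.eye(3) * 0.01)


class TestClassifyBonds:
    def test_methane_like_fragment_all_ch(self):
        cell = UnitCell(10, 10, 10)
        c = np.array([0.5, 0.5, 0.5])
        atoms = [Atom("C1", "C", c)]
        d = 1.09 / 10 / np.sqrt(3)
        for i, sign in enumerate([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]):
            atoms.append(Atom(f"H{i+1}", "H", c + d * np.array(sign)))
        s = CrystalStructure(cell, [SymmetryOp.identity()], atoms)
        classes = classify_bonds(s)
        assert len(classes["C-H"]) == 4
        assert not classes["intra X-H...Y"] and not classes["inter X-H...Y"]

    def _dimer(self, o2_distance):
        # water dimer toy: O1-H1 donates toward O2 at the given H⋯Y length
        cell = UnitCell(12, 12, 12)
        o1 = np.array([0.3, 0.5, 0.5])
        h1 = o1 + np.array([0.96 / 12, 0, 0])
        o2 = h1 + np.array([o2_distance / 12, 0, 0])  # angle exactly 180°
        atoms = [
            Atom("O1", "O", o1), Atom("H1", "H", h1), Atom("O2", "O", o2),
            Atom("H2", "H", o2 + np.array([0, 0.96 / 12, 0])),
        ]
        return CrystalStructure(cell, [SymmetryOp.identity()], atoms)

    def test_dimer_inter_hydrogen_bond(self):
        classes = classify_bonds(self._dimer(1.9))
        assert ("O1", "H1") in classes["inter X-H...Y"]

    def test_stretched_contact_is_not_a_bond(self):
        with pytest.warns(UserWarning, match="no classical hydrogen bond"):
            classes = classify_bonds(self._dimer(3.5))
        assert ("O1", "H1") not in classes["inter X-H...Y"]

    def test_intra_when_fragments_shared(self):
        classes = classify_bonds(self._dimer(1.9), fragments={
            "O1": 0, "H1": 0, "O2": 0, "H2": 0,
        })
        assert ("O1", "H1") in classes["intra X-H...Y"]

    def test_orphan_h_warns(self):
        s = CrystalStructure(
            UnitCell(10, 10, 10), [SymmetryOp.identity()],
            [Atom("H1", "H", [0.1, 0.1, 0.1]), Atom("C1", "C", [0.6, 0.6, 0.6])],
        )
        with pytest.warns(UserWarning, match="covalent partner"):
            classify_bonds(s)


class TestQualityReport:
    def _structures(self):
        cell = UnitCell(9, 9, 9)
        heavy_u = [
            np.array([0.010, 0.012, 0.011, 0.001, -0.001, 0.002]),
            np.array([0.013, 0.009, 0.012, -0.002, 0.001, 0.001]),
            np.array([0.011, 0.011, 0.010, 0.002, 0.002, -0.001]),
        ]
        # O1-H1 donates a near-linear hydrogen bond to N1 (H⋯N ≈ 2.0 Å)
        o1 = np.array([0.30, 0.50, 0.50])
        atoms = [
            Atom("O1", "O", o1, adp=heavy_u[0]),
            Atom("C1", "C", [0.50, 0.72, 0.50], adp=heavy_u[1]),
            Atom("N1", "N", [0.62, 0.45, 0.50], adp=heavy_u[2]),
            Atom("H1", "H", o1 + [0.96 / 9, 0, 0],
                 adp=np.array([0.03, 0.025, 0.028, 0.002, 0.001, -0.001])),
        ]
        refined = CrystalStructure(cell, [SymmetryOp.identity()], atoms)
        return refined, refined.copy()

    def test_identical_structures_zero_deviations(self):
        refined, reference = self._structures()
        report = quality_report(refined, reference)
        assert all(abs(v) < 1e-12 for v in report.delta_r.values())
        assert all(abs(v) < 1e-8 for v in report.s12.values())
        assert report.adp_fit.q == pytest.approx(1.0, abs=1e-10)

    def test_summaries_match_order_statistics_oracle(self):
        refined, reference = self._structures()
        # displace H along the bond and check the class summary numbers
        refined.atom("H1").frac_pos = refined.atom("H1").frac_pos + [0.008 / 9, 0, 0]
        report = quality_report(refined, reference)
        # H1 donates O1-H1...C? no: Y must be N/O; N1 at 2.2 Å from H1
        values = sorted(report.delta_r.values())
        for cls, summ in report.class_summaries.items():
            if summ["delta_r"].get("n"):
                drs = [report.delta_r[p] for p in report.classes[cls]]
                assert summ["delta_r"]["median"] == pytest.approx(np.median(drs))
                q1, q3 = np.quantile(drs, [0.25, 0.75], method="median_unbiased")
                assert summ["delta_r"]["q1"] == pytest.approx(q1)
                assert summ["delta_r"]["whisker_high"] == pytest.approx(
                    q3 + 1.5 * (q3 - q1)
                )

    def test_sigma_scaling_defaults_to_raw(self):
        refined, reference = self._structures()
        refined.atom("H1").frac_pos = refined.atom("H1").frac_pos + [0.005 / 9, 0, 0]
        report = quality_report(refined, reference)
        for summ in report.class_summaries.values():
            if summ["delta_r"].get("n"):
                assert summ["delta_r"]["mean_abs_over_sigma"] == pytest.approx(
                    summ["delta_r"]["mean_abs"]
                )

    def test_json_round_trip(self):
        import json

        refined, reference = self._structures()
        report = quality_report(refined, reference)
        loaded = json.loads(report.to_json())
        assert "wr2" in loaded and "class_summaries" in loaded
        assert report.to_text()
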