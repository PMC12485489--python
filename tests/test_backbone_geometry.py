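"""Dihedral math, covalent z-scores, chain breaks and the builder round-trip."""

import math

import numpy as np
import pytest

from barbedwire.backbone_geometry import (
    GeometryTargets,
    ResidueSpec,
    analyze_backbone,
    build_backbone,
    compute_dihedral,
)
from barbedwire.fixtures import transform
from barbedwire.structure_io import Structure


def ideal_chain(n, phi=-57.0, psi=-47.0, omega=180.0, **kwargs):
    return build_backbone(
        [ResidueSpec("ALA", phi, psi, omega) for _ in range(n)], **kwargs
    )


class TestComputeDihedral:
    def test_trans_peptide_is_180(self):
        st = ideal_chain(3)
        g = analyze_backbone(st)["A"]
        assert g[1].omega == pytest.approx(180.0, abs=1e-9)
        assert g[2].omega == pytest.approx(180.0, abs=1e-9)

    def test_mirror_negates_dihedral(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 3
            d = compute_dihedral(*pts)
            d_mirror = compute_dihedral(*(-pts))
            if abs(d) == pytest.approx(180.0):
                continue
            assert d_mirror == pytest.approx(-d, abs=1e-9)

    def test_collinear_points_undefined(self):
        p = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
        assert math.isnan(compute_dihedral(*p))

    def test_builder_dihedral_recovered(self):
        st = build_backbone([ResidueSpec("ALA", -75.0, 150.0, 180.0)] * 4)
        g = analyze_backbone(st)["A"]
        assert g[1].phi == pytest.approx(-75.0, abs=1e-6)
        assert g[1].psi == pytest.approx(150.0, abs=1e-6)


class TestAnalyzeBackbone:
    def test_ideal_helix_zero_zscores_trans_omegas(self):
        g = analyze_backbone(ideal_chain(6))["A"]
        for i in range(1, 5):
            assert g[i].omega == pytest.approx(180.0, abs=1e-9)
            for name, z in g[i].bond_z.items():
                assert abs(z) < 1e-9, f"{name} z={z}"

    def test_cnca_override_gives_minus_four_z(self):
        spec = [ResidueSpec("ALA", -57.0, -47.0, 180.0) for _ in range(5)]
        targets = GeometryTargets.load()
        spec[2].overrides["C-N-CA"] = targets.ideal("C-N-CA") - 4 * targets.sigma(
            "C-N-CA"
        )
        g = analyze_backbone(build_backbone(spec))["A"]
        assert g[2].bond_z["C-N-CA"] == pytest.approx(-4.0, abs=1e-9)
        assert g[1].bond_z.get("C-N-CA", 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_gap_declares_chain_break_and_kills_dihedrals(self):
        a = ideal_chain(3)
        b = ideal_chain(3, start_seq=4)
        transform(b, None, np.array([50.0, 0.0, 0.0]))
        st = Structure()
        st.chains["A"] = a.chains["A"] + b.chains["A"]
        g = analyze_backbone(st)["A"]
        assert g[3].chain_break_before and g[2].chain_break_after
        assert math.isnan(g[3].phi)
        assert math.isnan(g[3].omega)
        assert math.isnan(g[2].psi)
        assert "C-N-CA" not in g[3].bond_z

    def test_cis_omega_roundtrip(self):
        spec = [ResidueSpec(), ResidueSpec(omega=10.0), ResidueSpec()]
        g = analyze_backbone(build_backbone(spec))["A"]
        assert g[1].omega == pytest.approx(10.0, abs=1e-6)


class TestBuildBackbone:
    def test_helix_ca_spacing(self):
        st = ideal_chain(10)
        ca = [r.atom("CA").position for r in st.chains["A"]]
        for i in range(7):
            assert 5.0 <= np.linalg.norm(ca[i + 3] - ca[i]) <= 5.4

    def test_ppii_geometry_recovered_exactly(self):
        st = build_backbone([ResidueSpec("PRO", -75.0, 150.0, 180.0)] * 8)
        g = analyze_backbone(st)["A"]
        for i in range(1, 7):
            assert g[i].phi == pytest.approx(-75.0, abs=1e-6)
            assert g[i].psi == pytest.approx(150.0, abs=1e-6)

    def test_nonpositive_bond_override_rejected(self):
        with pytest.raises(ValueError):
            ResidueSpec(overrides={"C-N": -1.0})

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError):
            ResidueSpec(overrides={"X-Y": 1.0})

    def test_random_spec_roundtrip(self):
        """build -> analyze recovers 100 random dihedral/override specs."""
        rng = np.random.default_rng(42)
        targets = GeometryTargets.load()
        for _ in range(100):
            n = int(rng.integers(3, 9))
            specs = []
            for i in range(n):
                s = ResidueSpec(
                    "ALA",
                    float(rng.uniform(-179, 179)),
                    float(rng.uniform(-179, 179)),
                    float(rng.uniform(-179, 179)),
                )
                if rng.random() < 0.3 and i > 0:
                    name = str(rng.choice(["C-N-CA", "CA-C-N", "C-N"]))
                    s.overrides[name] = targets.ideal(name) + float(
                        rng.uniform(-4, 4)
                    ) * targets.sigma(name)
                specs.append(s)
            g = analyze_backbone(build_backbone(specs))["A"]
            for i in range(n):
                if i > 0:
                    assert g[i].phi == pytest.approx(specs[i].phi, abs=1e-6)
                    assert g[i].omega == pytest.approx(specs[i].omega, abs=1e-6)
                if i < n - 1:
                    assert g[i].psi == pytest.approx(specs[i].psi, abs=1e-6)
                for name, value in specs[i].overrides.items():
                    targets_z = (value - targets.ideal(name)) / targets.sigma(name)
                    assert g[i].bond_z[name] == pytest.approx(targets_z, abs=1e-6)


class TestRigidMotionInvariance:
    def test_dihedrals_angles_z_unchanged(self):
        st = ideal_chain(8)
        ref = analyze_backbone(st)["A"]
        theta = 1.1
        R = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        moved = analyze_backbone(transform(st, R, np.array([5.0, -3.0, 9.0])))["A"]
        for a, b in zip(ref, moved):
            for field in ("phi", "psi", "omega", "ca_angle", "ca_dihedral_in"):
                va, vb = getattr(a, field), getattr(b, field)
                if math.isnan(va):
                    assert math.isnan(vb)
                else:
                    assert vb == pytest.approx(va, abs=1e-9)
            for name in a.bond_z:
                assert b.bond_z[name] == pytest.approx(a.bond_z[name], abs=1e-9)
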