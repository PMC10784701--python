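"""Domain rotation, screw decomposition, displacement fields, dihedrals."""

from __future__ import annotations

import numpy as np
import pytest

from conforma.model import AtomRecord, DomainDefinition, Residue, ResidueKey, StructureModel
from conforma.motion import (
    backbone_dihedrals,
    center_of_mass,
    circular_delta,
    decompose_transform,
    difference_field,
    displacement_field,
    domain_anchored_fit,
    domain_rotation,
    kink_delta,
)
from conforma.synth import ToyStructureSpec, build_helix, make_two_domain_pair

from tests._oracles import random_rotation


class TestDomainAnchoredFit:
    def test_identical_models_give_identity(self, toy_pair, toy_domains):
        open_model, _, _ = toy_pair
        fitted, result = domain_anchored_fit(open_model, open_model, toy_domains["A"])
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_anchor_superposes_after_hinge(self, toy_pair, toy_domains):
        open_model, closed_model, _ = toy_pair
        _fitted, result = domain_anchored_fit(open_model, closed_model, toy_domains["A"])
        assert result.rmsd < 0.01


class TestDomainRotation:
    def test_recovers_planted_hinge_angle_and_axis(self, toy_pair, toy_domains):
        open_model, closed_model, truth = toy_pair
        fitted, _ = domain_anchored_fit(open_model, closed_model, toy_domains["A"])
        motion = domain_rotation(open_model, fitted, toy_domains["B"])
        assert motion.angle_deg == pytest.approx(truth["theta_deg"], abs=0.05)
        assert abs(motion.axis @ np.array(truth["axis"])) > 0.999

    def test_identical_models_angle_zero_axis_undefined(self, toy_pair, toy_domains):
        open_model, _, _ = toy_pair
        motion = domain_rotation(open_model, open_model, toy_domains["B"])
        assert motion.angle_deg == pytest.approx(0.0, abs=1e-6)
        assert not motion.axis_defined
        assert "near identity" in motion.note

    def test_recomposition_reproduces_mobile_coordinates(self, toy_pair, toy_domains):
        open_model, closed_model, _ = toy_pair
        fitted, _ = domain_anchored_fit(open_model, closed_model, toy_domains["A"])
        motion = domain_rotation(open_model, fitted, toy_domains["B"])
        ref_ca = np.array(
            [r.ca.coords for r in open_model.chain("A")[40:]]
        )
        mob_ca = np.array([r.ca.coords for r in fitted.chain("A")[40:]])
        assert np.abs(motion.apply(ref_ca) - mob_ca).max() < 1e-4

    def test_frame_invariance(self, toy_domains, rng):
        spec = ToyStructureSpec(theta_deg=9.0)
        open_model, closed_model, _ = make_two_domain_pair(spec)
        R = random_rotation(rng)
        t = rng.normal(0, 20, 3)

        def measure(ref, mob):
            fitted, _ = domain_anchored_fit(ref, mob, toy_domains["A"])
            rot = domain_rotation(ref, fitted, toy_domains["B"])
            disp = displacement_field(ref, fitted, toy_domains["B"])
            return rot.angle_deg, disp.magnitudes

        a0, m0 = measure(open_model, closed_model)
        a1, m1 = measure(open_model.transform(R, t), closed_model.transform(R, t))
        assert a1 == pytest.approx(a0, abs=1e-6)
        assert np.abs(m1 - m0).max() < 1e-6


class TestScrewDecomposition:
    @pytest.mark.parametrize("angle", [3.0, 45.0, 120.0, 179.5])
    def test_round_trip_through_decomposition(self, angle, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        from conforma.motion import _axis_angle_matrix

        R = _axis_angle_matrix(axis, np.deg2rad(angle))
        t = rng.normal(0, 5, 3)
        motion = decompose_transform(R, t)
        pts = rng.normal(0, 10, (20, 3))
        assert np.abs(motion.apply(pts) - (pts @ R.T + t)).max() < 1e-6
        assert motion.angle_deg == pytest.approx(angle, abs=1e-6)

    def test_near_identity_flagged(self):
        motion = decompose_transform(np.eye(3), np.array([1.0, 2.0, 2.0]))
        assert motion.angle_deg == pytest.approx(0.0)
        assert motion.axis is None
        assert motion.screw_shift == pytest.approx(3.0)


class TestDisplacementField:
    def test_identical_models_zero_field(self, toy_pair, toy_domains):
        open_model, _, _ = toy_pair
        field = displacement_field(open_model, open_model, toy_domains["B"])
        assert field.stats["max"] == pytest.approx(0.0, abs=1e-12)

    def test_chord_law_per_residue(self, toy_domains):
        # residue at perpendicular distance r from a theta hinge moves by
        # the chord 2 r sin(theta/2)
        for theta in (2.0, 12.0, 30.0):
            open_model, closed_model, truth = make_two_domain_pair(
                ToyStructureSpec(theta_deg=theta)
            )
            fitted, _ = domain_anchored_fit(open_model, closed_model, toy_domains["A"])
            field = displacement_field(open_model, fitted, toy_domains["B"])
            half = np.deg2rad(theta) / 2.0
            for key, _vec, mag in field.entries:
                r = truth["axis_radii"][key.seq_num]
                assert mag == pytest.approx(2.0 * r * np.sin(half), abs=1e-3)

    def test_difference_with_itself_is_zero(self, toy_pair, toy_domains):
        open_model, closed_model, _ = toy_pair
        fitted, _ = domain_anchored_fit(open_model, closed_model, toy_domains["A"])
        field = displacement_field(open_model, fitted, toy_domains["B"])
        diff = difference_field(field, field)
        assert diff.stats["max"] == pytest.approx(0.0, abs=1e-12)

    def test_noise_difference_matches_monte_carlo_oracle(self, toy_domains):
        # two fields against a shared reference, each closed copy carrying
        # independent N(0, sigma^2) noise per coordinate: the difference is
        # N(0, 2 sigma^2 I3); its mean magnitude is checked against a
        # 10^4-draw Monte-Carlo estimate rather than a closed form
        sigma = 0.5
        spec = ToyStructureSpec(n_res_domain_a=80, n_res_domain_b=80, theta_deg=12.0)
        open_model, closed_model, _ = make_two_domain_pair(spec)
        rng = np.random.default_rng(77)
        domain_a = DomainDefinition("a", [("A", 1, 80)])
        domain_b = DomainDefinition("b", [("A", 81, 160)])

        fields = []
        for _ in range(2):
            noisy = closed_model.copy()
            for res in noisy.chain("A"):
                for atom in res.heavy_atoms():
                    atom.coords = atom.coords + rng.normal(0, sigma, 3)
            fitted, _ = domain_anchored_fit(open_model, noisy, domain_a)
            fields.append(displacement_field(open_model, fitted, domain_b))
        diff = difference_field(fields[0], fields[1])

        draws = np.linalg.norm(
            np.random.default_rng(4242).normal(0, sigma * np.sqrt(2), (10_000, 3)),
            axis=1,
        )
        # anchored refits absorb part of the noise; 15% brackets both the
        # refit shrinkage and the 160-residue sampling error
        assert diff.stats["mean"] == pytest.approx(draws.mean(), rel=0.15)

    def test_empty_intersection_raises(self, toy_pair, toy_domains):
        open_model, closed_model, _ = toy_pair
        fitted, _ = domain_anchored_fit(open_model, closed_model, toy_domains["A"])
        f1 = displacement_field(open_model, fitted, DomainDefinition("x", [("A", 41, 50)]))
        f2 = displacement_field(open_model, fitted, DomainDefinition("y", [("A", 60, 70)]))
        with pytest.raises(ValueError, match="intersect"):
            difference_field(f1, f2)


class TestCenterOfMass:
    def _single(self, element: str, coords) -> StructureModel:
        res = Residue(
            ResidueKey("A", 1, "", "UNK"),
            {"X1": AtomRecord("X1", element, np.asarray(coords, float))},
        )
        return StructureModel("m", {"A": [res]})

    def test_single_atom(self):
        model = self._single("C", [1.0, 2.0, 3.0])
        d = DomainDefinition("d", [("A", 1, 1)])
        assert np.allclose(center_of_mass(model, d), [1, 2, 3])

    def test_two_equal_atoms_balance_at_origin(self):
        res = Residue(
            ResidueKey("A", 1, "", "UNK"),
            {
                "C1": AtomRecord("C1", "C", np.array([1.0, 0, 0])),
                "C2": AtomRecord("C2", "C", np.array([-1.0, 0, 0])),
            },
        )
        model = StructureModel("m", {"A": [res]})
        d = DomainDefinition("d", [("A", 1, 1)])
        assert np.allclose(center_of_mass(model, d), [0, 0, 0])

    def test_mass_weighting_shifts_toward_sulfur(self):
        res = Residue(
            ResidueKey("A", 1, "", "UNK"),
            {
                "C1": AtomRecord("C1", "C", np.array([0.0, 0, 0])),
                "S1": AtomRecord("S1", "S", np.array([2.0, 0, 0])),
            },
        )
        model = StructureModel("m", {"A": [res]})
        d = DomainDefinition("d", [("A", 1, 1)])
        geo = center_of_mass(model, d, "geometric")
        mass = center_of_mass(model, d, "mass")
        assert geo[0] == pytest.approx(1.0)
        # hand arithmetic: 2 * 32.06 / (12.011 + 32.06)
        assert mass[0] == pytest.approx(2 * 32.06 / 44.071, abs=1e-6)


class TestBackboneDihedrals:
    def test_helix_dihedrals_recovered_exactly(self):
        series = backbone_dihedrals(build_helix(10, phi=-57.0, psi=-47.0), "A")
        for num in range(2, 10):
            assert series.phi(num) == pytest.approx(-57.0, abs=0.01)
            assert series.psi(num) == pytest.approx(-47.0, abs=0.01)

    def test_termini_undefined(self):
        series = backbone_dihedrals(build_helix(5), "A")
        assert series.phi(1) is None
        assert series.psi(5) is None

    def test_numbering_gap_splits_segments(self):
        model = build_helix(10)
        model.chains["A"] = [r for r in model.chain("A") if r.key.seq_num not in (5, 6)]
        series = backbone_dihedrals(model, "A")
        # residue 4 ends a segment, residue 7 starts one
        assert series.psi(4) is None
        assert series.phi(7) is None
        assert series.phi(4) is not None
        assert series.psi(7) is not None


class TestDihedralOracle:
    def test_matches_biotite_on_random_quadruples(self, rng):
        import biotite.structure as struc

        from conforma.motion import dihedral_angle

        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 3.0
            mine = dihedral_angle(*pts)
            ref = float(np.degrees(struc.dihedral(*pts)))
            # biotite computes in float32; compare circularly at 1e-3 deg
            assert circular_delta(mine, ref) < 1e-3
            assert np.sign(mine) == np.sign(ref) or abs(abs(mine) - 180.0) < 1e-3


class TestKinkDelta:
    def test_identical_series_all_zero(self):
        series = backbone_dihedrals(build_helix(8), "A")
        for rec in kink_delta(series, series, [3, 4, 5]):
            assert rec["delta_phi"] == pytest.approx(0.0)
            assert rec["delta_psi"] == pytest.approx(0.0)

    def test_planted_psi_change_recovered(self):
        a = build_helix(8, psi=-47.0)
        b = build_helix(8, psi=-87.0)
        recs = kink_delta(
            backbone_dihedrals(a, "A"), backbone_dihedrals(b, "A"), [4]
        )
        assert recs[0]["delta_psi"] == pytest.approx(40.0, abs=0.01)

    def test_circular_wrapping(self):
        assert circular_delta(178.0, -178.0) == pytest.approx(4.0)
        assert circular_delta(-179.0, 179.0) == pytest.approx(2.0)

    def test_undefined_residue_flagged_not_dropped(self):
        series = backbone_dihedrals(build_helix(5), "A")
        recs = kink_delta(series, series, [1, 3])
        assert recs[0]["flags"] == ["phi undefined"]
        assert recs[1]["flags"] == []
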