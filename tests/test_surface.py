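"""Accessible surface area, interface area and grid-probe cavity volumes."""

from __future__ import annotations

import numpy as np
import pytest

from conforma.model import AtomRecord, Residue, ResidueKey, StructureModel
from conforma.surface import (
    cavity_reduction,
    interface_area,
    pocket_volumes,
    sasa,
)
from conforma.synth import CavitySolidSpec, _fibonacci_unit, make_cavity_solid

from tests._oracles import random_rotation


def _atom(name: str, element: str, coords, chain="A", num=1) -> tuple[ResidueKey, AtomRecord]:
    return (ResidueKey(chain, num, "", "UNK"), AtomRecord(name, element, np.asarray(coords, float)))


def _ball_model(radius: float = 6.0, shell_step: float = 1.2) -> StructureModel:
    """Convex solid ball of carbon atoms (no internal voids)."""
    pts = [np.zeros(3)]
    for r in np.arange(shell_step, radius + 1e-9, shell_step):
        n = max(6, int(4 * np.pi * r**2 / 1.0))
        pts.extend(r * _fibonacci_unit(n))
    residues = [
        Residue(ResidueKey("A", i + 1, "", "UNK"), {"C1": AtomRecord("C1", "C", p)})
        for i, p in enumerate(pts)
    ]
    return StructureModel("ball", {"A": residues})


class TestSasa:
    def test_single_atom_matches_analytic_sphere(self):
        result = sasa([_atom("C1", "C", [0, 0, 0])])
        analytic = 4 * np.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(analytic, rel=0.01)

    def test_distant_atoms_are_additive(self):
        single = sasa([_atom("C1", "C", [0, 0, 0])]).total
        both = sasa(
            [_atom("C1", "C", [0, 0, 0]), _atom("C2", "C", [100.0, 0, 0], num=2)]
        ).total
        assert both == pytest.approx(2 * single, rel=1e-9)

    def test_fully_enclosed_atom_has_zero_area(self):
        shell, _ = make_cavity_solid(CavitySolidSpec(shell_radius=4.0, atom_spacing=0.8))
        atoms = shell.all_atoms() + [_atom("C0", "C", [0, 0, 0], chain="B")]
        result = sasa(atoms)
        buried = [a for (k, _n, a) in result.per_atom if k.chain_id == "B"]
        assert buried[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_density_convergence(self):
        model = _ball_model(radius=4.8)
        coarse = sasa(model, n_points=960).total
        fine = sasa(model, n_points=1920).total
        assert abs(fine - coarse) / fine < 0.005

    def test_unknown_element_uses_fallback_radius(self):
        result = sasa([_atom("Q1", "XX", [0, 0, 0])])
        assert result.total == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            sasa([])

    def test_agrees_with_biotite_shrake_rupley(self):
        import biotite.structure as struc

        model = _ball_model(radius=4.8)
        atoms = model.all_atoms()
        coords = np.array([a.coords for _, a in atoms])
        arr = struc.AtomArray(len(atoms))
        arr.coord = coords
        arr.element = np.array(["C"] * len(atoms))
        ref = struc.sasa(
            arr,
            probe_radius=1.4,
            vdw_radii=np.full(len(atoms), 1.70),
            point_number=1000,
        )
        mine = sasa(model, probe_radius=1.4, n_points=1000)
        assert mine.total == pytest.approx(float(ref.sum()), rel=0.02)


class TestInterfaceArea:
    def _two_chain_model(self, separation: float) -> StructureModel:
        chains = {}
        for cid, offset in (("A", 0.0), ("B", separation)):
            residues = [
                Residue(
                    ResidueKey(cid, i + 1, "", "UNK"),
                    {"C1": AtomRecord("C1", "C", np.array([offset, float(i) * 1.5, 0.0]))},
                )
                for i in range(8)
            ]
            chains[cid] = residues
        return StructureModel("pair", chains)

    def test_distant_chains_have_zero_interface(self):
        model = self._two_chain_model(100.0)
        result = interface_area(model, ["A"], ["B"])
        assert result.area == pytest.approx(0.0, abs=1e-6)

    def test_contact_interface_matches_high_density_oracle(self):
        model = self._two_chain_model(4.0)
        standard = interface_area(model, ["A"], ["B"], n_points=960)
        oracle = interface_area(model, ["A"], ["B"], n_points=7680)
        assert standard.area > 50.0
        assert standard.area == pytest.approx(oracle.area, rel=0.02)

    def test_symmetry_is_exact(self):
        model = self._two_chain_model(4.0)
        ab = interface_area(model, ["A"], ["B"])
        ba = interface_area(model, ["B"], ["A"])
        assert ab.area == ba.area

    def test_overlapping_groups_rejected(self):
        model = self._two_chain_model(4.0)
        with pytest.raises(ValueError, match="overlap"):
            interface_area(model, ["A"], ["A"])


class TestPocketVolumes:
    def test_enclosed_sphere_volume_within_discretization(self):
        shell, analytic = make_cavity_solid(CavitySolidSpec(shell_radius=7.7, atom_vdw=1.7))
        assert analytic == pytest.approx(4 / 3 * np.pi * 6.0**3, rel=1e-12)
        result = pocket_volumes(shell)
        assert len(result.pockets) >= 1
        assert result.pockets[0].volume == pytest.approx(analytic, rel=0.10)

    def test_convex_solid_has_no_pockets(self):
        assert pocket_volumes(_ball_model()).pockets == []

    def test_rigid_motion_invariance(self, rng):
        shell, analytic = make_cavity_solid(CavitySolidSpec())
        volumes = []
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.normal(0, 3, 3)
            volumes.append(pocket_volumes(shell.transform(R, t)).pockets[0].volume)
        volumes = np.array(volumes)
        assert np.all(np.abs(volumes - analytic) / analytic < 0.10)
        # orientation scatter is pure grid quantization, well under the
        # analytic tolerance
        assert (volumes.max() - volumes.min()) / volumes.mean() < 0.05

    def test_grid_refinement_approaches_analytic(self):
        shell, analytic = make_cavity_solid(CavitySolidSpec(atom_spacing=0.5))
        # depth threshold is expressed in grid steps, so it scales with spacing
        coarse = pocket_volumes(shell, grid_spacing=1.0, probe_radius=3.0, depth_threshold=5)
        fine = pocket_volumes(shell, grid_spacing=0.5, probe_radius=3.0, depth_threshold=10)
        err_coarse = abs(coarse.pockets[0].volume - analytic)
        err_fine = abs(fine.pockets[0].volume - analytic)
        assert err_fine <= err_coarse

    def test_open_shell_is_solvent_not_pocket(self):
        shell, analytic = make_cavity_solid(CavitySolidSpec(aperture_deg=180.0))
        assert analytic == 0.0
        result = pocket_volumes(shell)
        assert result.pockets == []

    def test_probe_excluded_aperture_keeps_cavity(self):
        # hole too small for the 3 A probe: cavity remains enclosed
        shell, analytic = make_cavity_solid(CavitySolidSpec(aperture_deg=30.0))
        assert analytic > 0
        result = pocket_volumes(shell)
        assert result.pockets and result.pockets[0].volume == pytest.approx(analytic, rel=0.10)

    def test_memory_ceiling_names_remedy(self):
        shell, _ = make_cavity_solid(CavitySolidSpec())
        with pytest.raises(MemoryError, match="coarser"):
            pocket_volumes(shell, grid_spacing=0.05, max_grid_points=10_000)

    def test_bad_parameters_rejected(self):
        shell, _ = make_cavity_solid(CavitySolidSpec())
        with pytest.raises(ValueError):
            pocket_volumes(shell, grid_spacing=0.0)
        with pytest.raises(ValueError):
            pocket_volumes(shell, grid_spacing=0.5, probe_radius=0.2)


class TestCavityReduction:
    def test_equal_volumes_zero_percent(self):
        shell, _ = make_cavity_solid(CavitySolidSpec())
        result = pocket_volumes(shell)
        assert cavity_reduction(result, result) == pytest.approx(0.0)

    def test_sixty_percent_reduction_arithmetic(self):
        # cavity radii chosen so V_closed / V_open = 0.4 analytically
        open_shell, v_open = make_cavity_solid(CavitySolidSpec(shell_radius=7.7))
        r_closed = 6.0 * 0.4 ** (1 / 3)
        closed_shell, v_closed = make_cavity_solid(
            CavitySolidSpec(shell_radius=r_closed + 1.7)
        )
        assert 100 * (v_open - v_closed) / v_open == pytest.approx(60.0, abs=1e-9)
        reduction = cavity_reduction(
            pocket_volumes(open_shell), pocket_volumes(closed_shell)
        )
        assert reduction == pytest.approx(60.0, abs=6.0)

    def test_point_selector_follows_cavity(self):
        shell, _ = make_cavity_solid(CavitySolidSpec())
        result = pocket_volumes(shell)
        reduction = cavity_reduction(result, result, selector=np.zeros(3))
        assert reduction == pytest.approx(0.0)

    def test_zero_open_volume_raises(self):
        shell, _ = make_cavity_solid(CavitySolidSpec())
        filled = pocket_volumes(_ball_model())
        with pytest.raises(ValueError, match="zero"):
            cavity_reduction(filled, pocket_volumes(shell))
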