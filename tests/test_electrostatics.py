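"""Charge assignment, screened-Coulomb potential and patch detection."""

import numpy as np
import pytest

from thdtools.electrostatics import (
    ChargeScheme,
    ScreenedCoulombModel,
    SurfaceField,
    assign_charges,
    find_patches,
    orient_axis_toward_termini,
    potential_at,
    surface_field,
    surface_points,
    total_charge,
)
from thdtools.errors import InputError
from thdtools.interface import SASAParams
from thdtools.structure_io import Atom, Chain, Residue, Structure, assign_radii
from thdtools.synthetic_data import make_charged_slab, make_helix, make_sphere, sphere_area


def _residue_structure(resname, atom_specs, chain_id="A", kind="polymer"):
    atoms = [Atom(name, element, pos) for name, element, pos in atom_specs]
    return Structure([Chain(chain_id, [Residue(chain_id, 1, "", resname, atoms)], kind)])


class TestAssignCharges:
    def test_neutral_backbone_stays_neutral(self, helix):
        assign_charges(helix, ChargeScheme(include_termini=False))
        assert total_charge(helix) == 0.0

    def test_termini_add_plus_and_minus_one(self, helix):
        helix["A"].residues[-1].atoms.append(Atom("OXT", "O", (99.0, 0, 0)))
        assign_charges(helix)
        assert total_charge(helix) == pytest.approx(0.0)  # +1 N-term, -1 OXT
        assert helix["A"].residues[0].atom("N").charge == pytest.approx(1.0)

    def test_charged_residues_carry_their_formal_charge(self):
        arg = _residue_structure("ARG", [("NH1", "N", (0, 0, 0)), ("NH2", "N", (1, 0, 0))])
        asp = _residue_structure("ASP", [("OD1", "O", (0, 0, 0)), ("OD2", "O", (1, 0, 0))])
        lys = _residue_structure("LYS", [("NZ", "N", (0, 0, 0))])
        for st, expected in [(arg, 1.0), (asp, -1.0), (lys, 1.0)]:
            assign_charges(st, ChargeScheme(include_termini=False))
            assert total_charge(st) == pytest.approx(expected)

    def test_unknown_residue_warns_and_stays_neutral(self):
        st = _residue_structure("QQQ", [("X1", "C", (0, 0, 0))], kind="non-polymer")
        with pytest.warns(UserWarning):
            assign_charges(st)
        assert total_charge(st) == 0.0


class TestPotential:
    def test_unscreened_coulomb_closed_form(self):
        st = make_sphere(1.7)
        st.atoms()[0].charge = 1.0
        model = ScreenedCoulombModel(screening_length=np.inf, dielectric=80.0)
        value = potential_at(np.array([[5.0, 0.0, 0.0]]), st, model)[0]
        # Bjerrum length in water at 298 K is ~7.0 A -> phi = l_B / (d) kT/e
        expected = model.bjerrum_length() / 5.0
        assert value == pytest.approx(expected, rel=1e-9)
        assert model.bjerrum_length() == pytest.approx(7.0, abs=0.1)

    def test_neutral_structure_gives_zero_everywhere(self, helix):
        pts = np.random.default_rng(0).normal(scale=10, size=(50, 3))
        assert np.all(potential_at(pts, helix) == 0.0)

    def test_antisymmetry_at_midpoint(self):
        plus = Atom("NZ", "N", (-3.0, 0, 0), charge=+1.0)
        minus = Atom("OD1", "O", (3.0, 0, 0), charge=-1.0)
        st = Structure([Chain("A", [Residue("A", 1, "", "LYS", [plus]),
                                    Residue("A", 2, "", "ASP", [minus])], "polymer")])
        value = potential_at(np.zeros((1, 3)), st)[0]
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_charges(self, rng):
        pts = rng.normal(scale=8, size=(20, 3))
        a1 = Atom("NZ", "N", (0.0, 0, 0), charge=+1.0)
        a2 = Atom("OD1", "O", (2.0, 1, 0), charge=-0.5)
        both = Structure([Chain("A", [Residue("A", 1, "", "LYS", [a1]),
                                      Residue("A", 2, "", "ASP", [a2])], "polymer")])
        only1 = Structure([Chain("A", [Residue("A", 1, "", "LYS", [a1.copy()])], "polymer")])
        only2 = Structure([Chain("A", [Residue("A", 2, "", "ASP", [a2.copy()])], "polymer")])
        combined = potential_at(pts, both)
        assert np.allclose(combined, potential_at(pts, only1) + potential_at(pts, only2),
                           atol=1e-9)

    def test_close_point_is_clamped_with_warning(self):
        st = make_sphere(1.7)
        st.atoms()[0].charge = 1.0
        with pytest.warns(UserWarning):
            value = potential_at(np.array([[0.1, 0.0, 0.0]]), st)[0]
        assert np.isfinite(value)


class TestSurfacePoints:
    def test_single_atom_weights_sum_to_sphere_area(self):
        st = make_sphere(1.7)
        pts, weights, owners = surface_points(st)
        assert weights.sum() == pytest.approx(sphere_area(1.7), rel=0.01)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.7 + 1.4)
        assert all(o.name == "LIG" for o in owners)

    def test_buried_atom_contributes_no_points(self):
        big = Atom("X1", "C", (0.0, 0, 0), vdw_radius=4.0)
        small = Atom("X2", "C", (0.0, 0, 0.5), vdw_radius=0.5)
        st = Structure([Chain("A", [Residue("A", 1, "", "LIG", [big])], "non-polymer"),
                        Chain("B", [Residue("B", 2, "", "LIG", [small])], "non-polymer")])
        pts, weights, owners = surface_points(st)
        assert all(o.id[0] == "A" for o in owners)


class TestPatches:
    def test_charged_slab_has_one_patch_on_charged_face(self):
        slab = make_charged_slab(6, 6, "top")
        field = surface_field(slab, SASAParams(points_per_atom=240))
        patches = find_patches(field, 2.0, min_area=20.0,
                               axis=np.array([0, 0, 1.0]), axis_point=np.zeros(3))
        basic = [p for p in patches if p.sign > 0]
        assert len(basic) == 1
        assert basic[0].location_class == "top"
        assert {r.name for r in basic[0].member_residues} <= {"LYS"}

    def test_neutral_slab_has_no_patches(self):
        slab = make_charged_slab(6, 6, "none")
        field = surface_field(slab, SASAParams(points_per_atom=240))
        assert find_patches(field, 2.0, min_area=20.0) == []

    def test_doubling_grid_roughly_doubles_patch_area(self):
        areas = []
        for nx in (6, 12):
            slab = make_charged_slab(nx, 6, "top")
            field = surface_field(slab, SASAParams(points_per_atom=240))
            patches = find_patches(field, 2.0, min_area=20.0)
            areas.append(sum(p.area for p in patches if p.sign > 0))
        assert areas[1] / areas[0] == pytest.approx(2.0, rel=0.25)

    def test_patches_partition_superthreshold_points(self):
        slab = make_charged_slab(6, 6, "top")
        field = surface_field(slab, SASAParams(points_per_atom=240))
        patches = find_patches(field, 2.0, min_area=0.0)
        counts = np.zeros(len(field.points), dtype=int)
        for p in patches:
            counts[p.member_indices] += 1
        assert counts.max() <= 1  # no point in two patches
        super_thr = int((np.abs(field.values) >= 2.0).sum())
        assert counts.sum() == super_thr  # min_area 0: every point assigned

    def test_lower_threshold_never_shrinks_patches(self):
        slab = make_charged_slab(6, 6, "top")
        field = surface_field(slab, SASAParams(points_per_atom=240))
        tight = find_patches(field, 3.0, min_area=20.0)
        loose = find_patches(field, 1.5, min_area=20.0)
        assert sum(p.area for p in loose) >= sum(p.area for p in tight)

    def test_invalid_threshold_rejected(self):
        field = SurfaceField(np.zeros((1, 3)), np.zeros(1), np.ones(1), [None])
        with pytest.raises(InputError):
            find_patches(field, -1.0)


def test_axis_orientation_points_toward_termini():
    helix = assign_radii(make_helix(10))
    # helix extends along -z from the origin; termini mean sits near the ends
    axis = np.array([0.0, 0.0, 1.0])
    oriented = orient_axis_toward_termini(helix, axis, np.zeros(3))
    assert np.linalg.norm(oriented) == pytest.approx(1.0)
    flipped = orient_axis_toward_termini(helix, -oriented, np.zeros(3))
    assert np.allclose(flipped, oriented)  # orientation is canonical
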