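"""SASA quadrature, buried area, hydrogen-bond / stacking / contact detection."""

import numpy as np
import pytest

from thdtools.errors import ConfigurationError, InputError
from thdtools.interface import (
    HBondCriteria,
    SASAParams,
    StackingCriteria,
    buried_area,
    contact_map,
    fibonacci_sphere,
    hydrogen_bonds,
    interface_report,
    sasa,
    stacking_pairs,
)
from thdtools.structure_io import Atom, Chain, Residue, Structure, assign_radii
from thdtools.synthetic_data import (
    make_hbond_pair,
    make_sphere,
    make_two_sphere,
    sphere_area,
    two_sphere_areas,
)


def brute_force_sasa(structure, probe=1.4, n_points=700, seed=99):
    """Independent oracle: random (seeded) spherical point set, O(n^2) occlusion."""
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_points, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    atoms = [a for a in structure.atoms() if not a.is_hydrogen]
    centers = np.array([a.pos for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe
    total = 0.0
    for i in range(len(atoms)):
        pts = centers[i] + radii[i] * directions
        ok = np.ones(n_points, dtype=bool)
        for j in range(len(atoms)):
            if j == i:
                continue
            ok &= ((pts - centers[j]) ** 2).sum(axis=1) >= radii[j] ** 2
        total += ok.mean() * 4 * np.pi * radii[i] ** 2
    return total


class TestSasa:
    def test_isolated_carbon_matches_analytic_sphere(self):
        st = make_sphere(1.70)
        result = sasa(st)
        assert result.total == pytest.approx(sphere_area(1.70), rel=0.01)
        assert result.total == pytest.approx(4 * np.pi * 3.10 ** 2, rel=0.01)

    def test_quadrature_convergence_on_doubling(self, helix):
        coarse = sasa(helix, SASAParams(points_per_atom=960)).total
        fine = sasa(helix, SASAParams(points_per_atom=1920)).total
        assert abs(fine - coarse) / fine < 0.005

    def test_distant_spheres_keep_full_area(self):
        st, oracle = make_two_sphere(1.7, 1.7, 12.0)
        result = sasa(st)
        assert result.total == pytest.approx(2 * sphere_area(1.7), rel=0.01)
        assert oracle["buried_total"] == 0.0

    @pytest.mark.parametrize("distance", np.linspace(0.8, 6.0, 12))
    def test_two_sphere_cap_oracle(self, distance):
        st, oracle = make_two_sphere(1.7, 1.52, float(distance))
        result = sasa(st)
        assert result.total == pytest.approx(oracle["total"], rel=0.015)

    def test_occluder_never_increases_any_area(self, helix):
        base = sasa(helix)
        occluded = helix.copy()
        extra = Atom("XX", "C", np.array(helix.atoms()[0].pos) + [1.0, 0, 0],
                     vdw_radius=1.7)
        occluded.add_chain(Chain("Z", [Residue("Z", 1, "", "LIG", [extra])],
                                 "non-polymer"))
        after = sasa(occluded)
        # same atoms lead the list; the appended occluder is last
        assert np.all(after.per_atom_area[:-1] <= base.per_atom_area + 1e-9)

    def test_agrees_with_independent_random_point_oracle(self, helix):
        ours = sasa(helix).total
        oracle = brute_force_sasa(helix, n_points=3000)
        assert ours == pytest.approx(oracle, rel=0.01)

    def test_missing_radius_is_configuration_error(self):
        st = make_sphere(1.7)
        st.atoms()[0].vdw_radius = None
        with pytest.raises(ConfigurationError):
            sasa(st)

    def test_per_atom_sums_to_total(self, helix):
        result = sasa(helix)
        assert result.per_atom_area.sum() == pytest.approx(result.total, rel=1e-9)
        assert sum(result.per_residue_area.values()) == pytest.approx(result.total,
                                                                      rel=1e-9)

    def test_fibonacci_points_are_unit_and_deterministic(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, fibonacci_sphere(960))


class TestBuriedArea:
    def test_far_groups_bury_nothing(self):
        st, _ = make_two_sphere(1.7, 1.7, 20.0)
        total, a, b = buried_area([st["A"]], [st["B"]])
        assert abs(total) < 1.0 and abs(a) < 0.5 and abs(b) < 0.5

    @pytest.mark.parametrize("distance", [1.0, 2.0, 3.0, 4.5])
    def test_matches_cap_formula(self, distance):
        st, oracle = make_two_sphere(1.7, 1.7, distance)
        # two atoms only: a fine quadrature is free and isolates method error
        total, a, b = buried_area([st["A"]], [st["B"]],
                                  SASAParams(points_per_atom=4000))
        assert total == pytest.approx(oracle["buried_total"], rel=0.015)
        assert a + b == pytest.approx(total, rel=1e-9)

    def test_symmetric_in_arguments(self, trimer):
        st, _ = trimer
        params = SASAParams(points_per_atom=240)
        ab = buried_area([st["A"]], [st["A_s1"]], params)
        ba = buried_area([st["A_s1"]], [st["A"]], params)
        assert ab[0] == pytest.approx(ba[0], rel=1e-9)

    def test_overlapping_groups_rejected(self, helix):
        with pytest.raises(InputError):
            buried_area([helix["A"]], [helix["A"]])


class TestHydrogenBonds:
    def test_ideal_pair_detected_with_rounded_distance(self):
        donor, acceptor = make_hbond_pair(2.9, 120.0)
        bonds = hydrogen_bonds(donor, acceptor)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.90, abs=1e-9)
        assert bonds[0].classification == "main-main"

    def test_long_pair_not_detected(self):
        donor, acceptor = make_hbond_pair(5.0, 120.0)
        assert hydrogen_bonds(donor, acceptor) == []

    def test_bad_antecedent_angle_rejected(self):
        donor, acceptor = make_hbond_pair(2.9, 60.0)
        assert hydrogen_bonds(donor, acceptor) == []

    def test_cutoff_is_configurable(self):
        donor, acceptor = make_hbond_pair(3.8, 120.0)
        assert hydrogen_bonds(donor, acceptor) == []
        wide = hydrogen_bonds(donor, acceptor, HBondCriteria(max_distance=3.9))
        assert len(wide) == 1


def _phe_ring(chain_id, seq, center, normal, radius=1.39):
    """Planar six-membered ring with CB/CG stubs, oriented by its normal."""
    normal = np.asarray(normal, dtype=float)
    normal /= np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = []
    for k, name in enumerate(names):
        ang = 2 * np.pi * k / 6
        pos = np.asarray(center) + radius * (np.cos(ang) * u + np.sin(ang) * v)
        atoms.append(Atom(name, "C", pos))
    return Residue(chain_id, seq, "", "PHE", atoms)


class TestStacking:
    def test_parallel_rings_detected(self):
        a = Structure([Chain("A", [_phe_ring("A", 1, (0, 0, 0), (0, 0, 1))], "polymer")])
        b = Structure([Chain("B", [_phe_ring("B", 2, (0, 0, 3.8), (0, 0, 1))], "polymer")])
        pairs = stacking_pairs(a, b)
        assert len(pairs) == 1
        assert pairs[0].centroid_distance == pytest.approx(3.8, abs=1e-6)
        assert pairs[0].plane_angle == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_rings_not_detected_by_default(self):
        a = Structure([Chain("A", [_phe_ring("A", 1, (0, 0, 0), (0, 0, 1))], "polymer")])
        b = Structure([Chain("B", [_phe_ring("B", 2, (0, 0, 3.8), (1, 0, 0))], "polymer")])
        assert stacking_pairs(a, b) == []

    def test_arginine_guanidinium_counts_as_planar_partner(self):
        ring = Structure([Chain("A", [_phe_ring("A", 1, (0, 0, 0), (0, 0, 1))], "polymer")])
        arg_atoms = [Atom("NE", "N", (1.2, 0, 3.6)), Atom("CZ", "C", (0, 0, 3.6)),
                     Atom("NH1", "N", (-0.7, 1.1, 3.6)), Atom("NH2", "N", (-0.7, -1.1, 3.6))]
        arg = Structure([Chain("B", [Residue("B", 5, "", "ARG", arg_atoms)], "polymer")])
        pairs = stacking_pairs(ring, arg)
        assert len(pairs) == 1
        assert pairs[0].residue_b.name == "ARG"


class TestContactsAndReport:
    def test_far_groups_have_empty_contact_sets(self):
        st, _ = make_two_sphere(1.7, 1.7, 30.0)
        a, b = contact_map([st["A"]], [st["B"]])
        assert a == [] and b == []

    def test_engineered_contact_found_exactly(self, trimer):
        st, _ = trimer
        contacts_a, contacts_b = contact_map([st["A"]], [st["A_s1"]], cutoff=4.5)
        # recompute by brute force over heavy-atom pairs
        import itertools
        expected_a = set()
        expected_b = set()
        for ra in st["A"].residues:
            for rb in st["A_s1"].residues:
                dmin = min(np.linalg.norm(x.pos - y.pos)
                           for x, y in itertools.product(ra.heavy_atoms(),
                                                         rb.heavy_atoms()))
                if dmin <= 4.5:
                    expected_a.add(ra.id)
                    expected_b.add(rb.id)
        assert {r.id for r in contacts_a} == expected_a
        assert {r.id for r in contacts_b} == expected_b

    def test_report_composes_the_individual_operations(self, trimer, fast_sasa):
        st, _ = trimer
        report = interface_report([st["A"]], [st["A_s1"]], "A", "A_s1", fast_sasa)
        assert report.bsa_total == pytest.approx(
            buried_area([st["A"]], [st["A_s1"]], fast_sasa)[0], rel=1e-9)
        assert len(report.hbonds) == len(hydrogen_bonds([st["A"]], [st["A_s1"]]))
        direct_a, _ = contact_map([st["A"]], [st["A_s1"]])
        assert [r.id for r in report.contacts_a] == [r.id for r in direct_a]
        payload = report.to_dict()
        assert payload["bsa_total"] == pytest.approx(report.bsa_total, abs=0.05)
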