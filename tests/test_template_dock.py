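"""Template-transfer docking, rigid-body clash relief and consistency checks."""

import numpy as np
import pytest

from thdtools.errors import DockingError, InputError, MinimizationError
from thdtools.geometry import RigidTransform, rotation_difference_rad
from thdtools.structure_io import Atom, Chain, Residue, Structure, assign_radii, coords_of
from thdtools.symmetry import apply_transform
from thdtools.synthetic_data import make_c3_trimer, make_helix, random_rigid_transform
from thdtools.template_dock import (
    EnergyModel,
    TemplateComplex,
    check_inter_receptor_clashes,
    count_clashes,
    mutagenesis_consistency,
    rigid_minimize,
    transfer_dock,
)


def _toy_receptor():
    receptor = make_helix(5, chain_id="R")
    park = RigidTransform.from_axis_angle((0, 0, 1), 60.0).compose(
        RigidTransform(np.eye(3), np.array([8.5, 0.0, 0.0])))
    return assign_radii(apply_transform(receptor, park))


@pytest.fixture
def dock_setup(trimer):
    st, transforms = trimer
    receptor = _toy_receptor()
    template = TemplateComplex([st["A"].copy(), st["A_s1"].copy()],
                               receptor["R"].copy(), "toy_template")
    return st, transforms, receptor, template


class TestTransferDock:
    def test_self_docking_recovers_deposited_pose(self, dock_setup):
        st, transforms, receptor, template = dock_setup
        result = transfer_dock([st["A"], st["A_s1"], st["A_s2"]], receptor,
                               [template], trimer_operator=transforms[1])
        placed = result.consensus.receptor_transform.apply(coords_of(receptor))
        assert np.abs(placed - coords_of(template.receptor_chain)).max() <= 1e-6
        assert result.consensus.thd_superposition_rmsd <= 1e-9

    def test_known_transform_template_recovered(self, dock_setup):
        st, transforms, receptor, template = dock_setup
        t = random_rigid_transform(11)
        moved_template = TemplateComplex(
            [apply_transform(c, t) for c in template.ligand_chains],
            apply_transform(template.receptor_chain, t), "moved")
        result = transfer_dock([st["A"], st["A_s1"], st["A_s2"]], receptor,
                               [moved_template])
        placed = result.consensus.receptor_transform.apply(coords_of(receptor))
        assert np.abs(placed - coords_of(template.receptor_chain)).max() <= 1e-6

    def test_rotation_equivariance(self, dock_setup):
        st, transforms, receptor, template = dock_setup
        base = transfer_dock([st["A"], st["A_s1"], st["A_s2"]], receptor, [template])
        t = random_rigid_transform(21)
        moved_query = [apply_transform(st[c], t) for c in ("A", "A_s1", "A_s2")]
        moved = transfer_dock(moved_query, receptor, [template])
        expected = t.compose(base.consensus.receptor_transform)
        got = moved.consensus.receptor_transform
        assert rotation_difference_rad(got.rotation, expected.rotation) <= 1e-6
        assert np.abs(got.translation - expected.translation).max() <= 1e-5

    def test_multiple_templates_spread_and_consensus(self, dock_setup):
        st, transforms, receptor, template = dock_setup
        jitter = RigidTransform.from_axis_angle((0, 0, 1), 1.0)
        shifted = TemplateComplex(template.ligand_chains,
                                  apply_transform(template.receptor_chain, jitter),
                                  "jittered")
        result = transfer_dock([st["A"], st["A_s1"], st["A_s2"]], receptor,
                               [template, shifted])
        assert len(result.placements) == 2
        assert result.consensus.template_source in ("toy_template", "jittered")
        assert 0.0 <= result.spread < 8.0

    def test_unalignable_template_raises(self, dock_setup):
        st, transforms, receptor, _ = dock_setup
        # a template whose ligand shares no fold with the query: random points
        rng = np.random.default_rng(3)
        atoms = [Atom("CA", "C", rng.normal(scale=20, size=3)) for _ in range(40)]
        residues = [Residue("X", i + 1, "", "GLY", [a]) for i, a in enumerate(atoms)]
        weird = Chain("X", residues, "polymer")
        template = TemplateComplex([weird], receptor["R"].copy(), "junk")
        with pytest.raises(DockingError):
            transfer_dock([st["A"], st["A_s1"], st["A_s2"]], receptor, [template],
                          rmsd_limit=0.5)


def _two_atom_system(distance):
    a = Atom("X1", "C", (0.0, 0.0, 0.0), vdw_radius=1.7)
    b = Atom("X2", "C", (distance, 0.0, 0.0), vdw_radius=1.7)
    fixed = Structure([Chain("A", [Residue("A", 1, "", "LIG", [a])], "non-polymer")])
    movable = Structure([Chain("B", [Residue("B", 1, "", "LIG", [b])], "non-polymer")])
    return fixed, movable


class TestRigidMinimize:
    def test_non_clashing_start_does_not_move(self, dock_setup):
        st, _, receptor, _ = dock_setup
        before = coords_of(receptor)
        transform, trace = rigid_minimize([st["A"], st["A_s1"], st["A_s2"]],
                                          receptor)
        assert trace == [0.0]
        assert transform.is_identity(tol=1e-12)
        assert np.array_equal(coords_of(receptor), before)

    def test_two_atom_clash_separates_to_contact_distance(self):
        model = EnergyModel()
        contact = model.contact_fraction * (1.7 + 1.7)
        fixed, movable = _two_atom_system(0.8 * contact)
        _, trace = rigid_minimize(fixed, movable, model, gtol=1e-6)
        final_distance = np.linalg.norm(coords_of(movable)[0] - coords_of(fixed)[0])
        assert final_distance >= contact - 1e-3
        assert trace[-1] <= 1e-6

    def test_energy_trace_monotone_non_increasing(self, trimer):
        st, _ = trimer
        clashing = apply_transform(st["A"].copy(),
                                   RigidTransform(np.eye(3), np.array([1.5, 0, 0])),
                                   "_m")
        movable = Structure([clashing])
        assign_radii(movable)
        _, trace = rigid_minimize([st["A"]], movable, max_steps=300)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-12)
        assert trace[-1] < trace[0]

    def test_overlapping_groups_rejected(self, trimer):
        st, _ = trimer
        with pytest.raises(InputError):
            rigid_minimize([st["A"]], [st["A"]])


class TestClashCounting:
    def test_far_groups_have_no_clashes(self, dock_setup):
        st, _, receptor, _ = dock_setup
        n, pairs = count_clashes([st["A"]], receptor)
        assert n == 0 and pairs == []

    def test_count_matches_brute_force(self, rng):
        atoms_a, atoms_b = [], []
        for i in range(25):
            atoms_a.append(Atom("C1", "C", rng.normal(scale=4, size=3), vdw_radius=1.7))
            atoms_b.append(Atom("C2", "C", rng.normal(scale=4, size=3), vdw_radius=1.7))
        ga = Structure([Chain("A", [Residue("A", 1, "", "LIG", atoms_a)], "non-polymer")])
        gb = Structure([Chain("B", [Residue("B", 1, "", "LIG", atoms_b)], "non-polymer")])
        n, _ = count_clashes(ga, gb)
        brute = sum(1 for a in atoms_a for b in atoms_b
                    if np.linalg.norm(a.pos - b.pos) < 0.6 * (1.7 + 1.7))
        assert n == brute

    def test_trimeric_model_inter_receptor_clashes(self, dock_setup):
        st, transforms, receptor, template = dock_setup
        result = transfer_dock([st["A"], st["A_s1"], st["A_s2"]], receptor,
                               [template], trimer_operator=transforms[1])
        assign_radii(result.modeled_complex)
        n, _ = check_inter_receptor_clashes(result.modeled_complex)
        assert n == 0

    def test_missing_receptor_copies_rejected(self, trimer):
        st, _ = trimer
        with pytest.raises(InputError):
            check_inter_receptor_clashes(st)


class TestMutagenesisConsistency:
    def test_engineered_contact_residue_flagged(self, dock_setup):
        st, transforms, receptor, template = dock_setup
        result = transfer_dock([st["A"], st["A_s1"], st["A_s2"]], receptor,
                               [template], trimer_operator=transforms[1])
        assign_radii(result.modeled_complex)
        receptor_chains = [c for c in result.modeled_complex.chains
                           if c.id.endswith("_r1")]
        ligand_chains = [result.modeled_complex[c] for c in ("A", "A_s1", "A_s2")]
        contact_res = None
        from thdtools.interface import contact_map
        contacts, _ = contact_map(receptor_chains, ligand_chains)
        assert contacts, "toy receptor should touch the trimer"
        contact_res = contacts[0].seq_number
        far_res = max(r.seq_number for c in receptor_chains for r in c.residues
                      if r.seq_number not in {x.seq_number for x in contacts})
        report = mutagenesis_consistency(result.modeled_complex, receptor_chains,
                                         ligand_chains, [contact_res], [far_res])
        assert report["all_important_in_contact"]
        assert report["important"][0]["buried_area"] >= 0.0
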