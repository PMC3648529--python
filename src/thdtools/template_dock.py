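"""Template-transfer docking of a receptor CRD onto a THD trimer.

TNF-family receptors bind the groove between two protomers of the cytokine
trimer.  Given experimentally determined homologous THD–CRD complexes, the
receptor placement is transferred to the query: (i) the template protomer
pair flanking its receptor is superposed onto each of the three equivalent
protomer pairs of the query trimer (best fit wins), (ii) the template CRD is
carried along into the query frame, (iii) the query receptor model is
superposed onto the mapped CRD.  The consensus placement (lowest THD
superposition RMSD) is then relieved of steric clashes by a deterministic
rigid-body minimization of a half-harmonic repulsion — a reproducible stand-in
for full crystallographic refinement, which is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DockingError, InputError, MinimizationError
from .geometry import RigidTransform
from .structure_io import Chain, Structure, coords_of, heavy_atoms, set_coords
from .superpose import superpose_chains
from .symmetry import apply_transform
from .interface import buried_area, hydrogen_bonds, contact_map, SASAParams

# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class TemplateComplex:
    """A solved homolog complex: THD ligand chains + one receptor CRD chain."""

    ligand_chains: list[Chain]
    receptor_chain: Chain
    source_id: str = ""

    def __post_init__(self):
        ligand_ids = {c.id for c in self.ligand_chains}
        if self.receptor_chain.id in ligand_ids:
            raise InputError("ligand and receptor must not share chains")


@dataclass
class Placement:
    template_source: str
    receptor_transform: RigidTransform
    thd_superposition_rmsd: float
    crd_superposition_rmsd: float

    def __post_init__(self):
        if self.thd_superposition_rmsd < 0 or self.crd_superposition_rmsd < 0:
            raise InputError("rmsd fields must be non-negative")


@dataclass
class DockResult:
    placements: list[Placement]
    consensus: Placement
    modeled_complex: Structure
    spread: float  # max pairwise receptor-centroid distance among placements, A
    clash_report: dict = field(default_factory=dict)
    energy_trace: list = field(default_factory=list)


@dataclass
class EnergyModel:
    """Half-harmonic steric repulsion below a fraction of the vdW contact distance."""

    contact_fraction: float = 0.89  # repulsion onset at this fraction of r_i + r_j
    repulsion_scale: float = 1.0    # force constant, energy-units / A^2
    clash_fraction: float = 0.6     # severe-clash criterion for counting


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------


def _min_chain_distance(chain_a: Chain, chain_b: Chain) -> float:
    a = np.array([atom.pos for atom in heavy_atoms(chain_a)])
    b = np.array([atom.pos for atom in heavy_atoms(chain_b)])
    return float(cKDTree(b).query(a)[0].min())


def flanking_pair(template: TemplateComplex, cutoff: float = 8.0) -> list[Chain]:
    """The two template ligand chains closest to (within ``cutoff`` of) the CRD."""
    scored = sorted(template.ligand_chains,
                    key=lambda c: _min_chain_distance(c, template.receptor_chain))
    pair = [c for c in scored[:2]]
    if len(pair) < 2:
        # single-protomer template: superpose on one chain only
        return scored[:1]
    return pair


def _adjacent_pairs(chains: list[Chain]) -> list[tuple[Chain, Chain]]:
    n = len(chains)
    if n == 1:
        return [(chains[0],)]  # type: ignore[list-item]
    return [(chains[i], chains[(i + 1) % n]) for i in range(n)]


def transfer_dock(query_thd_chains: list[Chain], query_receptor: Structure,
                  templates: list[TemplateComplex],
                  trimer_operator: RigidTransform | None = None,
                  pair_cutoff: float = 8.0, rmsd_limit: float = 5.0,
                  spread_threshold: float = 8.0,
                  receptor_copies: int = 3) -> DockResult:
    """Transfer receptor placements from each template onto the query trimer.

    ``trimer_operator`` (the query's 3-fold transform, chain i -> chain i+1)
    regenerates the full trimeric model from the consensus receptor; when
    omitted only one receptor copy is placed.
    """
    if not templates:
        raise InputError("at least one template complex is required")
    receptor_chains = query_receptor.polymer_chains() or query_receptor.chains
    placements: list[Placement] = []
    failures = []
    for template in templates:
        pair = flanking_pair(template, pair_cutoff)
        best = None
        for query_pair in _adjacent_pairs(query_thd_chains):
            for ordering in (tuple(query_pair), tuple(reversed(query_pair))):
                if len(pair) != len(ordering):
                    continue
                try:
                    fit = superpose_chains(list(pair), list(ordering))
                except Exception:
                    continue
                # strict improvement with tolerance: symmetry-equivalent pairs
                # tie at rmsd ~0, and the first candidate must win in a way
                # that is stable under global rotations of the query
                if best is None or fit.rmsd < best.rmsd - 1e-9:
                    best = fit
        if best is None or best.rmsd > rmsd_limit:
            failures.append((template.source_id,
                             None if best is None else best.rmsd))
            continue
        # carry the template CRD into the query frame, then fit the query
        # receptor model onto it
        mapped_crd = apply_transform(template.receptor_chain, best.transform)
        crd_fit = superpose_chains(receptor_chains, [mapped_crd])
        placements.append(Placement(template.source_id, crd_fit.transform,
                                    best.rmsd, crd_fit.rmsd))
    if not placements:
        raise DockingError(
            f"no template aligned within {rmsd_limit} A; diagnostics: {failures}")

    consensus = min(placements, key=lambda p: p.thd_superposition_rmsd)

    # spread: receptor centroid under each placement
    centroid0 = coords_of(receptor_chains).mean(axis=0)
    centroids = [p.receptor_transform.apply(centroid0) for p in placements]
    spread = 0.0
    for i in range(len(centroids)):
        for j in range(i + 1, len(centroids)):
            spread = max(spread, float(np.linalg.norm(centroids[i] - centroids[j])))

    model = Structure([c.copy() for c in query_thd_chains],
                      source_id="docked_model")
    placed = [apply_transform(c, consensus.receptor_transform, "_r1")
              for c in receptor_chains]
    for chain in placed:
        model.add_chain(chain)
    if trimer_operator is not None and receptor_copies >= 2:
        transform = consensus.receptor_transform
        for k in range(2, receptor_copies + 1):
            transform = trimer_operator.compose(transform)
            for chain in receptor_chains:
                model.add_chain(apply_transform(chain, transform, f"_r{k}"))
    result = DockResult(placements, consensus, model, spread)
    result.clash_report["co_localized"] = spread <= spread_threshold
    return result


# ---------------------------------------------------------------------------
# rigid-body minimization
# ---------------------------------------------------------------------------


def _repulsion_energy_grad(fixed_pos, fixed_r, mov_pos, mov_r, model: EnergyModel):
    """Energy and per-movable-atom gradient of the half-harmonic repulsion."""
    tree = cKDTree(fixed_pos)
    d0_max = model.contact_fraction * (fixed_r.max() + mov_r.max())
    energy = 0.0
    grad = np.zeros_like(mov_pos)
    for j, (p, rj) in enumerate(zip(mov_pos, mov_r)):
        for i in tree.query_ball_point(p, d0_max):
            d0 = model.contact_fraction * (fixed_r[i] + rj)
            diff = p - fixed_pos[i]
            d = np.linalg.norm(diff)
            if d >= d0 or d < 1e-9:
                continue
            overlap = d0 - d
            energy += 0.5 * model.repulsion_scale * overlap ** 2
            grad[j] += -model.repulsion_scale * overlap * (diff / d)
    return energy, grad


def rigid_minimize(fixed_group, movable_group, energy_model: EnergyModel | None = None,
                   max_steps: int = 2000, gtol: float = 1e-4):
    """Deterministic steepest-descent on the 6 rigid-body DOF of ``movable_group``.

    Moves the group's atoms in place; returns ``(total RigidTransform,
    energy trace)``.  Energy is monotone non-increasing by construction of the
    backtracking line search; exhaustion of the backtracking at a non-zero
    gradient raises :class:`MinimizationError` with the trace.
    """
    model = energy_model or EnergyModel()
    fixed_atoms = heavy_atoms(fixed_group)
    movable_atoms = heavy_atoms(movable_group)
    if set(map(id, fixed_atoms)) & set(map(id, movable_atoms)):
        raise InputError("movable group overlaps the fixed group")
    for atom in fixed_atoms + movable_atoms:
        if atom.vdw_radius is None:
            raise InputError("assign radii before minimizing")
    fixed_pos = np.array([a.pos for a in fixed_atoms])
    fixed_r = np.array([a.vdw_radius for a in fixed_atoms])
    mov_r = np.array([a.vdw_radius for a in movable_atoms])
    pos = np.array([a.pos for a in movable_atoms])

    total = RigidTransform.identity()
    energy, grad = _repulsion_energy_grad(fixed_pos, fixed_r, pos, mov_r, model)
    trace = [energy]
    step = 0
    while step < max_steps:
        if energy <= 0.0:
            break
        center = pos.mean(axis=0)
        g_trans = grad.sum(axis=0)
        g_rot = np.cross(pos - center, grad).sum(axis=0)
        gnorm = max(np.linalg.norm(g_trans), np.linalg.norm(g_rot))
        if gnorm <= gtol:
            break
        # descend along the negative generalized gradient
        direction_t = -g_trans
        direction_w = -g_rot
        scale = max(np.linalg.norm(direction_t), np.linalg.norm(direction_w), 1e-12)
        alpha = 0.5 / scale  # first trial moves at most ~0.5 A / 0.5 rad-A
        improved = False
        for _ in range(40):
            w = alpha * direction_w
            angle = np.linalg.norm(w)
            if angle > 1e-12:
                increment = RigidTransform.from_axis_angle(w / angle, np.degrees(angle),
                                                           point=center)
            else:
                increment = RigidTransform.identity()
            shift = RigidTransform(np.eye(3), alpha * direction_t)
            trial_transform = shift.compose(increment)
            trial_pos = trial_transform.apply(pos)
            trial_energy, trial_grad = _repulsion_energy_grad(
                fixed_pos, fixed_r, trial_pos, mov_r, model)
            if trial_energy < energy:
                pos, energy, grad = trial_pos, trial_energy, trial_grad
                total = trial_transform.compose(total)
                trace.append(energy)
                improved = True
                break
            alpha *= 0.5
        if not improved:
            if energy <= gtol:
                break
            raise MinimizationError(
                f"line search exhausted at energy {energy:.4g} (step {step})", trace)
        step += 1
    set_coords(movable_atoms, pos)
    # hydrogens (if any) follow the same rigid motion
    for atom in (a for a in _all_atoms(movable_group) if a.is_hydrogen):
        atom.pos = total.apply(atom.pos)
    return total, trace


def _all_atoms(group):
    from .structure_io import iter_atoms
    return list(iter_atoms(group))


# ---------------------------------------------------------------------------
# clash counting & mutagenesis consistency
# ---------------------------------------------------------------------------


def count_clashes(group_a, group_b, clash_fraction: float = 0.6) -> tuple[int, list]:
    """Heavy-atom pairs closer than ``clash_fraction`` x (r_i + r_j)."""
    atoms_a = heavy_atoms(group_a)
    atoms_b = heavy_atoms(group_b)
    if not atoms_a or not atoms_b:
        return 0, []
    pos_a = np.array([a.pos for a in atoms_a])
    pos_b = np.array([a.pos for a in atoms_b])
    r_a = np.array([a.vdw_radius if a.vdw_radius else 1.8 for a in atoms_a])
    r_b = np.array([a.vdw_radius if a.vdw_radius else 1.8 for a in atoms_b])
    tree = cKDTree(pos_b)
    limit = clash_fraction * (r_a.max() + r_b.max())
    pairs = []
    for i, neighbors in enumerate(tree.query_ball_point(pos_a, limit)):
        for j in neighbors:
            d = np.linalg.norm(pos_a[i] - pos_b[j])
            if d < clash_fraction * (r_a[i] + r_b[j]):
                pairs.append((atoms_a[i], atoms_b[j], float(d)))
    return len(pairs), pairs


def check_inter_receptor_clashes(model: Structure, receptor_prefixes=("_r1", "_r2", "_r3"),
                                 clash_fraction: float = 0.6) -> tuple[int, list]:
    """Clashes among the symmetry-generated receptor copies of a trimeric model."""
    groups = []
    for prefix in receptor_prefixes:
        chains = [c for c in model.chains if c.id.endswith(prefix)]
        if chains:
            groups.append(chains)
    if len(groups) < 3:
        raise InputError(f"model does not contain 3 receptor copies "
                         f"(found {len(groups)} of {receptor_prefixes})")
    total, all_pairs = 0, []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            n, pairs = count_clashes(groups[i], groups[j], clash_fraction)
            total += n
            all_pairs.extend(pairs)
    return total, all_pairs


def mutagenesis_consistency(model: Structure, receptor_chains: list[Chain],
                            ligand_chains: list[Chain],
                            important_residues: list[int],
                            dispensable_residues: list[int],
                            contact_cutoff: float = 4.5,
                            sasa_params: SASAParams | None = None) -> dict:
    """Check a docked model against point-mutagenesis expectations.

    Important receptor residues should contact the ligand; dispensable ones
    should form no direct hydrogen bond to it.  Returns per-residue contact
    flags, buried areas and H-bond participation plus summary booleans.
    """
    params = sasa_params or SASAParams(points_per_atom=240)
    contacts_r, _ = contact_map(receptor_chains, ligand_chains, contact_cutoff)
    contact_numbers = {r.seq_number for r in contacts_r}
    bonds = hydrogen_bonds(receptor_chains, ligand_chains)
    hbond_numbers = set()
    receptor_ids = {c.id for c in receptor_chains}
    for b in bonds:
        if b.donor_residue.chain_id in receptor_ids:
            hbond_numbers.add(b.donor_residue.seq_number)
        if b.acceptor_residue.chain_id in receptor_ids:
            hbond_numbers.add(b.acceptor_residue.seq_number)

    # per-residue buried area from the per-atom SASA difference
    from .interface import sasa as _sasa
    alone = _sasa(receptor_chains, params)
    complexed = _sasa([receptor_chains, ligand_chains], params)
    n_r = len(alone.per_atom_area)
    per_res_buried: dict[int, float] = {}
    for res, a_alone, a_cplx in zip(
            [r for c in receptor_chains for r in c.residues for _ in r.heavy_atoms()],
            alone.per_atom_area, complexed.per_atom_area[:n_r]):
        per_res_buried[res.seq_number] = per_res_buried.get(res.seq_number, 0.0) + \
            (a_alone - a_cplx)

    def row(num):
        return {
            "residue": num,
            "in_contact": num in contact_numbers,
            "buried_area": round(per_res_buried.get(num, 0.0), 1),
            "forms_hbond": num in hbond_numbers,
        }

    report = {
        "important": [row(n) for n in important_residues],
        "dispensable": [row(n) for n in dispensable_residues],
    }
    report["all_important_in_contact"] = all(r["in_contact"] for r in report["important"])
    report["no_dispensable_hbonds"] = all(not r["forms_hbond"] for r in report["dispensable"])
    return report
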