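"""Interface characterization: SASA, buried area, hydrogen bonds, stacking, contacts.

The solvent-accessible surface area is computed by Shrake–Rupley numerical
quadrature: a deterministic Fibonacci-lattice point set is scaled onto each
probe-expanded atom sphere and points occluded by any neighboring expanded
sphere are discarded.  Buried surface area follows the difference convention
``SASA(A) + SASA(B) - SASA(A∪B)`` (both sides summed), per-side losses are
reported alongside so the single-side reading is always inspectable.

Hydrogen bonds are detected between heavy donor/acceptor atoms (crystal
structures carry no hydrogens): donor-capable N/O against acceptor-capable
N/O/S within a distance cutoff, with an antecedent-angle filter whenever the
donor's bonded antecedent atom is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InputError
from .structure_io import Residue, atom_residues, heavy_atoms

# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


@dataclass
class SASAParams:
    probe_radius: float = 1.4
    points_per_atom: int = 960
    radii_set_name: str = "bondi"
    include_hydrogens: bool = False

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise InputError("probe radius must be positive")
        if self.points_per_atom < 92:
            raise InputError("need at least 92 quadrature points per atom")


@dataclass
class SASAResult:
    per_atom_area: np.ndarray
    per_residue_area: dict
    total: float
    params: SASAParams
    atoms: list = field(default_factory=list, repr=False)
    # retained accessible quadrature points (filled on request)
    points: np.ndarray | None = field(default=None, repr=False)
    point_weights: np.ndarray | None = field(default=None, repr=False)
    point_owner: np.ndarray | None = field(default=None, repr=False)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# fixed stream for the per-atom lattice orientations; part of the quadrature
# scheme, not a tunable source of randomness
_ORIENTATION_SEED = 97
_N_ORIENTATIONS = 4096
_ORIENTATION_TABLE: np.ndarray | None = None


def _orientation_table() -> np.ndarray:
    global _ORIENTATION_TABLE
    if _ORIENTATION_TABLE is None:
        q = np.random.default_rng(_ORIENTATION_SEED).normal(size=(_N_ORIENTATIONS, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        w, x, y, z = q.T
        R = np.empty((_N_ORIENTATIONS, 3, 3))
        R[:, 0, 0] = 1 - 2 * (y * y + z * z); R[:, 0, 1] = 2 * (x * y - z * w)
        R[:, 0, 2] = 2 * (x * z + y * w)
        R[:, 1, 0] = 2 * (x * y + z * w); R[:, 1, 1] = 1 - 2 * (x * x + z * z)
        R[:, 1, 2] = 2 * (y * z - x * w)
        R[:, 2, 0] = 2 * (x * z - y * w); R[:, 2, 1] = 2 * (y * z + x * w)
        R[:, 2, 2] = 1 - 2 * (x * x + y * y)
        _ORIENTATION_TABLE = R
    return _ORIENTATION_TABLE


def _atom_orientations(centers: np.ndarray) -> np.ndarray:
    """Deterministic per-atom rotations of the quadrature lattice.

    Giving every atom its own lattice orientation decorrelates the
    cap-boundary discretization error between neighboring atoms, which
    markedly improves convergence of totals on periodic structures (helices,
    sheets) at fixed points_per_atom.  The orientation is keyed on the atom's
    coordinates (CRC of the position bytes), so results do not depend on the
    order in which atoms are listed.
    """
    import zlib

    table = _orientation_table()
    idx = np.array([zlib.crc32(c.tobytes()) % _N_ORIENTATIONS for c in centers])
    return table[idx]


def _collect_atoms(group, params: SASAParams):
    pairs = [(res, atom) for res, atom in atom_residues(group)
             if params.include_hydrogens or not atom.is_hydrogen]
    if not pairs:
        raise InputError("no atoms in group")
    for _, atom in pairs:
        if atom.vdw_radius is None:
            raise ConfigurationError(
                f"atom {atom.name} has no vdW radius; run assign_radii first")
    return pairs


def sasa(group, params: SASAParams | None = None, keep_points: bool = False) -> SASAResult:
    """Shrake–Rupley accessible surface area of a structure, chain or atom group."""
    params = params or SASAParams()
    pairs = _collect_atoms(group, params)
    residues = [res for res, _ in pairs]
    atoms = [atom for _, atom in pairs]
    centers = np.array([a.pos for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + params.probe_radius
    n_atoms = len(atoms)
    unit = fibonacci_sphere(params.points_per_atom)
    orientations = _atom_orientations(centers)
    tree = cKDTree(centers)
    max_r = radii.max()

    per_atom = np.zeros(n_atoms)
    kept_pts, kept_w, kept_owner = [], [], []
    for i in range(n_atoms):
        pts = centers[i] + radii[i] * (unit @ orientations[i].T)
        neighbors = [j for j in tree.query_ball_point(centers[i], radii[i] + max_r)
                     if j != i and np.linalg.norm(centers[j] - centers[i]) < radii[i] + radii[j]]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = ((pts - centers[j]) ** 2).sum(axis=1)
            accessible &= d2 >= radii[j] ** 2
        frac = accessible.mean()
        area = frac * 4.0 * np.pi * radii[i] ** 2
        per_atom[i] = area
        if keep_points and accessible.any():
            kept_pts.append(pts[accessible])
            w = 4.0 * np.pi * radii[i] ** 2 / params.points_per_atom
            kept_w.append(np.full(int(accessible.sum()), w))
            kept_owner.append(np.full(int(accessible.sum()), i))

    per_residue: dict = {}
    for res, area in zip(residues, per_atom):
        per_residue[res.id] = per_residue.get(res.id, 0.0) + area
    result = SASAResult(per_atom, per_residue, float(per_atom.sum()), params, atoms)
    if keep_points:
        result.points = np.vstack(kept_pts) if kept_pts else np.zeros((0, 3))
        result.point_weights = np.concatenate(kept_w) if kept_w else np.zeros(0)
        result.point_owner = np.concatenate(kept_owner) if kept_owner else np.zeros(0, dtype=int)
    return result


def buried_area(group_a, group_b, params: SASAParams | None = None
                ) -> tuple[float, float, float]:
    """Buried surface area: (total, A-side loss, B-side loss).

    ``total = SASA(A) + SASA(B) - SASA(A∪B)``; the per-side values are each
    group's own accessibility loss upon complexation, and sum to the total.
    """
    params = params or SASAParams()
    atoms_a = {id(atom) for atom in heavy_atoms(group_a)}
    atoms_b = {id(atom) for atom in heavy_atoms(group_b)}
    if atoms_a & atoms_b:
        raise InputError("groups share atoms; buried area requires disjoint groups")
    res_a = sasa(group_a, params)
    res_b = sasa(group_b, params)
    res_ab = sasa([group_a, group_b], params)
    n_a = len(res_a.per_atom_area)
    bsa_a = float(res_a.total - res_ab.per_atom_area[:n_a].sum())
    bsa_b = float(res_b.total - res_ab.per_atom_area[n_a:].sum())
    return bsa_a + bsa_b, bsa_a, bsa_b


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# donor heavy atom -> bonded antecedent used for the angle criterion
_SIDECHAIN_DONORS = {
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"}, "GLN": {"NE2": "CD"}, "HIS": {"ND1": "CG", "NE2": "CD2"},
    "LYS": {"NZ": "CE"}, "TRP": {"NE1": "CD1"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1": "CG", "OD2": "CG"}, "GLU": {"OE1": "CD", "OE2": "CD"},
    "ASN": {"OD1": "CG"}, "GLN": {"OE1": "CD"},
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "MET": {"SD": "CG"}, "CYS": {"SG": "CB"},
}


@dataclass
class HBondCriteria:
    max_distance: float = 3.6
    min_antecedent_angle: float = 90.0  # degrees, D-antecedent...D...A


@dataclass
class HBond:
    donor_residue: Residue
    donor_atom: object
    acceptor_residue: Residue
    acceptor_atom: object
    distance: float
    antecedent_angle: float | None
    classification: str  # side-side | side-main | main-main

    def label(self) -> str:
        return (f"{self.donor_residue.label}:{self.donor_atom.name}"
                f"--{self.acceptor_residue.label}:{self.acceptor_atom.name}"
                f" {self.distance:.2f} A")


def _donors(group):
    out = []
    for res, atom in atom_residues(group):
        if atom.is_hydrogen:
            continue
        if atom.name == "N" and res.name != "PRO":
            out.append((res, atom, res.atom("CA")))
        ante_name = _SIDECHAIN_DONORS.get(res.name, {}).get(atom.name)
        if ante_name:
            out.append((res, atom, res.atom(ante_name)))
    return out


def _acceptors(group):
    out = []
    for res, atom in atom_residues(group):
        if atom.is_hydrogen:
            continue
        if atom.name in ("O", "OXT"):
            out.append((res, atom, res.atom("C")))
        ante_name = _SIDECHAIN_ACCEPTORS.get(res.name, {}).get(atom.name)
        if ante_name:
            out.append((res, atom, res.atom(ante_name)))
    return out


def _classify(donor_atom, acceptor_atom) -> str:
    d_main = donor_atom.name in BACKBONE_ATOMS
    a_main = acceptor_atom.name in BACKBONE_ATOMS
    if d_main and a_main:
        return "main-main"
    if d_main or a_main:
        return "side-main"
    return "side-side"


def _hbonds_directed(donors, acceptors, criteria: HBondCriteria) -> list[HBond]:
    if not donors or not acceptors:
        return []
    d_pos = np.array([a.pos for _, a, _ in donors])
    a_pos = np.array([a.pos for _, a, _ in acceptors])
    tree = cKDTree(a_pos)
    bonds = []
    for i, (d_res, d_atom, d_ante) in enumerate(donors):
        for j in tree.query_ball_point(d_pos[i], criteria.max_distance):
            a_res, a_atom, _ = acceptors[j]
            if a_res.id == d_res.id:
                continue
            dist = float(np.linalg.norm(a_pos[j] - d_pos[i]))
            if dist > criteria.max_distance or dist < 0.1:
                continue
            angle = None
            if d_ante is not None:
                v1 = d_ante.pos - d_atom.pos
                v2 = a_atom.pos - d_atom.pos
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom > 1e-9:
                    angle = float(np.degrees(np.arccos(
                        np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))))
                    if angle < criteria.min_antecedent_angle:
                        continue
            bonds.append(HBond(d_res, d_atom, a_res, a_atom, round(dist, 2),
                               angle, _classify(d_atom, a_atom)))
    return bonds


def hydrogen_bonds(group_a, group_b, criteria: HBondCriteria | None = None) -> list[HBond]:
    """Inter-group hydrogen bonds on heavy-atom donor/acceptor geometry.

    Both directions (donor in A, acceptor in B and vice versa) are searched;
    a donor-acceptor atom pair satisfying both roles is reported once.
    """
    criteria = criteria or HBondCriteria()
    bonds = _hbonds_directed(_donors(group_a), _acceptors(group_b), criteria)
    bonds += _hbonds_directed(_donors(group_b), _acceptors(group_a), criteria)
    seen, unique = set(), []
    for b in bonds:
        key = frozenset([(b.donor_residue.id, b.donor_atom.name),
                         (b.acceptor_residue.id, b.acceptor_atom.name)])
        if key not in seen:
            seen.add(key)
            unique.append(b)
    unique.sort(key=lambda b: (b.donor_residue.id, b.donor_atom.name,
                               b.acceptor_residue.id, b.acceptor_atom.name))
    return unique


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def contact_map(group_a, group_b, cutoff: float = 4.5
                ) -> tuple[list[Residue], list[Residue]]:
    """Residues of each group with any heavy atom within ``cutoff`` of the other."""
    pairs_a = [(r, a) for r, a in atom_residues(group_a) if not a.is_hydrogen]
    pairs_b = [(r, a) for r, a in atom_residues(group_b) if not a.is_hydrogen]
    if not pairs_a or not pairs_b:
        return [], []
    pos_a = np.array([a.pos for _, a in pairs_a])
    pos_b = np.array([a.pos for _, a in pairs_b])
    tree_b = cKDTree(pos_b)
    hits = tree_b.query_ball_point(pos_a, cutoff)
    ids_a, ids_b = {}, {}
    for (res_a, _), hit in zip(pairs_a, hits):
        if hit:
            ids_a.setdefault(res_a.id, res_a)
            for j in hit:
                res_b = pairs_b[j][0]
                ids_b.setdefault(res_b.id, res_b)
    order = lambda r: (r.chain_id, r.seq_number, r.insertion_code)
    return sorted(ids_a.values(), key=order), sorted(ids_b.values(), key=order)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

# planar side-chain groups: aromatic rings and the arginine guanidinium plane
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
}


@dataclass
class StackingCriteria:
    max_centroid_distance: float = 4.5
    max_plane_angle: float = 30.0  # parallel stacking only; T-shaped off by default


@dataclass
class StackingPair:
    residue_a: Residue
    residue_b: Residue
    centroid_distance: float
    plane_angle: float


def _ring_geometry(res: Residue):
    names = RING_ATOMS.get(res.name)
    if not names:
        return None
    atoms = [res.atom(n) for n in names]
    if any(a is None for a in atoms):
        return None
    pts = np.array([a.pos for a in atoms])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]  # plane normal = direction of least extent


def stacking_pairs(group_a, group_b, criteria: StackingCriteria | None = None
                   ) -> list[StackingPair]:
    """Parallel pi-pi / cation-pi pairs between planar side-chain groups."""
    criteria = criteria or StackingCriteria()
    rings_a = [(r, g) for r in _unique_residues(group_a) if (g := _ring_geometry(r))]
    rings_b = [(r, g) for r in _unique_residues(group_b) if (g := _ring_geometry(r))]
    pairs = []
    for res_a, (cen_a, n_a) in rings_a:
        for res_b, (cen_b, n_b) in rings_b:
            if res_a.id == res_b.id:
                continue
            dist = float(np.linalg.norm(cen_a - cen_b))
            if dist > criteria.max_centroid_distance:
                continue
            cos_angle = abs(float(np.dot(n_a, n_b)))
            angle = float(np.degrees(np.arccos(np.clip(cos_angle, 0.0, 1.0))))
            if angle <= criteria.max_plane_angle:
                pairs.append(StackingPair(res_a, res_b, dist, angle))
    pairs.sort(key=lambda p: (p.residue_a.id, p.residue_b.id))
    return pairs


def _unique_residues(group):
    seen, out = set(), []
    for res, _ in atom_residues(group):
        if res.id not in seen:
            seen.add(res.id)
            out.append(res)
    return out


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------


@dataclass
class InterfaceReport:
    group_a_label: str
    group_b_label: str
    bsa_total: float
    bsa_a_side: float
    bsa_b_side: float
    hbonds: list[HBond]
    stacking: list[StackingPair]
    contacts_a: list[Residue]
    contacts_b: list[Residue]
    contact_cutoff: float
    sasa_params: SASAParams

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a_label,
            "group_b": self.group_b_label,
            "bsa_total": round(self.bsa_total, 1),
            "bsa_a_side": round(self.bsa_a_side, 1),
            "bsa_b_side": round(self.bsa_b_side, 1),
            "n_hbonds": len(self.hbonds),
            "hbonds": [{
                "donor": f"{b.donor_residue.label}:{b.donor_atom.name}",
                "acceptor": f"{b.acceptor_residue.label}:{b.acceptor_atom.name}",
                "distance": b.distance,
                "class": b.classification,
            } for b in self.hbonds],
            "stacking": [{
                "a": p.residue_a.label, "b": p.residue_b.label,
                "centroid_distance": round(p.centroid_distance, 2),
                "plane_angle": round(p.plane_angle, 1),
            } for p in self.stacking],
            "contacts_a": [r.label for r in self.contacts_a],
            "contacts_b": [r.label for r in self.contacts_b],
            "params": {
                "probe_radius": self.sasa_params.probe_radius,
                "points_per_atom": self.sasa_params.points_per_atom,
                "radii_set": self.sasa_params.radii_set_name,
                "contact_cutoff": self.contact_cutoff,
            },
        }


def interface_report(group_a, group_b, label_a: str = "A", label_b: str = "B",
                     sasa_params: SASAParams | None = None,
                     hbond_criteria: HBondCriteria | None = None,
                     stacking_criteria: StackingCriteria | None = None,
                     contact_cutoff: float = 4.5) -> InterfaceReport:
    """One report combining buried area, H-bonds, stacking and contact sets."""
    sasa_params = sasa_params or SASAParams()
    total, side_a, side_b = buried_area(group_a, group_b, sasa_params)
    bonds = hydrogen_bonds(group_a, group_b, hbond_criteria)
    stacks = stacking_pairs(group_a, group_b, stacking_criteria)
    contacts_a, contacts_b = contact_map(group_a, group_b, contact_cutoff)
    return InterfaceReport(label_a, label_b, total, side_a, side_b, bonds,
                           stacks, contacts_a, contacts_b, contact_cutoff, sasa_params)
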