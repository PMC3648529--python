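"""Screened-Coulomb surface potential and charged-patch detection.

The goal is topological, not quantitative: locate the basic (positively
charged) faces of a trimeric cytokine — the receptor-binding side patch and
the glycosaminoglycan-binding top patch — on the solvent-accessible surface.
A Debye-screened Coulomb sum over formal side-chain charges is entirely
adequate for that question and keeps the computation deterministic and fast;
a Poisson–Boltzmann solver is deliberately out of scope.

Potentials are expressed in kT/e at 298 K.  With distances in Angstrom the
unscreened potential of a unit charge is ``l_B(eps_r)/d`` kT/e, where
``l_B = e^2/(4 pi eps_0 eps_r kT)`` is the Bjerrum length (about 7.0 A in
water, eps_r = 80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import InputError
from .interface import SASAParams, sasa
from .structure_io import Residue, Structure, atom_residues

# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------


@dataclass
class ChargeScheme:
    """Formal charges distributed over the terminal heavy atoms of charged groups."""

    name: str = "formal-ph7"
    # (residue name, atom name) -> charge in elementary units
    rules: dict = field(default_factory=lambda: {
        ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
        ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
        ("LYS", "NZ"): +1.0,
        ("ARG", "NH1"): +0.5, ("ARG", "NH2"): +0.5,
        # histidine neutral at pH 7.4
    })
    n_terminus_charge: float = +1.0  # on the first residue's N
    c_terminus_charge: float = -1.0  # on OXT when modeled
    include_termini: bool = True


KNOWN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL", "MSE",
}


def assign_charges(structure: Structure, scheme: ChargeScheme | None = None) -> Structure:
    """Assign per-atom partial charges in place; returns the structure."""
    scheme = scheme or ChargeScheme()
    unknown = set()
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.charge = scheme.rules.get((res.name, atom.name), 0.0)
            if res.name not in KNOWN_RESIDUES and res.name not in ("HOH", "WAT"):
                if (res.name, res.atoms[0].name) not in scheme.rules:
                    unknown.add(res.name)
        if scheme.include_termini and chain.entity_kind == "polymer" and chain.residues:
            first_n = chain.residues[0].atom("N")
            if first_n is not None:
                first_n.charge += scheme.n_terminus_charge
            oxt = chain.residues[-1].atom("OXT")
            if oxt is not None:
                oxt.charge += scheme.c_terminus_charge
    if unknown:
        warnings.warn(f"no charge rules for residues {sorted(unknown)}; left neutral",
                      stacklevel=2)
    return structure


def total_charge(structure: Structure) -> float:
    return float(sum(a.charge for a in structure.atoms()))


# ---------------------------------------------------------------------------
# surface field
# ---------------------------------------------------------------------------


@dataclass
class SurfaceField:
    points: np.ndarray          # (N,3) accessible quadrature points
    values: np.ndarray          # potential in kT/e
    weights: np.ndarray         # per-point area weight, A^2
    owner_residues: list[Residue]

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise InputError("non-finite potential values")


def surface_points(group, params: SASAParams | None = None):
    """Accessible quadrature points of the probe-expanded surface.

    Returns ``(points, weights, owner_residues)``; the weights sum to the
    total SASA of the group.
    """
    result = sasa(group, params, keep_points=True)
    pairs = [(res, atom) for res, atom in atom_residues(group)
             if (params or SASAParams()).include_hydrogens or not atom.is_hydrogen]
    residues = [res for res, _ in pairs]
    owners = [residues[i] for i in result.point_owner]
    return result.points, result.point_weights, owners


@dataclass
class ScreenedCoulombModel:
    screening_length: float = 8.0   # A; Debye-like exponential damping
    dielectric: float = 80.0
    temperature: float = 298.0      # K
    min_distance: float = 0.5       # A; closer charges are clamped

    def bjerrum_length(self) -> float:
        e, eps0, kb = constants.e, constants.epsilon_0, constants.k
        meters = e ** 2 / (4 * np.pi * eps0 * self.dielectric * kb * self.temperature)
        return meters * 1e10  # -> Angstrom


def potential_at(points, charged_structure: Structure,
                 model: ScreenedCoulombModel | None = None) -> np.ndarray:
    """Screened-Coulomb potential (kT/e) of the structure's charges at the points."""
    model = model or ScreenedCoulombModel()
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    atoms = [a for a in charged_structure.atoms() if a.charge != 0.0]
    if not atoms:
        return np.zeros(len(pts))
    centers = np.array([a.pos for a in atoms])
    charges = np.array([a.charge for a in atoms])
    prefactor = model.bjerrum_length()
    values = np.zeros(len(pts))
    clamped = 0
    # chunked double loop keeps memory bounded for large assemblies
    chunk = 2048
    for start in range(0, len(pts), chunk):
        block = pts[start:start + chunk]
        d = np.linalg.norm(block[:, None, :] - centers[None, :, :], axis=2)
        close = d < model.min_distance
        clamped += int(close.sum())
        d = np.maximum(d, model.min_distance)
        lam = model.screening_length
        screen = np.exp(-d / lam) if np.isfinite(lam) else 1.0
        values[start:start + chunk] = prefactor * (charges[None, :] * screen / d).sum(axis=1)
    if clamped:
        warnings.warn(f"{clamped} point-charge distances below {model.min_distance} A clamped",
                      stacklevel=2)
    return values


def surface_field(structure: Structure, sasa_params: SASAParams | None = None,
                  model: ScreenedCoulombModel | None = None,
                  scheme: ChargeScheme | None = None) -> SurfaceField:
    """Convenience composition: charges -> surface points -> potential."""
    assign_charges(structure, scheme)
    points, weights, owners = surface_points(structure, sasa_params)
    values = potential_at(points, structure, model)
    return SurfaceField(points, values, weights, owners)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------


@dataclass
class SurfacePatch:
    member_indices: np.ndarray
    area: float
    mean_potential: float
    sign: int
    centroid: np.ndarray
    location_class: str | None = None  # top | bottom | side
    member_residues: list[Residue] = field(default_factory=list)

    def residue_ids(self) -> set:
        return {r.id for r in self.member_residues}


def _cluster(points: np.ndarray, link_radius: float) -> np.ndarray:
    """Single-linkage clustering: connected components of the link-radius graph."""
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(link_radius, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        graph = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = csr_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def find_patches(field: SurfaceField, threshold_kT: float = 2.0,
                 link_radius: float = 5.0, min_area: float = 50.0,
                 axis: np.ndarray | None = None, axis_point: np.ndarray | None = None,
                 top_fraction: float = 0.25) -> list[SurfacePatch]:
    """Cluster same-sign super-threshold surface points into charged patches.

    ``axis``/``axis_point`` (the molecular 3-fold) enable the location
    classification: a patch whose centroid projects into the highest
    ``top_fraction`` of the assembly's axial extent is "top", the lowest is
    "bottom", anything else "side".  The axial orientation is the caller's
    responsibility (point the axis toward the membrane-proximal face).
    """
    if threshold_kT <= 0:
        raise InputError("threshold must be positive (sign handled internally)")
    patches: list[SurfacePatch] = []
    for sign in (+1, -1):
        mask = (sign * field.values) >= threshold_kT
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        labels = _cluster(field.points[idx], link_radius)
        for lab in np.unique(labels):
            members = idx[labels == lab]
            area = float(field.weights[members].sum())
            if area < min_area:
                continue
            weights = field.weights[members]
            centroid = (field.points[members] * weights[:, None]).sum(axis=0) / weights.sum()
            residues = []
            seen = set()
            for i in members:
                res = field.owner_residues[i]
                if res.id not in seen:
                    seen.add(res.id)
                    residues.append(res)
            patches.append(SurfacePatch(
                members, area,
                float(np.average(field.values[members], weights=weights)),
                sign, centroid, None, residues))
    if axis is not None:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        origin = np.zeros(3) if axis_point is None else np.asarray(axis_point, dtype=float)
        proj_all = (field.points - origin) @ axis
        lo, hi = float(proj_all.min()), float(proj_all.max())
        span = max(hi - lo, 1e-9)
        for patch in patches:
            s = float((patch.centroid - origin) @ axis)
            frac = (s - lo) / span
            if frac >= 1.0 - top_fraction:
                patch.location_class = "top"
            elif frac <= top_fraction:
                patch.location_class = "bottom"
            else:
                patch.location_class = "side"
    patches.sort(key=lambda p: -p.area)
    return patches


def orient_axis_toward_termini(structure: Structure, axis: np.ndarray,
                               axis_point: np.ndarray) -> np.ndarray:
    """Flip the axis so it points toward the chain-termini face.

    For a type-II membrane cytokine the N/C termini of the homology domain
    face the membrane; with this orientation "top" means membrane-proximal.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    origin = np.asarray(axis_point, dtype=float)
    termini, everything = [], []
    for chain in structure.polymer_chains():
        if not chain.residues:
            continue
        for res in (chain.residues[0], chain.residues[-1]):
            ca = res.atom("CA") or res.atoms[0]
            termini.append(ca.pos)
        everything.extend(a.pos for a in chain.atoms())
    if not termini:
        return axis
    t_proj = np.mean([(p - origin) @ axis for p in termini])
    mid = np.mean([(p - origin) @ axis for p in everything])
    return axis if t_proj >= mid else -axis
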