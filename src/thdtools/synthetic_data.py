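"""Deterministic synthetic structures with analytic oracles.

Every generator is a pure function of its parameters (plus an explicit seed
where randomness is involved), and the analytic values it returns — sphere and
two-sphere accessible areas, ideal helix geometry, exact C3 operators — are
computed from closed forms that are independent of the modules they test.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .geometry import RigidTransform
from .structure_io import (
    Atom,
    Chain,
    CrystalInfo,
    Residue,
    Structure,
    assign_radii,
)
from .symmetry import apply_transform

DEFAULT_PROBE = 1.4


def _single_atom_structure(name, element, pos, resname="LIG", chain_id="A",
                           kind="non-polymer") -> Structure:
    atom = Atom(name, element, np.asarray(pos, dtype=float))
    res = Residue(chain_id, 1, "", resname, [atom])
    return Structure([Chain(chain_id, [res], kind)], source_id="synthetic")


def make_sphere(radius: float = 1.70, element: str = "C") -> Structure:
    """Single hard-sphere atom at the origin with the requested vdW radius."""
    if radius <= 0:
        raise InputError("sphere radius must be positive")
    st = _single_atom_structure("X1", element, (0.0, 0.0, 0.0))
    st.atoms()[0].vdw_radius = float(radius)
    return st


def sphere_area(radius: float, probe: float = DEFAULT_PROBE) -> float:
    """Closed-form accessible area of an isolated sphere."""
    return 4.0 * np.pi * (radius + probe) ** 2


def two_sphere_areas(r1: float, r2: float, distance: float,
                     probe: float = DEFAULT_PROBE) -> dict:
    """Closed-form accessible/buried areas of two probe-expanded spheres.

    Uses the spherical-cap formula: the part of sphere 1 (radius R1 = r1+probe)
    hidden inside sphere 2 is the cap with polar angle cos(theta) =
    (R1^2 + d^2 - R2^2) / (2 R1 d).
    """
    if min(r1, r2) <= 0 or distance < 0:
        raise InputError("radii must be positive and distance non-negative")
    R1, R2, d = r1 + probe, r2 + probe, distance
    full1, full2 = 4 * np.pi * R1 ** 2, 4 * np.pi * R2 ** 2

    def exposed(Ra, Rb):
        if d >= Ra + Rb:            # disjoint
            return 4 * np.pi * Ra ** 2
        if d + Ra <= Rb:            # fully engulfed
            return 0.0
        if d + Rb <= Ra:            # engulfs the other
            return 4 * np.pi * Ra ** 2
        cos_t = (Ra ** 2 + d ** 2 - Rb ** 2) / (2 * Ra * d)
        return 2 * np.pi * Ra ** 2 * (1.0 + cos_t)

    a1, a2 = exposed(R1, R2), exposed(R2, R1)
    return {
        "area_1": a1,
        "area_2": a2,
        "total": a1 + a2,
        "buried_total": (full1 + full2) - (a1 + a2),
        "buried_1": full1 - a1,
        "buried_2": full2 - a2,
    }


def make_two_sphere(r1: float, r2: float, distance: float,
                    elements=("C", "C"), probe: float = DEFAULT_PROBE
                    ) -> tuple[Structure, dict]:
    """Two hard-sphere atoms on the x axis plus their analytic area oracle."""
    a1 = Atom("X1", elements[0], (0.0, 0.0, 0.0), vdw_radius=float(r1))
    a2 = Atom("X2", elements[1], (float(distance), 0.0, 0.0), vdw_radius=float(r2))
    chain_a = Chain("A", [Residue("A", 1, "", "LIG", [a1])], "non-polymer")
    chain_b = Chain("B", [Residue("B", 1, "", "LIG", [a2])], "non-polymer")
    st = Structure([chain_a, chain_b], source_id="synthetic")
    return st, two_sphere_areas(r1, r2, distance, probe)


# ---------------------------------------------------------------------------
# ideal helix via internal-coordinate (NeRF) chain extension
# ---------------------------------------------------------------------------

# standard backbone geometry (Engh–Huber-type values)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.530}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "N-CA-CB": 110.5}
PHI_HELIX, PSI_HELIX, OMEGA = -57.0, -47.0, 180.0


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom D given three predecessors A-B-C, |CD|, angle(BCD), dihedral(ABCD)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix(n_residues: int, chain_id: str = "A", phi: float = PHI_HELIX,
               psi: float = PSI_HELIX) -> Structure:
    """Ideal alpha-helical poly-alanine with full backbone (N, CA, C, O) + CB."""
    if n_residues < 1:
        raise InputError("helix needs at least one residue")
    # seed the first residue explicitly
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_BOND["N-CA"], 0.0, 0.0])
    # residue 1 has no preceding C; the dihedral reference is an arbitrary dummy
    C = _place_atom(np.array([0.0, 0.0, -1.0]), N, CA, _BOND["CA-C"],
                    _ANGLE["N-CA-C"], psi)
    backbone = [(N, CA, C)]
    for _ in range(1, n_residues):
        prev_n, prev_ca, prev_c = backbone[-1]
        new_n = _place_atom(prev_n, prev_ca, prev_c, _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        new_ca = _place_atom(prev_ca, prev_c, new_n, _BOND["N-CA"], _ANGLE["C-N-CA"], OMEGA)
        new_c = _place_atom(prev_c, new_n, new_ca, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        backbone.append((new_n, new_ca, new_c))
    residues = []
    for i, (n_pos, ca_pos, c_pos) in enumerate(backbone, start=1):
        atoms = [Atom("N", "N", n_pos), Atom("CA", "C", ca_pos), Atom("C", "C", c_pos)]
        if i < n_residues:
            next_n = backbone[i][0]
            o_pos = _place_atom(next_n, ca_pos, c_pos, _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
        else:
            o_pos = _place_atom(n_pos, ca_pos, c_pos, _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
        atoms.append(Atom("O", "O", o_pos))
        atoms.append(Atom("CB", "C", _place_atom(c_pos, n_pos, ca_pos, _BOND["CA-CB"],
                                                 _ANGLE["N-CA-CB"], 122.5)))
        residues.append(Residue(chain_id, i, "", "ALA", atoms))
    return Structure([Chain(chain_id, residues, "polymer")], source_id="synthetic_helix")


# ---------------------------------------------------------------------------
# C3 trimer
# ---------------------------------------------------------------------------

P3_TRIPLETS = ["x,y,z", "-y,x-y,z", "-x+y,-x,z"]


def p3_crystal_info(a: float = 60.0, c: float = 40.0) -> CrystalInfo:
    """Hexagonal P3-like cell whose Cartesian operators are exact z rotations."""
    return CrystalInfo(a, a, c, 90.0, 90.0, 120.0, "P 3", list(P3_TRIPLETS))


def make_c3_trimer(protomer: Structure | None = None, axis=(0.0, 0.0, 1.0),
                   point=(0.0, 0.0, 0.0)) -> tuple[Structure, list[RigidTransform]]:
    """Exact 3-fold assembly: protomer plus its 120 and 240 degree copies.

    Returns the trimer and the three generating transforms so that the
    symmetry machinery can be cross-checked against them.  For the default z
    axis the trimer also carries a hexagonal P3 cell whose operators reproduce
    the same transforms through fractional conjugation.
    """
    if protomer is None:
        # default protomer: helix re-centered on the rotation axis, then pushed
        # out radially so that adjacent mates form a genuine contact interface
        protomer = make_helix(8)
        from .structure_io import coords_of
        center = coords_of(protomer).mean(axis=0)
        offset = RigidTransform(np.eye(3), np.array([6.0 - center[0], -center[1], 0.0]))
        protomer = apply_transform(protomer, offset)
    transforms = [RigidTransform.identity()] + [
        RigidTransform.from_axis_angle(axis, angle, point) for angle in (120.0, 240.0)]
    trimer = Structure([], None, protomer.source_id + "_c3", protomer.model_number)
    for k, transform in enumerate(transforms):
        suffix = None if k == 0 else f"_s{k}"
        for chain in protomer.chains:
            trimer.add_chain(apply_transform(chain, transform, suffix))
    axis_arr = np.asarray(axis, dtype=float)
    if np.allclose(axis_arr / np.linalg.norm(axis_arr), [0, 0, 1]) and \
            np.allclose(np.asarray(point, dtype=float), 0.0):
        trimer.crystal_info = p3_crystal_info()
    return trimer, transforms


# ---------------------------------------------------------------------------
# hydrogen-bond fixture
# ---------------------------------------------------------------------------


def make_hbond_pair(distance: float = 2.9, angle_deg: float = 120.0
                    ) -> tuple[Structure, Structure]:
    """Backbone amide donor facing a carbonyl acceptor at prescribed geometry.

    Returns two single-residue structures: the donor residue (with N and its
    antecedent CA placed so that angle(CA-N...O) equals ``angle_deg``) and the
    acceptor residue (with C=O).
    """
    n_pos = np.array([0.0, 0.0, 0.0])
    o_pos = np.array([float(distance), 0.0, 0.0])
    theta = np.deg2rad(angle_deg)
    # CA at unit-ish bond length from N, in the xy-plane, at the requested angle to N->O
    ca_pos = n_pos + 1.458 * np.array([np.cos(theta), np.sin(theta), 0.0])
    donor_atoms = [Atom("N", "N", n_pos), Atom("CA", "C", ca_pos)]
    donor = Structure([Chain("D", [Residue("D", 1, "", "ALA", donor_atoms)], "polymer")],
                      source_id="synthetic_donor")
    c_pos = o_pos + 1.231 * np.array([np.cos(np.deg2rad(30.0)), np.sin(np.deg2rad(30.0)), 0.0])
    ca2 = c_pos + 1.525 * np.array([1.0, 0.0, 0.0])
    acceptor_atoms = [Atom("O", "O", o_pos), Atom("C", "C", c_pos), Atom("CA", "C", ca2)]
    acceptor = Structure([Chain("E", [Residue("E", 2, "", "ALA", acceptor_atoms)], "polymer")],
                         source_id="synthetic_acceptor")
    return donor, acceptor


# ---------------------------------------------------------------------------
# random rigid transforms
# ---------------------------------------------------------------------------


def random_rigid_transform(seed_or_rng=0, translation_range: float = 50.0) -> RigidTransform:
    """Rotation uniform on SO(3) (normalized-quaternion method), translation
    uniform in [-range, range]^3."""
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-translation_range, translation_range, size=3)
    return RigidTransform(R, t, atol=1e-8)


# ---------------------------------------------------------------------------
# charged slab
# ---------------------------------------------------------------------------


def make_charged_slab(nx: int = 6, ny: int = 6, charge_face: str = "top",
                      spacing: float = 4.0, charge: float = 1.0,
                      thickness: float = 20.0) -> Structure:
    """Two-layer atom grid with one face carrying lysine-like +1 charges.

    The charged layer is built from LYS NZ-type nitrogen atoms so that both
    the default charge scheme and direct per-atom charges agree on it; the
    neutral layer is carbon.  ``charge_face`` in {"top", "none"}.  The default
    layer separation of 20 A is about 2.5 screening lengths, so the neutral
    face sits well below the usual 2 kT/e patch threshold while the charged
    face sits well above it — a clean construction oracle for patch detection.
    """
    if charge_face not in ("top", "none"):
        raise InputError("charge_face must be 'top' or 'none'")
    chains = []
    resnum = 0
    for layer, z in (("bottom", 0.0), ("top", thickness)):
        residues = []
        charged = layer == "top" and charge_face == "top"
        for i in range(nx):
            for j in range(ny):
                resnum += 1
                pos = np.array([i * spacing, j * spacing, z])
                if charged:
                    atom = Atom("NZ", "N", pos, charge=float(charge))
                    residues.append(Residue(layer[0].upper(), resnum, "", "LYS", [atom]))
                else:
                    atom = Atom("C1", "C", pos, charge=0.0)
                    residues.append(Residue(layer[0].upper(), resnum, "", "SLB", [atom]))
        chains.append(Chain(layer[0].upper(), residues, "non-polymer"))
    st = Structure(chains, source_id="synthetic_slab")
    assign_radii(st)
    return st
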