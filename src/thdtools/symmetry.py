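"""Crystallographic symmetry: fractional frames, operator algebra, assembly expansion.

The biological TWEAK trimer is not present as three chains in the asymmetric
unit — it is generated by the crystallographic 3-fold of space group P3.  This
module turns fractional-space operator triplets into exact Cartesian rigid
transforms (conjugation with the orthogonalization matrix) and expands a
protomer into the full point-group assembly.  The detected molecular 3-fold
axis is later used to classify surface patches as "top" or "side".
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .errors import GeometryError, InputError, MetadataError, ParseError, SymmetryDetectionError
from .geometry import RigidTransform
from .structure_io import Chain, CrystalInfo, Structure, coords_of, extract_sequence

SYMMETRY_CHAIN_SUFFIX = "_s"  # mate k of chain A is named A_s<k>


@dataclass(frozen=True)
class FractionalFrame:
    """Orthogonalization / fractionalization matrix pair for a unit cell.

    Convention: crystal axis a along Cartesian x, b in the xy-plane (the
    standard PDB CRYST1 convention, so deposited coordinates round-trip).
    """

    orthogonalization: np.ndarray  # fractional -> Cartesian
    fractionalization: np.ndarray  # Cartesian -> fractional

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def to_fractional(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.fractionalization.T


def frames_from_cell(crystal_info: CrystalInfo) -> FractionalFrame:
    """Build the orthogonalization pair from cell lengths and angles."""
    a, b, c = crystal_info.a, crystal_info.b, crystal_info.c
    al, be, ga = np.deg2rad([crystal_info.alpha, crystal_info.beta, crystal_info.gamma])
    ca, cb, cg, sg = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
    vol_factor = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if vol_factor <= 0 or abs(sg) < 1e-12:
        raise GeometryError("degenerate cell: volume <= 0")
    v = np.sqrt(vol_factor)
    orth = np.array([
        [a, b * cg, c * cb],
        [0.0, b * sg, c * (ca - cb * cg) / sg],
        [0.0, 0.0, c * v / sg],
    ])
    frac = np.linalg.inv(orth)
    if np.abs(orth @ frac - np.eye(3)).max() > 1e-10:
        raise GeometryError("orthogonalization/fractionalization pair failed to invert")
    return FractionalFrame(orth, frac)


def parse_symop(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a triplet like ``-Y,X-Y,Z`` into fractional (rotation, translation)."""
    if not isinstance(triplet, str) or not triplet.strip():
        raise ParseError("empty symmetry-operator triplet")
    allowed = set("xyzXYZ0123456789+-/,. ")
    for pos, char in enumerate(triplet):
        if char not in allowed:
            raise ParseError(f"bad character {char!r} at position {pos} in triplet {triplet!r}")
    try:
        op = gemmi.Op(triplet.lower().replace(" ", ""))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"malformed triplet {triplet!r}: {exc}") from exc
    den = float(gemmi.Op.DEN)
    rot = np.array(op.rot, dtype=float) / den
    tran = np.array(op.tran, dtype=float) / den
    return rot, tran


def cartesian_operator(triplet: str, frame: FractionalFrame,
                       atol: float = 1e-9) -> RigidTransform:
    """Conjugate a fractional operator into a Cartesian rigid transform."""
    rot_f, tran_f = parse_symop(triplet)
    R = frame.orthogonalization @ rot_f @ frame.fractionalization
    t = frame.orthogonalization @ tran_f
    return RigidTransform(R, t, atol=max(atol, 1e-9))


def apply_transform(obj, transform: RigidTransform, chain_suffix: str | None = None):
    """Return a transformed deep copy of a Structure or Chain.

    Positions are mapped ``r -> R r + t``; all other metadata is preserved.
    ``chain_suffix`` is appended to every chain id of the copy.
    """
    if isinstance(obj, Chain):
        chain = obj.copy(obj.id + chain_suffix if chain_suffix else obj.id)
        for res in chain.residues:
            for atom in res.atoms:
                atom.pos = transform.apply(atom.pos)
        return chain
    if isinstance(obj, Structure):
        moved = obj.copy()
        moved.chains = [apply_transform(c, transform, chain_suffix) for c in obj.chains]
        return moved
    raise InputError(f"cannot transform object of type {type(obj).__name__}")


def expand_assembly(protomer: Structure, crystal_info: CrystalInfo | None = None,
                    operator_subset=None) -> Structure:
    """Expand a protomer by the point-group operators of its crystal form.

    One copy per operator; the identity copy keeps the original chain ids,
    mate k gets ids suffixed ``_s<k>``.  Operator translations are applied as
    given — no packing (±1 cell) search, only the point-group expansion needed
    for an in-place assembly such as the P3 trimer.
    """
    ci = crystal_info or protomer.crystal_info
    if ci is None:
        raise MetadataError("expand_assembly needs crystal_info (cell + operators)")
    triplets = list(operator_subset) if operator_subset is not None else list(ci.symmetry_operators)
    if not triplets:
        raise MetadataError("no symmetry operators given")
    frame = frames_from_cell(ci)
    transforms = [cartesian_operator(tr, frame) for tr in triplets]

    assembly = Structure([], ci, protomer.source_id + "_assembly", protomer.model_number)
    identity_used = False
    mate = 0
    for transform in transforms:
        if transform.is_identity(tol=1e-6) and not identity_used:
            identity_used = True
            for chain in protomer.chains:
                assembly.add_chain(chain.copy())
            continue
        mate += 1
        suffix = f"{SYMMETRY_CHAIN_SUFFIX}{mate}"
        for chain in protomer.chains:
            assembly.add_chain(apply_transform(chain, transform, suffix))
    return assembly


def equivalent_chain_groups(assembly: Structure) -> list[list[Chain]]:
    """Group polymer chains by identical sequence (the symmetry-mate families)."""
    groups: dict[str, list[Chain]] = {}
    for chain in assembly.polymer_chains():
        groups.setdefault(extract_sequence(chain), []).append(chain)
    return [chains for chains in groups.values() if len(chains) > 1] or \
        [chains for chains in groups.values()]


def molecular_axis(assembly: Structure, chain_ids=None, rmsd_threshold: float = 2.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit rotation axis of the transform mapping mate 1 onto mate 2.

    Returns ``(unit direction, point on axis)``.  Requires at least three
    equivalent chains (same sequence); raises if the mates do not superpose
    within ``rmsd_threshold``.
    """
    from .superpose import kabsch  # local import to avoid a module cycle

    if chain_ids is not None:
        chains = [assembly[cid] for cid in chain_ids]
    else:
        groups = sorted(equivalent_chain_groups(assembly), key=len, reverse=True)
        chains = groups[0] if groups else []
    if len(chains) < 3:
        raise SymmetryDetectionError(
            f"need >= 3 equivalent chains to define a molecular axis, got {len(chains)}")
    a, b = coords_of(chains[0]), coords_of(chains[1])
    if len(a) != len(b):
        raise SymmetryDetectionError("equivalent chains have different atom counts")
    result = kabsch(a, b)
    if result.rmsd > rmsd_threshold:
        raise SymmetryDetectionError(
            f"chains are not superposable (rmsd {result.rmsd:.2f} A > {rmsd_threshold} A)")
    R, t = result.transform.rotation, result.transform.translation
    axis = result.transform.rotation_axis()
    # fixed point: minimize |(I - R) p - t|; the null direction along the axis
    # makes this rank-2, so take the minimum-norm least-squares solution
    point, *_ = np.linalg.lstsq(np.eye(3) - R, t, rcond=None)
    return axis, point


def mate_transform(assembly: Structure, chain_a: str, chain_b: str) -> RigidTransform:
    """Rigid transform superposing chain_a onto chain_b (exact for symmetry mates)."""
    from .superpose import kabsch

    a, b = coords_of(assembly[chain_a]), coords_of(assembly[chain_b])
    return kabsch(a, b).transform
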