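"""Least-squares rigid superposition with sequence-based residue pairing.

``kabsch`` solves the orthogonal Procrustes problem with the determinant
correction that rejects reflections; ``align_chains`` pairs residues of two
homologous chains by global Needleman–Wunsch alignment (BLOSUM62, affine
gaps); ``superpose_chains`` composes the two, fitting on CA atoms by default
with one optional round of outlier trimming so that flexible loops do not
dominate a homolog fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import GeometryError, InputError
from .geometry import RigidTransform
from .structure_io import Chain, Residue, Structure, extract_sequence

# alignment parameters; recorded in AlignmentMap so reports carry provenance
GAP_OPEN = 10.0
GAP_EXTEND = 0.5
SUBSTITUTION_MATRIX = "BLOSUM62"


@dataclass
class AlignmentMap:
    """Residue pairing between two chains from a global sequence alignment."""

    pairs: list[tuple[Residue, Residue]]
    score: float
    identity_fraction: float
    parameters: dict = field(default_factory=lambda: {
        "matrix": SUBSTITUTION_MATRIX, "gap_open": GAP_OPEN, "gap_extend": GAP_EXTEND})

    def __post_init__(self):
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise InputError("identity_fraction outside [0,1]")


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    paired_atom_names: tuple[str, ...] = ("CA",)
    rmsd_before_trim: float | None = None
    n_trimmed: int = 0

    def __post_init__(self):
        if self.rmsd < 0:
            raise InputError("rmsd must be non-negative")


def kabsch(coords_a, coords_b, weights=None) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping A onto B.

    Minimizes the (weighted) RMSD; reflections are rejected by flipping the
    sign of the smallest singular vector when det < 0, so planar and other
    degenerate point sets still yield det(R) = +1.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise GeometryError(f"coordinate sets must both be (N,3); got {A.shape} and {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
    wsum = w.sum()
    ca = (w[:, None] * A).sum(axis=0) / wsum
    cb = (w[:, None] * B).sum(axis=0) / wsum
    A0, B0 = A - ca, B - cb
    H = (w[:, None] * A0).T @ B0
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets leave the rotation about the line undetermined
    if S[1] <= 1e-9 * max(S[0], 1.0):
        raise GeometryError("points are (nearly) collinear; rotation is undetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t, atol=1e-8)
    diff = transform.apply(A) - B
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(transform, rmsd, n)


def _build_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(SUBSTITUTION_MATRIX)
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    aligner.mode = "global"
    return aligner


def align_chains(chain_a: Chain, chain_b: Chain) -> AlignmentMap:
    """Globally align two polymer chains and pair their residues.

    Biopython's dynamic-programming aligner does the heavy lifting; the first
    reported optimal alignment is taken, which is deterministic for fixed
    inputs and parameters.
    """
    seq_a, seq_b = extract_sequence(chain_a), extract_sequence(chain_b)
    if not seq_a or not seq_b:
        raise InputError("cannot align an empty sequence")
    alignment = _build_aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[Residue, Residue]] = []
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            pairs.append((chain_a.residues[i], chain_b.residues[j]))
            if seq_a[i] == seq_b[j]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    return AlignmentMap(pairs, float(alignment.score), identity)


def _as_chain_list(obj) -> list[Chain]:
    if isinstance(obj, Chain):
        return [obj]
    if isinstance(obj, Structure):
        return obj.polymer_chains()
    return list(obj)


def superpose_chains(mobile, target, atom_selection=("CA",),
                     trim: bool = True, trim_factor: float = 2.0) -> SuperpositionResult:
    """Sequence-pair two chains (or chain groups) and fit the selected atoms.

    Chain groups are paired in order (i-th mobile chain with i-th target
    chain).  When ``trim`` is set, one round of outlier rejection removes
    atom pairs with residual > ``trim_factor`` x rmsd and re-fits; the pre-trim
    rmsd is reported alongside.
    """
    mobile_chains, target_chains = _as_chain_list(mobile), _as_chain_list(target)
    if len(mobile_chains) != len(target_chains):
        raise InputError(
            f"chain groups differ in size: {len(mobile_chains)} vs {len(target_chains)}")
    names = tuple(atom_selection)
    xa, xb = [], []
    for cm, ct in zip(mobile_chains, target_chains):
        for ra, rb in align_chains(cm, ct).pairs:
            for name in names:
                aa, ab = ra.atom(name), rb.atom(name)
                if aa is not None and ab is not None:
                    xa.append(aa.pos)
                    xb.append(ab.pos)
    if len(xa) < 3:
        raise GeometryError(f"fewer than 3 paired {names} atoms")
    A, B = np.array(xa), np.array(xb)
    result = kabsch(A, B)
    result.paired_atom_names = names
    if not trim or result.rmsd == 0:
        return result
    residuals = np.linalg.norm(result.transform.apply(A) - B, axis=1)
    keep = residuals <= trim_factor * result.rmsd
    if keep.sum() >= 3 and keep.sum() < len(A):
        trimmed = kabsch(A[keep], B[keep])
        trimmed.paired_atom_names = names
        trimmed.rmsd_before_trim = result.rmsd
        trimmed.n_trimmed = int((~keep).sum())
        return trimmed
    return result
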