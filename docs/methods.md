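# Methods

This note documents the models, numerical choices and limitations behind
`thdtools`, in the order a typical analysis runs.

## Structure model and input conventions

Coordinates are Cartesian Ångström, right-handed; fractional coordinates
appear only inside the symmetry machinery. Author residue numbering is taken
as authoritative and never renumbered: residue labels quoted in papers
frequently mix numbering schemes (full-length precursor vs. construct vs.
deposited), so any label of interest should be located by sequence or
geometry, not by assuming an offset.

Alternate conformations are resolved at parse time to the highest-occupancy
conformer, ties broken by altloc identifier order — all downstream geometry
(areas, hydrogen bonds) then sees one deterministic atom set. Multi-model
(NMR) files contribute model 1 unless another model is requested; which
conformer of an NMR ensemble is "the" receptor model is a genuine free
choice, and the flag records it. Waters and non-polymer entities are parsed
and flagged but excluded from interface and surface computations by default,
since the reference interface areas in this field are protein–protein.

Van der Waals radii default to the Bondi (1964) element-wise set
(C 1.70 Å, N 1.55 Å, O 1.52 Å, S 1.80 Å …) with a 1.80 Å fallback for
unknown elements (warning, not error). The set is user-overridable through a
plain `KEY=VALUE` config file because legacy area programs differ slightly in
their radii; this is one of the two knobs (with the probe radius) that move
absolute buried-area numbers by a few percent.

## Symmetry expansion

The orthogonalization convention is the PDB standard — crystal axis **a**
along x, **b** in the xy-plane — so that CRYST1/`_cell` metadata round-trips.
Operator triplets (`-Y,X-Y,Z`) are parsed to exact rational matrices and
conjugated into Cartesian space, `R = M R_frac M⁻¹`; for trigonal/hexagonal
cells this conjugation is verified to produce orthonormal rotations to 1e-9,
i.e. fractional algebra never breaks rigidity. Operators are read from the
file when explicitly present (`REMARK 290` / `_space_group_symop`), otherwise
taken from the space-group symbol's standard table, with P1/P3 available as a
built-in fallback. Only point-group expansion is implemented — no ±1-cell
packing search — because generating an in-place biological assembly (a
trimer on a crystallographic 3-fold) needs nothing more.

Symmetry mates are named `<chain>_s<k>` for reversibility; PDB export maps
long ids to single characters and writes a sidecar `*.chainmap.tsv`.

The molecular 3-fold is recovered from data, not assumed: the rotation
superposing mate 1 onto mate 2 is computed, its axis extracted from the
antisymmetric part, and the axis point from the minimum-norm solution of
`(I − R)p = t`. Chains failing to superpose within 2 Å are rejected as
non-equivalent.

## Superposition

Kabsch via SVD with the determinant correction `D = diag(1, 1, sign det)`,
so degenerate (planar) point sets still return a proper rotation; collinear
sets are rejected as rank-deficient. Residue pairing for homologs is a
global Needleman–Wunsch alignment (Biopython's dynamic-programming aligner,
BLOSUM62, gap open 10 / extend 0.5); the alignment only needs to pair the
structurally conserved core, so the exact parameters are not critical, and
they are recorded in the result for provenance. Fitting uses CA atoms by
default with one round of outlier trimming (pairs with residual beyond 2×rmsd
removed, one re-fit, pre-trim rmsd reported) — flexible loops that are
disordered or divergent between homologs should not dominate a core fit, and
a single round keeps the procedure transparent. Expected accuracy is set by
the noise floor: for N residues with isotropic per-coordinate noise σ the
fitted rmsd concentrates near √3·σ·√(1 − 3/N), which the tests verify by
simulation.

## Surface areas

SASA is Shrake–Rupley numerical quadrature on probe-expanded spheres
(probe 1.4 Å): a Fibonacci (golden-angle) lattice of 960 points per atom by
default, points discarded when inside any neighboring expanded sphere,
neighbor search via a k-d tree. One refinement: each atom's lattice is
rotated by a deterministic orientation keyed on the atom's coordinates
(CRC-indexed into a fixed table). On periodic structures (helices, sheets)
identical lattice orientations produce correlated cap-boundary errors that
converge slowly; decorrelating them brings the doubling change of totals
well under 0.5% at 960 points while keeping results independent of atom
ordering and bit-reproducible.

Buried surface area uses the difference convention
`BSA = SASA(A) + SASA(B) − SASA(A∪B)`, i.e. **both sides summed** — the
convention under which a Fab–antigen interface of ~880 Å² and a ~800 Å²
protomer–protomer interface are "typical" values. Per-side losses are always
reported so the single-side reading (half the total for a symmetric
interface) stays inspectable; which grouping a published number used
(antibody vs. whole trimer or vs. one protomer) is often unstated, so the
pipeline computes and reports both.

Accuracy is controlled against closed forms: an isolated sphere is exact up
to point-count granularity, and the two-sphere system has an analytic
spherical-cap answer; the generator returns it as a true oracle. An
independent brute-force quadrature with a seeded random point set serves as
the second cross-check.

## Hydrogen bonds, stacking, contacts

Crystal structures at ~2.5 Å carry no hydrogens, so detection operates on
heavy atoms: donor-capable N/O (templated per residue type; proline backbone
N excluded) against acceptor-capable N/O/S, donor···acceptor distance
≤ 3.6 Å, and antecedent angle (antecedent–donor···acceptor) ≥ 90° whenever
the donor's bonded antecedent is present. The 3.6 Å default brackets the
longest distances typically quoted for interface bonds (3.4 Å) with margin;
the documented tuning range is 3.3–3.9 Å and the value is part of the
criteria object, echoed in every report. No hydrogen placement is attempted
and Asn/Gln/His flips are taken as deposited — both would add unverifiable
variance. Water-mediated bonds are out of scope.

Stacking pairs planar side-chain groups — aromatic rings and the arginine
guanidinium plane, treated uniformly (π-π and cation-π) — with centroid
distance ≤ 4.5 Å and inter-plane angle ≤ 30°; T-shaped geometries are off by
default. Contact maps flag residues with any heavy atom within 4.5 Å of the
partner group.

## Template-transfer docking

TNF-family receptors bind the groove between two protomers, so the transfer
frame is the protomer *pair*: the two template ligand chains nearest the
template CRD (within 8 Å) are superposed onto each of the three equivalent
pairs of the query trimer, in both chain orders, and the best fit wins.
Pairwise rather than whole-trimer superposition is robust to small
differences in trimer assembly between crystal forms; whether a published
model used protomers or trimers for the superposition is usually unstated,
and group selection supports both. Ties (exactly symmetric queries) are
broken by a strict-improvement threshold of 1e-9 Å so the choice is stable
under global rotations — transfer is then exactly rotation-equivariant.

The template CRD is carried into the query frame and the query receptor
model superposed onto it. The consensus is the placement from the template
with the lowest THD-superposition rmsd — averaging rotations across spread
poses is ill-defined, and the per-template placements plus their centroid
spread (max pairwise distance) are all reported so the consensus rule is
auditable. The full trimeric model applies the query's own 3-fold operator
to the consensus receptor; one receptor is refined and the other two
regenerated by symmetry.

Clash relief is a deliberately minimal, fully deterministic stand-in for
crystallographic rigid-body/positional refinement (which depends on force
fields and protocols that cannot be reproduced faithfully): a half-harmonic
repulsion switched on below 0.89×(rᵢ+rⱼ), minimized by steepest descent on
the six rigid-body degrees of freedom with a backtracking line search
(gradient tolerance 1e-4, max 2000 steps, no randomness). The energy trace
is monotone non-increasing by construction and returned with the result.
Severe clashes are counted at the conventional 0.6×(rᵢ+rⱼ) criterion. No
side-chain repacking, electrostatic scoring or conformational change of the
receptor is modeled — an NMR-derived CRD may rearrange on binding, and a
rigid-body treatment cannot capture that; interface areas from such models
carry correspondingly wide uncertainty.

Mutagenesis consistency asks the two questions point mutations can answer:
does a functionally important receptor residue touch the ligand (any heavy
atom within 4.5 Å, plus per-residue buried area), and does a dispensable
residue avoid direct hydrogen bonds.

## Surface charge patches

The electrostatic questions here are topological — *where* the basic
(positive) faces of the trimer are — so the potential is a screened Coulomb
sum over formal charges, not a Poisson–Boltzmann solution: φ(p) =
(l_B/ε-scaled) Σ qᵢ e^(−d/λ)/d in kT/e at 298 K, with λ = 8 Å and ε_r = 80.
Charges are formal and symmetric over terminal heavy atoms (Asp/Glu −0.5 on
each carboxylate oxygen, Lys +1 on NZ, Arg +0.5 on each NH, termini ±1 on
N/OXT); histidine is neutral, appropriate at the pH ≈ 7.4 of the binding
assays this supports. The familiar ±4 kT display range of published surface
figures is a rendering convention, not a target quantity.

Patches are single-linkage clusters (link radius 5 Å) of same-sign surface
points at |φ| ≥ 2 kT/e covering ≥ 50 Å², using the retained SASA quadrature
points with their area weights. Location classes project the patch centroid
onto the molecular 3-fold: the top quarter of the axial extent on the
chain-termini side is "top" (for a type-II membrane cytokine the termini
face the membrane), the bottom quarter "bottom", the rest "side". The
thresholds are configurable; published patch descriptions are pictorial, so
any acceptance on patches is existence + location + overlap with an
independently determined epitope, never a potential value.

## Synthetic data

Every generator is a pure function of its parameters; randomness enters only
through an explicit seed. The fixtures emulate the geometric content of the
real analyses — hard spheres with exact areas, ideal α-helices (φ −57°,
ψ −47°, Engh–Huber-type bond geometry, giving the canonical 1.5 Å rise and
3.8 Å CA–CA step), exact C3 trimers with their generating operators and a
matching hexagonal cell, donor–acceptor pairs at prescribed distance and
angle, two-layer charged slabs (20 Å layer separation ≈ 2.5 screening
lengths, so only the charged face exceeds the patch threshold), and rigid
transforms uniform on SO(3). What they do **not** emulate: real side-chain
diversity and rotamers, disordered loops, crystal-contact artifacts,
solvent, or the sequence divergence of genuine homologs. Passing the
synthetic suite therefore demonstrates correctness of the geometry and the
algorithms, not biological accuracy on any particular deposited structure;
the deposited-entry validation tests exist for that and require the user to
fetch the public coordinate files once.

## Problem sizes and determinism

Default problem sizes are desk-scale: 960 quadrature points per atom
(4000 for two-atom oracle comparisons, where it is free; 240 for surface
fields, where only the topology matters), 100 random transforms for
superposition calibration, 20 separations for the cap-formula sweep. All
default runs are bit-reproducible: fixed seeds, deterministic tie-breaks
(alignment traceback prefers match over gap; docking prefers the first
best-fit pair; altlocs break ties by identifier), and no parallelism.

## Known limitations

* Buried-area absolutes inherit the radii/probe convention; comparisons
  against numbers produced by other programs are meaningful only within a
  few percent.
* Hydrogen bonds are heavy-atom geometric candidates; without hydrogens,
  donor/acceptor role assignment for His/Ser/Thr/Tyr is template-based and
  chemically ambiguous cases are not adjudicated.
* The docking energy model relieves sterics only; it cannot rank
  alternative binding modes and does not move atoms internally.
* The screened-Coulomb field is not a substitute for Poisson–Boltzmann where
  quantitative potentials matter.
* No packing analysis: assemblies requiring translational symmetry copies
  are out of scope.
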