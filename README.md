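# thdtools

Structural analysis of TNF-homology-domain (THD) cytokine complexes: the
recurring desk-work around a trimeric TNF-family cytokine such as TWEAK, its
cysteine-rich-domain (CRD) receptor Fn14, and neutralizing antibodies.

TNF-family cytokines are homotrimers whose biological assembly is often not
deposited explicitly — in a crystal form like P3 the trimer is generated by a
crystallographic 3-fold. Their receptors bind the groove between two
protomers, so a receptor pose determined for one family member (e.g.
APRIL–BCMA or TALL–BAFFR) can be transferred to another by superposition.
`thdtools` packages that workflow for structural biologists and antibody
engineers:

* **structure_io** — PDB/mmCIF in and out (via gemmi) with a plain
  chains → residues → atoms model, crystal metadata, altloc resolution,
  Bondi vdW radii;
* **symmetry** — fractional/Cartesian frames, operator-triplet parsing,
  point-group expansion of the biological assembly, molecular 3-fold
  detection;
* **superpose** — Kabsch least-squares superposition (reflection-safe) with
  Needleman–Wunsch residue pairing (BLOSUM62, affine gaps) and one round of
  outlier trimming;
* **interface** — Shrake–Rupley solvent-accessible surface area (SASA),
  buried surface area `BSA = SASA(A) + SASA(B) − SASA(A∪B)`, heavy-atom
  hydrogen-bond detection, π/cation-π stacking, epitope/paratope contact
  maps;
* **template_dock** — transfer of a receptor CRD from homologous THD–CRD
  complexes onto a query trimer, consensus placement, deterministic
  rigid-body clash relief (half-harmonic repulsion, steepest descent), clash
  counting and mutagenesis-consistency checks;
* **electrostatics** — screened-Coulomb potential (kT/e at 298 K) on the
  accessible surface and single-linkage clustering of charged patches,
  classified top/side/bottom relative to the molecular 3-fold;
* **binding_assays** — SPR bookkeeping: `t½ = ln 2 / (60·kd)` and
  crossblocking molar ratios `MR% = 100·secondary/primary`;
* **synthetic_data** — deterministic fixtures with closed-form oracles
  (spheres, two-sphere cap areas, ideal α-helices, exact C3 trimers,
  donor–acceptor pairs, charged slabs, seeded random rigid transforms).

## Worked example

The end-to-end driver also runs entirely on synthetic inputs:

```bash
$ thdtools reproduce --fixtures-only --out results/bundle
{
  "trimer_axis_z": 1.0,
  "protomer_bsa": 146.8,
  "self_dock_crd_rmsd": 0.0,
  "dock_spread": 0.0,
  "inter_receptor_clashes_synthetic": 0,
  "basic_patches": 1
}
```

Reading the output: the detected molecular 3-fold of the synthetic C3 trimer
is exactly the z axis (`trimer_axis_z` = |axis·ẑ| = 1.0); adjacent protomers
bury 146.8 Å² of surface; self-docking a toy template recovers the deposited
receptor pose to numerical precision (`self_dock_crd_rmsd` = 0 Å, placement
spread 0 Å); the three symmetry-generated receptor copies do not clash; and
patch detection finds exactly one basic patch, on the charged face of the
test slab.

Single formulas are exposed the same way:

```bash
$ thdtools assay halflife --kd 1.0503e-4
110 min
```

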