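# sitematch

Local structural comparison of protein functional sites with user-defined
pseudoatom representations.

Enzyme active sites and ligand-binding pockets are small residue
constellations whose 3D arrangement is often conserved across proteins that
share neither fold nor sequence.  sitematch finds such similarities: it
projects structures into point representations you define with a small
residue-definition language, then enumerates, by branch-and-bound, **all
largest sets of residues (or atom groups) in two structures that superimpose
rigidly within an RMSD threshold**, independent of sequence order.  A
screening harness ranks a probe motif against many chains and validates the
ranking by ligand proximity and ROC AUC.  It is aimed at structural
bioinformaticians studying binding sites, catalytic motifs, and convergent
evolution.

## The model

* **Representation.**  A *pseudoatom* is a point standing for a residue or
  part of it: an atom (`def SER CA CB`), a centroid
  (`def HIS avg(ND1,NE2):bar`), or every atom whose name contains a
  substring (`def * \N;\O`, one point per matching atom, same-type pairing
  only).  *Equivalence rules* state which residues may pair and in which
  fragment order (`ALA GLY VAL`, `XXX.(A,B) YYY.(C,D)`); `*` is a fallback
  for residues without a specific definition.  Residues match as whole units
  (grouped mode) or pseudoatom-by-pseudoatom (independent mode).
  Three presets ship: `coarse_ca` (Cα only, free substitution),
  `ca_centroid_blosum` (Cα + side-chain centroid, substitutions with
  BLOSUM62 ≥ −1), and `chemgroups` (side-chain chemical groups, independent
  atoms, no main-chain matches).

* **Superposition.**  Optimal proper-rotation RMSD by the quaternion
  method: the largest eigenvalue λ of the 4×4 key matrix built from the
  centred cross-covariance gives RMSD = √((G_a + G_b − 2λ)/n); reflections
  are excluded.

* **Search.**  Seeds are all rule-allowed single-unit pairings; partial
  matches grow depth-wise and survive only while their optimal RMSD stays
  at or below the threshold (default 0.7 Å); all maximum-size matches are
  returned, ranked by RMSD.  The hot loop is compiled with numba and
  pre-screens extensions with distance-deviation bounds implied by the RMSD
  criterion itself.

* **Screening.**  Hits rank by size (desc) then RMSD (asc); small-match
  background is discarded; hits validate when a matched residue lies within
  4.5 Å of a qualifying ligand atom; ranking quality is the Mann–Whitney
  ROC AUC with midrank ties.

See `docs/methods.md` for assumptions, numerical choices, and limitations.

## Worked example

Plant an 8-residue motif in two synthetic 38-residue structures (0.1 Å
noise on the second copy, random rigid motion, shuffled residue order), and
find it back:

```python
import logging; logging.disable(logging.WARNING)
from sitematch.structure import model_to_pdb
from sitematch.synthetic import MotifSpec, plant_motif

pm = plant_motif(MotifSpec(k=8, noise_sigma=0.1, decoys=30, seed=42))
open("probe.pdb", "w").write(model_to_pdb(pm.model_a))
open("target.pdb", "w").write(model_to_pdb(pm.model_b))
open("probe.txt", "w").write("probe.pdb A\n")
open("target.txt", "w").write("target.pdb A\n")
print(sorted((a[1], b[1]) for a, b in pm.correspondence))
# [(4, 23), (6, 7), (10, 13), (20, 17), (25, 37), (26, 35), (27, 14), (37, 22)]
```

```bash
$ sitematch compare --probe probe.txt --targets target.txt --rep coarse_ca
match  size_units  size_pseudoatoms  rmsd    paired_residues
1      8           8                 0.1876  A:HIS:4=A:HIS:23;A:PHE:6=A:PHE:7;A:ARG:10=A:ARG:13;A:HIS:20=A:HIS:17;A:PHE:25=A:PHE:37;A:TRP:26=A:TRP:35;A:SER:27=A:SER:14;A:ARG:37=A:ARG:22
```

The single maximum match has 8 residue pairs — exactly the planted
correspondence — superimposing at 0.19 Å, well inside the 0.7 Å threshold;
no chance arrangement among the 30 decoys per side reaches that size.
`sitematch screen` scans one probe against a list of chains and writes the
ranked TSV hit table (optionally with `--validate-element P` proximity
validation); `--superposed-pdb` writes the target's coordinates superposed
onto the probe for visual inspection.

Real binding-site comparisons use `sitematch.sites.compare_sites`, which
selects ligand-contact residues (any atom within 4.5 Å of a ligand) in two
downloaded PDB entries and searches under any representation.

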