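# Methods

## The problem

Functional sites — enzyme active sites, ligand- and metal-binding pockets —
are small constellations of residues whose three-dimensional arrangement is
conserved even when the proteins carrying them share no fold or detectable
sequence similarity.  Finding such local similarities requires (i) a
*representation*: which points stand in for each residue, and which residues
are allowed to substitute for one another; and (ii) a *search*: the largest
subset of those points in two structures that superimposes rigidly within an
RMSD tolerance, irrespective of sequence order.  sitematch implements both,
with the representation under user control through a small residue-definition
language.

## Pseudoatom representations

A *pseudoatom* is a point representing a residue or part of one: a named PDB
atom (`CA`), the geometric centroid of a set of atoms
(`avg(OD1,OD2):CRX`), or every atom whose name contains a substring
(`\N`).  *Equivalence rules* declare which residues may pair and, through
fragment selectors (`TYR.(OH)`), which of their pseudoatoms, in which order.
Pairing is positional within a rule; pattern-derived pseudoatoms only pair
with products of the same pattern (atoms of the same type).  In *grouped*
mode all of a residue's pseudoatoms form one match unit; in
*independent-atom* mode each pseudoatom is its own unit, so one residue can
match several others through different chemical groups.  Pattern recipes are
restricted to independent mode: an ordered residue-level pairing is not
well defined when a recipe expands to a variable number of atoms.

Three presets ship with the package (see `sitematch/presets/`): a coarse
CA-only description with free substitution; CA plus side-chain centroid with
substitutions limited to BLOSUM62 score ≥ −1 (one rule per allowed pair,
generated from Biopython's BLOSUM62 table; glycine carries a degenerate
side-chain centroid at its CA so all rules pair two points); and a
chemical-group description (carboxylate, amide, guanidinium, hydroxyl,
imidazole, aromatic ring, sulfur, aliphatic centroids) matched as
independent entities with no cross-residue main-chain pairing — glycine,
having no side chain, is represented by its CA and restricted to matching
other glycines so the preset still covers all twenty amino acids.

Missing atoms never abort a projection: a single-atom recipe yields nothing,
a centroid averages over the atoms present (logged), and a residue
producing no pseudoatoms at all is dropped with a warning.

## Optimal superposition

The rigid-body optimum is computed by the quaternion method: the largest
eigenvalue λ of the 4×4 key matrix built from the 3×3 cross-covariance of
the centred point sets gives the minimal residual E = G_a + G_b − 2λ and
RMSD = √(E/n); the corresponding eigenvector quaternion gives the rotation.
Reflections are excluded by construction, which matters for chiral atom
arrangements.  RMSD is unweighted.  Degenerate inputs (single points,
collinear or coincident sets, symmetric sets with a tied top eigenvalue)
return a finite RMSD and a valid proper rotation; only the RMSD is then
uniquely determined.  Inside the search the eigenvalue is obtained from the
quartic characteristic polynomial by Newton iteration (tolerance 1e-11
relative) with a bisection fallback; the user-facing
`optimal_superposition` uses a symmetric eigendecomposition, and the test
suite holds both against an independent Kabsch-SVD implementation at
1e-8 Å on tens of thousands of random pairs.

A note on the two-point degenerate case: the optimum aligns both segments
along one axis with a common centroid, so each endpoint carries half the
length mismatch and RMSD = |d_a − d_b| / 2.

## Search

Matching starts from every single-unit pairing the rules allow and grows
partial matches one unit pair at a time, keeping a partial match only while
its pseudoatoms superimpose at or below the RMSD threshold (default 0.7 Å).
A match is a *set* of unit pairs; the package's admission semantics are:

> a pair set is admissible iff some insertion order keeps every
> intermediate partial match at or below the threshold,

and every admissible set is evaluated exactly once (duplicates reached
through different insertion orders are collapsed by their unordered pair
set).  All matches of maximum size are returned, ranked by RMSD.  These
semantics make the result independent of input residue order and exactly
symmetric under swapping the two structures, properties the test suite
enforces.  Because RMSD can decrease when points are added, pruning on the
partial match's own RMSD is a heuristic with respect to the global optimum
over all subsets; the brute-force oracle in the tests applies the identical
rule, so the equivalence checked there is exact by construction.

The implementation is a level-synchronous breadth-first closure compiled
with numba.  Extensions are pre-screened with bounds that follow from the
RMSD criterion itself — any n-point superposition with rmsd ≤ t satisfies
|d_a − d_b| ≤ t√(2n) for every point pair and Σ(d_a − d_b)² ≤ 2n(n−1)t²
over all pairs — so the pre-screen never rejects a set the criterion would
admit.  Candidate lists are materialised for width-2 states and deeper
states scan their width-2 ancestor's list with inline checks.  A node
budget (default 10⁸ evaluated partial matches) and a per-level cap guard
against degenerate inputs such as globally similar structures, which this
class of method is not meant for; exceeding either raises a clear error.
Independent-atom injectivity is at pseudoatom level: two pseudoatoms of one
residue may match different residues, but never the same pseudoatom.
Matches smaller than `min_report_size` (default 3 units) are suppressed.

## Screening and significance

A probe motif can be scanned against many target chains.  Hits are ranked
by decreasing size and then increasing RMSD — RMSD alone separates little
because the search extends matches until they are just under the threshold
— and the small-match background can be discarded with a size cutoff
(parameter, not hard-coded, because the sensible cutoff depends on the
probe's size).  Validation is by an orthogonal geometric criterion: a hit
counts as significant when any matched *target* residue has an atom
strictly within a distance cutoff (default 4.5 Å) of a qualifying ligand
atom (e.g. phosphorus for a phosphate-binding probe; water never counts as
a ligand).  The agreement between ranking and validation is summarised by
the ROC AUC in the Mann–Whitney formulation, with ties within a rank key
sharing the midrank; scikit-learn's implementation serves only as a
cross-check in the tests.

## Synthetic data

The generator produces geometrically plausible toy structures: residues
carry real backbone and side-chain atom names, CA positions are packed with
a 3.5 Å minimum separation in a cubic box, and side-chain atoms sit at
idealized offsets from the CA.  It models no stereochemistry — bond angles,
Ramachandran validity and rotamers are out of scope — so passing tests
demonstrate correctness of the representation/search machinery on
realistic point geometry, not performance on crystallographic artefacts
(alternate conformations and missing atoms are exercised by dedicated
hand-written fixtures instead).

`make_structure` defaults to folded-core packing density (120 Å³ per
residue).  `plant_motif` embeds one k-residue motif in two decoy clouds,
the second copy perturbed by a random proper rigid motion plus isotropic
Gaussian noise, with residue order shuffled; its decoy cloud uses 400 Å³
per residue, the patch-like spread of residues selected around a binding
site.  The density choice is substantive: at core packing density an
8-point constellation matching within 0.7 Å is no longer rare among ~38
random residues, so chance matches outgrow a planted 8-residue motif and
recovery becomes impossible for any search algorithm — the benchmark is
well-posed only in the site-like regime, which is also the regime the tool
is intended for (comparing selected sites, not whole structures).

The benchmark conditions used throughout tests and the acceptance script
are: motif size k = 8, per-coordinate noise σ = 0.1 Å, 30 decoys per side,
threshold 0.7 Å, 100 random seeds.

## Numerical and design choices

* PDB input goes through gemmi with fixed policies: first model of
  multi-model files; one conformer per atom (highest occupancy, ties broken
  toward the blank/'A' altloc); hydrogens kept (the representation decides
  usage); HETATM residues are ligands unless peptide-like (N, CA and C
  present — modified amino acids stay in the polymer and may carry their
  own `def` lines); author residue numbering is never changed.  Coordinate
  lines with unparseable numeric fields are dropped with a line-numbered
  warning before parsing.
* Atom names are taken verbatim from the PDB records; no alias
  normalisation (OXT, primed ribose names).
* Equivalence rules are the only pairing mechanism: a residue matches
  nothing — not even itself — unless a rule names it.  A rule listing k
  residues allows every ordered member pair including self-pairs.
* When several rules apply to one residue pair, each correspondence is
  tried as an alternative branch.
* One residue may appear in only one `def` line.
* Ties among maximum matches are all returned, ordered by RMSD then
  lexicographic pair order, for deterministic output.
* Screening targets are independent work items; results are identical
  under any processing order (enforced by test).

## Limitations

* The admission rule is insertion-order-based, matching the recursive
  search it implements, not a global optimisation over all subsets; a set
  whose every proper chain of subsets violates the threshold is never
  reported even if its own RMSD is below it (such sets are rare and
  physically marginal — they sit just under the threshold).
* No statistical significance model is attached to match sizes or RMSDs;
  ranking plus orthogonal validation is the supported methodology.
* Comparing globally similar structures is out of scope; the node budget
  exists to fail fast on such inputs.
* The synthetic generator's geometry is plausible but not stereochemical;
  conclusions about real crystal structures should rest on the real-data
  replication path (`sitematch.sites.compare_sites` with downloaded PDB
  entries).
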