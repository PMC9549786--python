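# Methods

## Overview

`pocketsphere` predicts and compares ligand-binding sites by local
structural similarity to templates cut from known protein–ligand
complexes. A template ("sphere") is the ligand plus all protein residues
with at least one heavy atom within 12.0 Å of any ligand heavy atom;
residues within 4.5 Å form its interface set. Detection aligns the
template's residues onto a query structure, transplants the template
ligand rigidly by the alignment transform (the ligand conformation is
never altered — this is not docking), and filters the result on four
statistics (Nc, GDC, N4, cl). Accepted matches are merged into consensus
pockets; predictions are evaluated against unified-binding-site (UBS)
references with MCC and F.

## Structure model and ligand rules

Structures are parsed with gemmi from PDB or mmCIF text. Residue identity
is the author triple (chain, number, insertion code). Alternate locations
collapse to the highest-occupancy conformer, ties broken by file order.
Hydrogens (and deuterium) are parsed but excluded from every distance
computation and heavy-atom count. Modified amino acids inside a polymer
chain remain polymer residues. Ligand instances are: each non-water hetero
group (single-heavy-atom groups classified as metal/ion, the rest as
compounds) and each polymer chain of ≤ 25 residues when at least one
longer chain is present (a lone short chain is the query itself). Waters
(HOH/WAT/DOD) are never ligands. All distance thresholds are inclusive
(≤), except the clash cutoff which is strict (< 1.0 Å) as printed.

## The aligner

Alignment is sequence-independent and uses one representative point per
residue (Cα by default; Cβ mode falls back to Cα where Cβ is absent).

* **Seeding.** Rigid Kabsch superpositions are generated from every
  gapless 7-residue fragment of the template paired with every
  same-length gapless query window (stride 2 on the query to bound cost).
  Seeds whose fragment RMSD exceeds 3 Å are discarded.
* **Refinement.** Each seed alternates (a) assignment of chain-consistent,
  sequence-order-monotone mutual nearest neighbours within 6.0 Å under the
  current transform (monotonicity enforced by longest-increasing-
  subsequence per chain pair) with (b) re-superposition on the assigned
  pairs, to convergence or 20 rounds.
* **Ranking.** Converged candidates (de-duplicated by pair set) are ranked
  by LGA_S, ties by larger conserved-pair count, then lower RMSD. The
  search exits early on a perfect self-match.

**Scores.** LGA_S = 100·(0.75·GDT + 0.25·LCS). GDT averages, over
thresholds {1, 2, 4, 8} Å, the maximal fraction of template residues
superposable within the threshold (per-threshold iterative refinement of
the superposed subset). LCS averages, over RMSD cutoffs {1, 2, 5} Å, the
longest contiguous aligned run superposable under the cutoff. Both
fractions are normalised by the **full template size** (ns), not by the
number of aligned pairs: during candidate ranking a per-pair normalisation
would let a small, tight partial alignment outscore a complete one, which
inverts the intended ranking; normalising by ns follows the GDT_TS
convention of this scoring family. Conserved pairs (Nc) are those within
4.0 Å under the final transform; the reported transform and RMSD are
re-fit on the conserved set. SeqID is the percentage of identical residue
types among conserved pairs.

**GDC.** For each conserved pair, heavy atoms are matched by identical
atom name; the atom universe of a pair is the union of heavy-atom names of
both residues, so an atom present in only one residue counts as outside
every threshold. With thresholds dᵢ = 0.5·i Å and weights wᵢ = 11 − i
(i = 1..10), GDC = 100·Σwᵢfᵢ/Σwᵢ where fᵢ is the matched fraction within
dᵢ. GDC therefore credits side-chain placement, not just backbone.

## Detection, filtering, clustering

The transplanted ligand defines contacts (residues with a heavy atom
≤ 4.5 Å from a ligand heavy atom) and clashes (< 1.0 Å), both counted per
residue — several clashing atoms within one residue are a single clash. A
match is accepted when Nc ≥ 10 and GDC ≥ 55.0 and N4 ≥ 1 and cl ≤ 2;
high confidence additionally requires Nc ≥ 25, GDC ≥ 65 and cl ≤ 1.
Matches are sorted by (GDC desc, Nc desc, RMSD asc).

Accepted matches merge into consensus pockets when the contact-set
**overlap coefficient** |A∩B|/min(|A|,|B|) exceeds 0.80 (the denominator
is not fixed by the merge rule's phrasing; Jaccard is available as a
config option) **or** the all-heavy-atom ligand centroids lie within
2.0 Å. The two criteria are combined as a single merge graph whose
connected components (single-linkage transitive closure) are the
clusters — the rules are stated as merge conditions without an order, and
joint closure is the order-independent reading. Core centroids (mean over
buried ligand atoms: ≥ 10 protein heavy atoms within 5.0 Å) are reported
for diagnosis of exposed ligand parts but not used for merging, since the
2.0 Å rule is defined on whole-ligand centroids.

## Evaluation

UBS references are unions of 4.5 Å contact residues over family members in
a common numbering; a global-sequence-alignment mapper
(`map_to_reference`, BLOSUM62, affine gaps) is provided and unmapped
residues are surfaced, never silently dropped. The confusion universe is
all residues of the scored structure. MCC follows the standard formula
with the 0-with-flag convention when any denominator factor vanishes;
F = 2TP/(2TP+FP+FN). Pocket-level comparison aligns one pocket's sphere
onto the other's 16 Å region and reports GDC, LGA_S and the distance
between the transplanted and native ligand centroids. "Exclusive"
clustering is single-linkage over pairs with GDC ≥ a threshold
(default 70 — a prominent configuration item, as no canonical value is
fixed for it). Affinity concordance filters pairs at GDC ≥ 95 and
centroid distance ≤ 0.5 Å (relaxed: 90 / 1.0 Å), then reports R² (squared
Pearson) and Spearman's ρ over the two affinity vectors; affinities are
−log10 molar values and Kd/Ki populations are never mixed in one call.

## Synthetic fixtures

The generator emulates the inputs the pipeline consumes in the wild:

* **Holo complexes**: 3–5 ideal α-helices (Cα radius 2.28 Å, rise 1.5 Å,
  twist 100°/residue → 3.80 Å Cα–Cα spacing) arranged antiparallel on a
  7 Å bundle radius, backbone N/CA/C/O and CB placed in the local chain
  frame, random seeded sequence. The inter-helix channel is the binding
  site: a rigid pseudo-ligand (carbon atoms, component `LIG`, ≥ 1.3 Å
  spacing, ≥ 2.6 Å from protein) is sampled inside it, and the exact 4.5 Å
  contact truth is recorded. Defaults (80 residues, 12 ligand atoms) give
  a sphere of ~70 residues and ~13–15 contact residues — a mid-sized,
  fully buried site.
* **Apo/homolog variants**: i.i.d. Gaussian coordinate noise on every atom
  plus seeded residue-type substitutions (CB retained as the side-chain
  representative), ligand removed unless retained. σ = 0.3 Å is the
  default apo condition — on the order of coordinate uncertainty between
  independently solved conformers.
* **Decoys**: self-avoiding random walks (3.8 Å Cα steps, non-adjacent
  Cα ≥ 4.0 Å) with full backbone+CB, no concave site by construction.

What the fixtures do **not** emulate: real side chains beyond CB (GDC on
fixtures exercises backbone+CB matching only), true secondary-structure
diversity, crystallographic artefacts, and cofactor chemistry. Passing
tests therefore demonstrate the geometric and statistical machinery, not
performance on experimental structures. Two fixtures with different seeds
share the same ideal backbone (sequence and ligand placement differ), so
cross-seed templates behave like perfect structural homologues; tests that
need a structurally distinct competitor use noisy or different-topology
variants.

Observed behaviour on decoys: the aligner typically finds 10–20 conserved
pairs between a ~70-residue sphere and an 80-residue walk (two connected
chains with identical spacing under a generous 4 Å conserved cutoff), and
rejection comes from the GDC and contact filters rather than the Nc floor.

## Numerical choices and degenerate inputs

Kabsch superposition rejects < 3 points and near-collinear sets (second
singular value < 1e-12 of scale); proper rotations only. Floating-point
comparisons use 1e-6 absolute tolerance. Empty alignments score 0 with a
flag rather than raising. MCC with a zero denominator is 0, flagged.
Affinity statistics with < 3 surviving pairs are NaN, flagged. Degenerate
spheres (isolated ligands) raise; in batch library building they are
skipped with a warning. Duplicate sphere ids get a numeric suffix.

## Problem sizes

Tests and the acceptance script run on 80-residue fixtures, ~70-residue
spheres, 10 fixture seeds, 20 decoys — sizes at which an alignment takes
well under a few seconds and the whole acceptance run a few minutes, while
every stage (shell cutting, seeding, refinement, all-atom scoring,
transplantation, clustering, evaluation) is exercised end to end.

## Known limitations

* The fragment-seeded search is heuristic: symmetry of A→B vs B→A holds
  only approximately (asserted to 1 LGA_S unit on fixtures).
* Chemical-fingerprint (Tanimoto/Tversky) template preselection is exposed
  as a no-op hook only.
* No assembly generation from symmetry operators; sequences come from
  observed residues, not SEQRES.
* No pose refinement, docking or energy evaluation — transplanted poses
  with cl > 0 are reported as-is.
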