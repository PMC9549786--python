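# pocketsphere

Template-based detection, scoring and clustering of ligand-binding sites in
protein structures.

## What it does and for whom

When a new protein structure (experimental or modelled, ligand-bound or
apo) lands on the desk of a structural biologist or a computational drug
hunter, the first question is often: *where does it bind ligands?*
`pocketsphere` answers it with a strictly structure-based, template
approach: every known protein–ligand complex contributes a reusable
**sphere template** — the ligand plus every protein residue with a heavy
atom within 12 Å of it. A query structure is searched by locally aligning
each template's residues onto it; where the backbone and side-chain
environment of a template is reproduced, the template's ligand is
transplanted rigidly into the query by the alignment transform, and the
resulting pose is characterised by contact and clash counts. Because
templates come only from experimentally observed complexes, geometric
artefacts (inter-chain holes, missing fragments) are never reported as
pockets, and sites can be found even when sequence identity to the
template source is very low.

## The scores

Alignment uses residue representative points (Cα, or Cβ with Cα fallback
for glycine) and a local–global search: rigid superpositions are seeded
from all 7-residue gapless fragment pairs and refined by alternating
order-monotone mutual-nearest-neighbour assignment with re-superposition.
Candidates are ranked by

    LGA_S = 100 · (w · GDT + (1 − w) · LCS),   w = 0.75

where GDT is the mean over thresholds {1, 2, 4, 8} Å of the largest
fraction of template residues superposable within the threshold, and LCS
is the mean over RMSD cutoffs {1, 2, 5} Å of the longest contiguous
aligned segment fraction. Side-chain agreement is scored all-atom by

    GDC = 100 · Σᵢ wᵢ fᵢ / Σᵢ wᵢ,   dᵢ = 0.5·i Å, wᵢ = 11 − i, i = 1..10

with fᵢ the fraction of name-matched heavy atoms within dᵢ.

A match is an accepted binding-site prediction when (all inclusive)

    Nc ≥ 10,  GDC ≥ 55.0,  N4 ≥ 1,  cl ≤ 2

where Nc counts conserved residue pairs (≤ 4 Å under the final transform),
N4 the query residues within 4.5 Å of the transplanted ligand, and cl the
residues with an atom closer than 1.0 Å to it (clashes, counted per
residue). Higher confidence is flagged at Nc ≥ 25, GDC ≥ 65, cl ≤ 1.
Accepted matches are merged into **consensus pockets** when >80% of their
contact residues coincide or their ligand centroids lie within 2.0 Å
(transitively); each cluster reports Nm members, Nlig distinct ligands and
the Nres union of contact residues. Predictions are evaluated against
unified binding sites (UBS; the union of residues contacted by any ligand
across a protein family) with

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F   = 2·TP / (2·TP + FP + FN)

## Worked example

```python
from pocketsphere import (build_sphere, evaluate_match, make_toy_complex,
                          perturb, structural_align)
from pocketsphere.synthetic import FixtureSpec

holo, truth = make_toy_complex(FixtureSpec(seed=1))
sphere = build_sphere(holo, holo.ligands[0])         # 12 A template
apo = perturb(holo, noise_sigma=0.3, mutate_frac=0.0, seed=11)  # ligand-free

aln = structural_align(sphere, apo)
match = evaluate_match(sphere, apo, aln)
```

prints (via `python examples/01_detect_binding_site.py`):

```
template LIG.12.toy1: Ns=74
Nc=74  RMSD=0.489 A  SeqID=100.0%
LGA=99.49  GDC=91.53
N4=15 contact residues, cl=0 clashes
accepted=True  high_confidence=True
true contact residues: 15, recovered: 15
```

All 74 sphere residues stay conserved under 0.3 Å coordinate noise, the
all-atom GDC of 91.5 comfortably clears the 55 acceptance floor, and the
transplanted ligand recovers all 15 true contact residues of the planted
site with no clashes. The other scripts under `examples/` walk through
consensus-pocket clustering, UBS-based evaluation (MCC/F) and
all-against-all pocket similarity with affinity concordance.

The same stages are available from the shell:

```bash
pocketsphere fixtures --out fix/
pocketsphere build-library --in complexes/ --out lib/
pocketsphere detect --query fix/apo.pdb --library lib/ --out matches.tsv
pocketsphere cluster --matches matches.tsv --out pockets.tsv
```

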