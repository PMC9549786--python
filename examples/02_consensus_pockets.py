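"""Merge matches from several templates into one consensus pocket.

Detects the planted site of one query with sphere templates taken from
four noisy homolog complexes, clusters the accepted matches (merge when
>80% of contact residues agree or ligand centroids are within 2 Å) and
prints the consensus summary (Nm members, Nlig ligands, Nres residues).
"""

from pocketsphere import (build_sphere, cluster_matches, evaluate_match,
                          make_toy_complex, perturb, structural_align,
                          summarize_clusters)
from pocketsphere.synthetic import FixtureSpec

query, _ = make_toy_complex(FixtureSpec(seed=2))

matches = []
for j in range(4):
    homolog = perturb(query, 0.3, 0.1, seed=40 + j, retain_ligands=True)
    homolog.struct_id = f"homolog{j}"
    sphere = build_sphere(homolog, homolog.ligands[0])
    aln = structural_align(sphere, query)
    match = evaluate_match(sphere, query, aln)
    if match.accepted:
        matches.append(match)

clusters = cluster_matches(matches)
print(f"{len(matches)} accepted matches -> {len(clusters)} consensus pocket(s)")
for c in clusters:
    print(f"cluster {c.cluster_id}: Nm={c.nm} Nlig={c.nlig} Nres={c.nres}")
print()
print(summarize_clusters(clusters)[["cluster_id", "LIGAND", "Nc", "GDC",
                                    "N4", "Nm", "Nres"]].to_string(index=False))
# All four homolog templates hit the same site, so they merge into a single
# consensus pocket whose Nres is the union of their contact residues.
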