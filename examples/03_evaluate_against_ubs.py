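"""Score predicted binding residues against a unified binding site (UBS).

The UBS is the union of residues contacted by any ligand across a protein
family. Prediction quality is summarised by the Matthews correlation
coefficient and the F score over the residue-level confusion table.
"""

from pocketsphere import (build_sphere, build_ubs, evaluate_match,
                          ligand_contacts, make_toy_complex, perturb,
                          score_prediction, structural_align)
from pocketsphere.synthetic import FixtureSpec

holo, truth = make_toy_complex(FixtureSpec(seed=3))

# family = the holo plus two perturbed holo conformations
members = [(holo, truth["contact_keys"])]
for seed in (31, 32):
    m = perturb(holo, 0.3, 0.0, seed=seed, retain_ligands=True)
    members.append((m, ligand_contacts(m, m.ligands[0])))
ubs = build_ubs(members, family_id="toy-family")
print(f"UBS over {len(members)} members: {len(ubs.ubs_keys)} residues")

# predict contacts on an apo conformation and score against the UBS
sphere = build_sphere(holo, holo.ligands[0])
apo = perturb(holo, 0.3, 0.0, seed=33)
match = evaluate_match(sphere, apo, structural_align(sphere, apo))
scores = score_prediction(match.contact_keys, ubs,
                          {r.key for r in apo.residues})
print(f"TP={scores.tp} FP={scores.fp} TN={scores.tn} FN={scores.fn}")
print(f"MCC={scores.mcc:.3f}  F={scores.f:.3f}")
# MCC near 1 means the predicted pocket residues coincide with the family
# reference; FP counts overpredicted residues, FN missed ones.
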