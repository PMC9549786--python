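"""Evaluation of binding-residue predictions and pocket-level comparisons.

Predictions are scored against a unified binding site (UBS): the union of
every residue contacted (<= 4.5 Å) by any ligand across a protein family.
Residue-level agreement is summarised by the Matthews correlation
coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and the F score

    F = 2*TP / (2*TP + FP + FN),

with MCC defined as 0 (flagged) when any denominator factor vanishes.

The module also provides all-against-all pocket similarity on 16 Å region
representations, exclusive (single-linkage) clustering of the resulting
similarity table, and the affinity-concordance analysis restricted to
highly similar pocket pairs (GDC >= 95 and ligand centroids within 0.5 Å;
relaxed: GDC >= 90 and 1.0 Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats
from scipy.spatial import cKDTree

from .align import structural_align
from .errors import AlignmentInfeasibleError, EmptyReferenceError
from .library import SphereTemplate
from .structure import LigandInstance, ResidueKey, Structure

AFFINITY_MIN_GDC = 95.0
AFFINITY_MAX_CENTROID = 0.5
AFFINITY_RELAXED_MIN_GDC = 90.0
AFFINITY_RELAXED_MAX_CENTROID = 1.0
EXCLUSIVE_CLUSTER_GDC = 70.0  # clustering threshold; prominent config item


@dataclass
class UBSReference:
    """Unified binding site for a protein family."""

    family_id: str
    member_ids: list[str]
    ubs_keys: set[ResidueKey]


@dataclass
class EvalScores:
    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float
    f: float
    mcc_undefined: bool = False


def ligand_contacts(s: Structure, lig: LigandInstance,
                    cutoff: float = 4.5) -> set[ResidueKey]:
    """Residues with a heavy atom within ``cutoff`` of a ligand heavy atom."""
    lig_coords = lig.heavy_coords()
    if lig_coords.shape[0] == 0:
        return set()
    tree = cKDTree(lig_coords)
    own = set(lig.source_residues)
    out: set[ResidueKey] = set()
    for res in s.residues:
        if res.key in own:
            continue
        coords = res.heavy_coords()
        if coords.shape[0] and float(np.min(tree.query(coords)[0])) <= cutoff:
            out.add(res.key)
    return out


def map_to_reference(ref: Structure, other: Structure) -> dict[ResidueKey, ResidueKey]:
    """Map residues of ``other`` onto ``ref`` numbering by global sequence alignment.

    Chains are paired by order of appearance; unaligned residues are simply
    absent from the mapping (callers can detect and report them).
    """
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    mapping: dict[ResidueKey, ResidueKey] = {}
    for rc, oc in zip(ref.chain_ids, other.chain_ids):
        ref_res = ref.chain_residues(rc)
        oth_res = other.chain_residues(oc)
        ref_seq = "".join(r.one_letter for r in ref_res)
        oth_seq = "".join(r.one_letter for r in oth_res)
        if not ref_seq or not oth_seq:
            continue
        aln = al.align(oth_seq, ref_seq)[0]
        for (os_, oe), (rs, re_) in zip(aln.aligned[0], aln.aligned[1]):
            for k in range(oe - os_):
                mapping[oth_res[os_ + k].key] = ref_res[rs + k].key
    return mapping


def build_ubs(family: list[tuple[Structure, set[ResidueKey]]],
              family_id: str = "family") -> UBSReference:
    """Union of per-member ligand-contact residue sets (common numbering)."""
    keys: set[ResidueKey] = set()
    for _s, contacts in family:
        keys |= set(contacts)
    if not keys:
        raise EmptyReferenceError(
            f"family {family_id}: no ligand contacts in any member")
    return UBSReference(family_id=family_id,
                        member_ids=[s.struct_id for s, _ in family],
                        ubs_keys=keys)


def confusion_counts(predicted: set[ResidueKey], ubs: UBSReference,
                     universe: set[ResidueKey]) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) of a predicted residue set against the UBS reference."""
    if not predicted <= universe:
        raise ValueError("predicted residues must lie within the scored universe")
    ref = ubs.ubs_keys & universe
    tp = len(predicted & ref)
    fp = len(predicted - ref)
    fn = len(ref - predicted)
    tn = len(universe) - tp - fp - fn
    return tp, fp, tn, fn


def mcc_f(tp: int, fp: int, tn: int, fn: int) -> EvalScores:
    """Matthews correlation coefficient and F score from a confusion table."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    undefined = denom == 0
    mcc = 0.0 if undefined else (tp * tn - fp * fn) / math.sqrt(denom)
    f_denom = 2 * tp + fp + fn
    f = 0.0 if f_denom == 0 else 2 * tp / f_denom
    return EvalScores(tp=tp, fp=fp, tn=tn, fn=fn, mcc=mcc, f=f,
                      mcc_undefined=undefined)


def score_prediction(predicted: set[ResidueKey], ubs: UBSReference,
                     universe: set[ResidueKey]) -> EvalScores:
    return mcc_f(*confusion_counts(predicted, ubs, universe))


def pocket_similarity(region_a: Structure, sphere_a: SphereTemplate,
                      region_b: Structure, sphere_b: SphereTemplate,
                      unit: str = "CA") -> tuple[float, float, float, bool]:
    """Similarity of pocket b to pocket a on 16 Å region representations.

    Aligns b's sphere onto a's region and returns ``(gdc, lga_s,
    centroid_distance, ok)`` where the centroid distance is between b's
    transplanted ligand and a's native ligand (heavy-atom centroids).
    ``ok=False`` flags an infeasible alignment (similarities 0).
    """
    from .detect import transplant_ligand
    try:
        aln = structural_align(sphere_b, region_a, unit=unit)
    except AlignmentInfeasibleError:
        return 0.0, 0.0, float("inf"), False
    if not aln.pairs:
        return 0.0, 0.0, float("inf"), False
    moved = transplant_ligand(aln.transform, sphere_b.ligand.atoms)
    moved_centroid = np.array([a.pos for a in moved if a.is_heavy]).mean(axis=0)
    native_centroid = sphere_a.ligand.heavy_coords().mean(axis=0)
    dist = float(np.linalg.norm(moved_centroid - native_centroid))
    return aln.gdc, aln.lga_s, dist, True


def all_vs_all_similarity(pockets: list[tuple[Structure, SphereTemplate]],
                          unit: str = "CA") -> pd.DataFrame:
    """Pairwise pocket-similarity table over (region, sphere) pairs."""
    rows = []
    for i, (ra, sa) in enumerate(pockets):
        for j, (rb, sb) in enumerate(pockets):
            if i == j:
                continue
            gdc, lga, cdist_, ok = pocket_similarity(ra, sa, rb, sb, unit=unit)
            rows.append({"a": ra.struct_id, "b": rb.struct_id, "gdc": gdc,
                         "lga_s": lga, "centroid_distance": cdist_, "ok": ok})
    return pd.DataFrame(rows, columns=["a", "b", "gdc", "lga_s",
                                       "centroid_distance", "ok"])


def exclusive_cluster(sim: pd.DataFrame,
                      threshold: float = EXCLUSIVE_CLUSTER_GDC) -> list[list[str]]:
    """Single-linkage partition of pockets by pairwise GDC.

    ``sim`` needs columns a, b, gdc; the table is symmetrised by max. Every
    id appearing in the table lands in exactly one cluster. Clusters are
    ordered by size (desc), then best internal gdc (desc), then first id.
    """
    ids = sorted(set(sim["a"]) | set(sim["b"]))
    best: dict[tuple[str, str], float] = {}
    for _, row in sim.iterrows():
        key = (min(row["a"], row["b"]), max(row["a"], row["b"]))
        g = float(row["gdc"])
        if key not in best or g > best[key]:
            best[key] = g
    g = nx.Graph()
    g.add_nodes_from(ids)
    for (a, b), score in best.items():
        if score >= threshold:
            g.add_edge(a, b, gdc=score)
    comps = [sorted(c) for c in nx.connected_components(g)]

    def best_internal(comp: list[str]) -> float:
        scores = [best.get((min(a, b), max(a, b)), 0.0)
                  for i, a in enumerate(comp) for b in comp[i + 1:]]
        return max(scores) if scores else 0.0

    comps.sort(key=lambda c: (-len(c), -best_internal(c), c[0]))
    return comps


def affinity_concordance(pairs: list[tuple[float, float, float, float]],
                         min_gdc: float = AFFINITY_MIN_GDC,
                         max_centroid: float = AFFINITY_MAX_CENTROID,
                         ) -> tuple[float, float, int, bool]:
    """Concordance of binding affinities between similar pocket pairs.

    Each record is ``(gdc, centroid_distance, affinity_a, affinity_b)``
    with affinities on a -log10 molar scale (pKd or pKi; never mix the two
    populations in one call). Pairs pass when ``gdc >= min_gdc`` and
    ``centroid_distance <= max_centroid``. Returns ``(r2, spearman,
    n_pairs, defined)``; statistics are NaN with ``defined=False`` when
    fewer than 3 pairs survive.
    """
    surviving = [(a, b) for gdc, cd, a, b in pairs
                 if gdc >= min_gdc and cd <= max_centroid]
    n = len(surviving)
    if n < 3:
        return float("nan"), float("nan"), n, False
    xs = np.array([a for a, _ in surviving])
    ys = np.array([b for _, b in surviving])
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        if np.allclose(xs, ys):
            return 1.0, 1.0, n, True
        return float("nan"), float("nan"), n, False
    r, _ = stats.pearsonr(xs, ys)
    rho, _ = stats.spearmanr(xs, ys)
    return float(r ** 2), float(rho), n, True
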