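"""Consensus pockets: merging individually detected matches into clusters.

Because many templates can match the same region of a query, accepted
matches are merged when they plainly describe the same site: either more
than 80% of their predicted contact residues coincide (overlap
coefficient), or their transplanted ligand centroids lie within 2.0 Å.
Merging is transitive (single linkage over the merge graph), and each
connected component becomes one consensus pocket summarising Nm members,
Nlig distinct ligands and the Nres union of contact residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .detect import PocketMatch
from .errors import InvalidLigandError
from .structure import Atom, ResidueKey, Structure

OVERLAP_FRAC = 0.80
CENTROID_CUTOFF = 2.0
BURIAL_RADIUS = 5.0
BURIAL_MIN_NEIGHBORS = 10


@dataclass
class PocketCluster:
    """One consensus pocket: merged matches plus summary counts."""

    cluster_id: int
    members: list[PocketMatch]

    @property
    def nm(self) -> int:
        return len(self.members)

    @property
    def nlig(self) -> int:
        return len({m.ligand_id for m in self.members})

    @property
    def consensus_keys(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for m in self.members:
            out |= m.contact_keys
        return out

    @property
    def nres(self) -> int:
        return len(self.consensus_keys)

    @property
    def representative(self) -> PocketMatch:
        return max(self.members, key=lambda m: m.alignment.gdc)


def ligand_centroid(atoms: list[Atom], mode: str = "all",
                    query: Structure | None = None,
                    burial_radius: float = BURIAL_RADIUS,
                    burial_min_neighbors: int = BURIAL_MIN_NEIGHBORS,
                    ) -> tuple[np.ndarray, bool]:
    """Heavy-atom centroid of a ligand pose.

    ``mode="all"``: unweighted mean over heavy atoms. ``mode="core"``: mean
    over buried atoms only — those with at least ``burial_min_neighbors``
    protein heavy atoms within ``burial_radius`` — since exposed parts of a
    ligand can point anywhere while the buried core is conserved. Returns
    ``(centroid, fell_back)``; ``fell_back`` is True when no atom is buried
    and the all-atom centroid is returned instead.
    """
    heavy = np.array([a.pos for a in atoms if a.is_heavy])
    if heavy.shape[0] == 0:
        raise InvalidLigandError("ligand has no heavy atoms")
    if mode == "all":
        return heavy.mean(axis=0), False
    if mode != "core":
        raise ValueError("mode must be 'all' or 'core'")
    if query is None:
        raise ValueError("mode='core' requires the query structure")
    from scipy.spatial import cKDTree
    prot = query.heavy_coords()
    if prot.shape[0] == 0:
        return heavy.mean(axis=0), True
    tree = cKDTree(prot)
    counts = np.array([len(tree.query_ball_point(p, burial_radius)) for p in heavy])
    buried = counts >= burial_min_neighbors
    if not np.any(buried):
        return heavy.mean(axis=0), True
    return heavy[buried].mean(axis=0), False


def _overlap_coefficient(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def cluster_matches(matches: list[PocketMatch],
                    overlap_frac: float = OVERLAP_FRAC,
                    centroid_cutoff: float = CENTROID_CUTOFF,
                    overlap_measure: str = "coefficient") -> list[PocketCluster]:
    """Merge matches into consensus pockets by transitive closure.

    Two matches are linked when their contact-set overlap exceeds
    ``overlap_frac`` (overlap coefficient by default, ``"jaccard"``
    optionally) or their all-atom ligand centroids are within
    ``centroid_cutoff``. Clusters are connected components, numbered by
    descending member count (ties: descending best GDC).
    """
    if not matches:
        return []
    measure = _overlap_coefficient if overlap_measure == "coefficient" else _jaccard
    g = nx.Graph()
    g.add_nodes_from(range(len(matches)))
    for i in range(len(matches)):
        for j in range(i + 1, len(matches)):
            a, b = matches[i], matches[j]
            if measure(a.contact_keys, b.contact_keys) > overlap_frac:
                g.add_edge(i, j)
            elif float(np.linalg.norm(a.centroid_all - b.centroid_all)) <= centroid_cutoff:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    clusters = [PocketCluster(cluster_id=0, members=[matches[i] for i in comp])
                for comp in comps]
    clusters.sort(key=lambda c: (-c.nm, -c.representative.alignment.gdc,
                                 c.members[0].sphere_id))
    for k, c in enumerate(clusters, start=1):
        c.cluster_id = k
    return clusters


def summarize_clusters(clusters: list[PocketCluster]) -> pd.DataFrame:
    """One row per member, grouped by cluster, with cluster summary columns."""
    from .detect import matches_to_table
    frames = []
    for c in clusters:
        df = matches_to_table(c.members)
        df.insert(0, "cluster_id", c.cluster_id)
        df["Nm"] = c.nm
        df["Nlig"] = c.nlig
        df["Nres"] = c.nres
        df["consensus_residues"] = ";".join(
            f"{ch}:{n}:{i}" for ch, n, i in sorted(c.consensus_keys))
        frames.append(df)
    if not frames:
        cols = ["cluster_id"] + matches_to_table([]).columns.tolist() + \
               ["Nm", "Nlig", "Nres", "consensus_residues"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)
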