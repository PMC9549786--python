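"""Pocket detection: match spheres to a query, transplant ligands, filter.

A sphere template that aligns well onto a query region predicts a binding
site there; the template's ligand is carried over by the alignment's rigid
transform without any conformational change, so steric clashes with the
query are possible and are counted. A match is accepted as a predicted
site when all four printed thresholds hold (inclusive, as printed):

    Nc >= 10, GDC >= 55.0, N4 >= 1, cl <= 2

with a higher-confidence tier at Nc >= 25, GDC >= 65 and cl <= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .align import AlignmentResult, RigidTransform, structural_align
from .library import SphereLibrary, SphereTemplate
from .structure import Atom, ResidueKey, Structure

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 4.5
CLASH_CUTOFF = 1.0
NC_MIN = 10
GDC_MIN = 55.0
N4_MIN = 1
CL_MAX = 2
HIGH_NC_MIN = 25
HIGH_GDC_MIN = 65.0
HIGH_CL_MAX = 1

MATCH_COLUMNS = ["LIGAND", "Ns", "RMSD", "Nc", "SeqID", "LGA", "GDC", "N4",
                 "cl", "accepted", "high_confidence", "contacts",
                 "centroid_x", "centroid_y", "centroid_z"]


@dataclass
class PocketMatch:
    """One sphere matched to a query region with a transplanted ligand."""

    sphere_id: str
    ligand_id: str
    ns: int
    alignment: AlignmentResult
    ligand_atoms: list[Atom]
    contact_keys: set[ResidueKey]
    clash_keys: set[ResidueKey]
    centroid_all: np.ndarray
    centroid_core: np.ndarray | None
    accepted: bool
    high_confidence: bool

    @property
    def n4(self) -> int:
        return len(self.contact_keys)

    @property
    def cl(self) -> int:
        return len(self.clash_keys)


def transplant_ligand(t: RigidTransform, atoms: list[Atom]) -> list[Atom]:
    """Map ligand atoms by the alignment transform; conformation unchanged."""
    if not atoms:
        return []
    pos = t.apply(np.array([a.pos for a in atoms]))
    return [Atom(name=a.name, element=a.element, pos=pos[k],
                 occupancy=a.occupancy) for k, a in enumerate(atoms)]


def contacts_and_clashes(query: Structure, ligand_atoms: list[Atom],
                         contact_cutoff: float = CONTACT_CUTOFF,
                         clash_cutoff: float = CLASH_CUTOFF,
                         ) -> tuple[set[ResidueKey], int, set[ResidueKey], int]:
    """Residue-level contact (<= 4.5 Å) and clash (< 1.0 Å) sets.

    Both are counted per residue over heavy atoms: several clashing atoms
    inside one residue still count as a single clash.
    """
    lig = np.array([a.pos for a in ligand_atoms if a.is_heavy])
    if lig.shape[0] == 0:
        raise ValueError("ligand has no heavy atoms")
    tree = cKDTree(lig)
    contacts: set[ResidueKey] = set()
    clashes: set[ResidueKey] = set()
    for res in query.residues:
        coords = res.heavy_coords()
        if coords.shape[0] == 0:
            continue
        dmin = float(np.min(tree.query(coords)[0]))
        if dmin <= contact_cutoff:
            contacts.add(res.key)
        if dmin < clash_cutoff:
            clashes.add(res.key)
    return contacts, len(contacts), clashes, len(clashes)


def _core_centroid(lig_heavy: np.ndarray, query: Structure,
                   burial_radius: float = 5.0,
                   burial_min_neighbors: int = 10) -> tuple[np.ndarray | None, bool]:
    """Centroid over buried ligand atoms (>= 10 protein heavy atoms within 5 Å)."""
    prot = query.heavy_coords()
    if prot.shape[0] == 0:
        return None, True
    tree = cKDTree(prot)
    counts = np.array([len(tree.query_ball_point(p, burial_radius)) for p in lig_heavy])
    buried = counts >= burial_min_neighbors
    if not np.any(buried):
        return None, True
    return lig_heavy[buried].mean(axis=0), False


def acceptance_flags(nc: int, gdc: float, n4: int, cl: int,
                     nc_min: int = NC_MIN, gdc_min: float = GDC_MIN,
                     n4_min: int = N4_MIN, cl_max: int = CL_MAX,
                     high_nc_min: int = HIGH_NC_MIN,
                     high_gdc_min: float = HIGH_GDC_MIN,
                     high_cl_max: int = HIGH_CL_MAX) -> tuple[bool, bool]:
    """(accepted, high_confidence) per the printed thresholds, all inclusive."""
    accepted = nc >= nc_min and gdc >= gdc_min and n4 >= n4_min and cl <= cl_max
    high = accepted and nc >= high_nc_min and gdc >= high_gdc_min \
        and cl <= high_cl_max
    return accepted, high


def evaluate_match(sphere: SphereTemplate, query: Structure,
                   alignment: AlignmentResult,
                   contact_cutoff: float = CONTACT_CUTOFF,
                   clash_cutoff: float = CLASH_CUTOFF,
                   nc_min: int = NC_MIN, gdc_min: float = GDC_MIN,
                   n4_min: int = N4_MIN, cl_max: int = CL_MAX) -> PocketMatch:
    """Transplant the sphere's ligand and apply the acceptance filters."""
    lig_atoms = transplant_ligand(alignment.transform, sphere.ligand.atoms)
    lig_heavy = np.array([a.pos for a in lig_atoms if a.is_heavy])
    contacts, n4, clashes, cl = contacts_and_clashes(
        query, lig_atoms, contact_cutoff, clash_cutoff)
    centroid_all = lig_heavy.mean(axis=0)
    centroid_core, _fallback = _core_centroid(lig_heavy, query)

    accepted, high = acceptance_flags(alignment.nc, alignment.gdc, n4, cl,
                                      nc_min, gdc_min, n4_min, cl_max)
    return PocketMatch(sphere_id=sphere.sphere_id,
                       ligand_id=sphere.ligand.ligand_id, ns=sphere.ns,
                       alignment=alignment, ligand_atoms=lig_atoms,
                       contact_keys=contacts, clash_keys=clashes,
                       centroid_all=centroid_all, centroid_core=centroid_core,
                       accepted=accepted, high_confidence=high)


def detect_pockets(query: Structure, lib: SphereLibrary, unit: str = "CA",
                   include_rejected: bool = False,
                   **thresholds) -> list[PocketMatch]:
    """Align every library sphere to the query and keep accepted matches.

    Returns matches sorted by (GDC desc, Nc desc, RMSD asc); pass
    ``include_rejected=True`` to keep rejected matches in the list too.
    """
    if len(query.residues) < 10:
        raise ValueError("query must have at least 10 residues")
    if len(lib) == 0:
        logger.warning("empty sphere library; no pockets to detect")
        return []
    matches: list[PocketMatch] = []
    for sphere in lib:
        try:
            aln = structural_align(sphere, query, unit=unit)
        except Exception as exc:
            logger.warning("alignment failed for %s: %s", sphere.sphere_id, exc)
            continue
        if not aln.pairs:
            continue
        m = evaluate_match(sphere, query, aln, **thresholds)
        if m.accepted or include_rejected:
            matches.append(m)
    matches.sort(key=lambda m: (-m.alignment.gdc, -m.alignment.nc,
                                m.alignment.rmsd, m.sphere_id))
    return matches


def matches_to_table(matches: list[PocketMatch]) -> pd.DataFrame:
    """Summary table in the reported-characteristics layout."""
    rows = []
    for m in matches:
        rows.append({
            "LIGAND": m.sphere_id,
            "Ns": m.ns,
            "RMSD": round(m.alignment.rmsd, 3),
            "Nc": m.alignment.nc,
            "SeqID": round(m.alignment.seq_id, 1),
            "LGA": round(m.alignment.lga_s, 2),
            "GDC": round(m.alignment.gdc, 2),
            "N4": m.n4,
            "cl": m.cl,
            "accepted": m.accepted,
            "high_confidence": m.high_confidence,
            "contacts": ";".join(f"{c}:{n}:{i}" for c, n, i in sorted(m.contact_keys)),
            "centroid_x": round(float(m.centroid_all[0]), 3),
            "centroid_y": round(float(m.centroid_all[1]), 3),
            "centroid_z": round(float(m.centroid_all[2]), 3),
        })
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)
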