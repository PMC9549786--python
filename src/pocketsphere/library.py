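"""Sphere-template library: construction, persistence and preselection.

A sphere template is the reusable unit of the method: a bound ligand plus
every protein residue with a heavy atom within 12 Å of it, annotated with
the 4.5 Å interface residue set and the one-letter sequence of the source
chain(s). Libraries are kept on disk as one PDB file per sphere plus a TSV
index.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .errors import DegenerateSphereError, InvalidCriteriaError, InvalidInputError
from .structure import (LigandInstance, Residue, ResidueKey, Structure,
                        WATER_NAMES, read_structure_file, to_gemmi)

logger = logging.getLogger(__name__)

SHELL_RADIUS = 12.0
INTERFACE_RADIUS = 4.5

INDEX_COLUMNS = ["sphere_id", "ligand_id", "n_heavy", "ns", "source_id", "kind"]


@dataclass
class SphereTemplate:
    """A ligand-environment template: 12 Å shell + ligand + metadata."""

    sphere_id: str
    residues: list[Residue]
    interface_keys: set[ResidueKey]
    ligand: LigandInstance
    source_id: str
    source_sequence: str

    @property
    def ns(self) -> int:
        return len(self.residues)

    def as_structure(self) -> Structure:
        """View the template as a Structure (shell = polymer, ligand = hetero)."""
        s = Structure(struct_id=self.sphere_id, residues=list(self.residues),
                      hetero=list(self.ligand.residues))
        s.ligands = [self.ligand]
        return s


@dataclass
class SphereLibrary:
    """An ordered collection of sphere templates with a metadata index."""

    entries: list[SphereTemplate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, sphere_id: str) -> SphereTemplate | None:
        for t in self.entries:
            if t.sphere_id == sphere_id:
                return t
        return None

    @property
    def index(self) -> pd.DataFrame:
        rows = [{
            "sphere_id": t.sphere_id,
            "ligand_id": t.ligand.ligand_id,
            "n_heavy": t.ligand.n_heavy,
            "ns": t.ns,
            "source_id": t.source_id,
            "kind": t.ligand.kind,
        } for t in self.entries]
        return pd.DataFrame(rows, columns=INDEX_COLUMNS)


def build_sphere(s: Structure, lig: LigandInstance,
                 shell_radius: float = SHELL_RADIUS,
                 interface_radius: float = INTERFACE_RADIUS) -> SphereTemplate:
    """Cut the shell of residues around one ligand out of a complex.

    Shell membership and the interface set use heavy atoms only, inclusive
    thresholds, and exclude waters and the ligand's own residues.
    """
    if not (shell_radius >= interface_radius > 0):
        raise ValueError("need shell_radius >= interface_radius > 0")
    lig_coords = lig.heavy_coords()
    if lig_coords.shape[0] == 0:
        raise DegenerateSphereError(f"ligand {lig.ligand_id} has no heavy atoms")
    tree = cKDTree(lig_coords)
    own = set(lig.source_residues)

    shell: list[Residue] = []
    interface: set[ResidueKey] = set()
    for res in s.residues:
        if res.key in own or res.res_name in WATER_NAMES:
            continue
        coords = res.heavy_coords()
        if coords.shape[0] == 0:
            continue
        dmin = float(np.min(tree.query(coords)[0]))
        if dmin <= shell_radius:
            shell.append(res)
            if dmin <= interface_radius:
                interface.add(res.key)
    if not shell:
        raise DegenerateSphereError(
            f"ligand {lig.ligand_id} in {s.struct_id} has an empty 12 A shell")

    sphere_id = f"{lig.ligand_id}.{lig.n_heavy}.{s.struct_id}"
    return SphereTemplate(sphere_id=sphere_id, residues=shell,
                          interface_keys=interface, ligand=lig,
                          source_id=s.struct_id, source_sequence=s.sequence())


def build_library(complexes: list[Structure],
                  shell_radius: float = SHELL_RADIUS,
                  interface_radius: float = INTERFACE_RADIUS) -> SphereLibrary:
    """One sphere per (structure, ligand instance); degenerate spheres skipped."""
    lib = SphereLibrary()
    seen: dict[str, int] = {}
    for s in complexes:
        for lig in s.ligands:
            try:
                t = build_sphere(s, lig, shell_radius, interface_radius)
            except DegenerateSphereError as exc:
                logger.warning("skipping degenerate sphere: %s", exc)
                continue
            if t.sphere_id in seen:
                seen[t.sphere_id] += 1
                new_id = f"{t.sphere_id}_{seen[t.sphere_id]}"
                logger.warning("duplicate sphere id %s -> %s", t.sphere_id, new_id)
                t.sphere_id = new_id
            else:
                seen[t.sphere_id] = 1
            lib.entries.append(t)
    return lib


def _aligner() -> Align.PairwiseAligner:
    # Smith-Waterman with BLOSUM62 and affine gaps (open 11, extend 1)
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def sw_identity(query_seq: str, target_seq: str) -> tuple[float, bool]:
    """Percent identity over the Smith–Waterman local alignment.

    Returns ``(identity, aligned)``; ``aligned`` is False when no
    positive-scoring local alignment exists (identity 0 in that case).
    The denominator is the number of columns of the local alignment.
    """
    if not query_seq or not target_seq:
        raise InvalidInputError("sw_identity requires two non-empty sequences")
    q = query_seq.upper()
    t = target_seq.upper()
    allowed = set("ACDEFGHIKLMNPQRSTVWYXBZJUO")
    if (set(q) | set(t)) - allowed:
        bad = sorted((set(q) | set(t)) - allowed)
        raise InvalidInputError(f"non-amino-acid letters in input: {bad}")
    al = _aligner()
    alignments = al.align(q, t)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0, False
    if best.score <= 0 or best.length == 0:
        return 0.0, False
    counts = best.counts()
    return 100.0 * counts.identities / best.length, True


def preselect(lib: SphereLibrary, criteria: dict) -> SphereLibrary:
    """Filter the library by ligand attributes and/or sequence identity.

    Recognised criteria: ``max_seq_id``/``min_seq_id`` (percent, require
    ``query_seq``), ``ligand_ids`` (set of names), ``n_heavy_range``
    ([min, max] heavy atoms). An empty criteria dict returns the library
    unchanged. All provided criteria must hold simultaneously.
    """
    unknown = set(criteria) - {"max_seq_id", "min_seq_id", "ligand_ids",
                               "n_heavy_range", "query_seq"}
    if unknown:
        raise InvalidCriteriaError(f"unknown criteria: {sorted(unknown)}")
    max_id = criteria.get("max_seq_id")
    min_id = criteria.get("min_seq_id")
    query_seq = criteria.get("query_seq")
    if (max_id is not None or min_id is not None) and not query_seq:
        raise InvalidCriteriaError("sequence-identity criteria require query_seq")
    if max_id is not None and min_id is not None and min_id > max_id:
        raise InvalidCriteriaError(f"min_seq_id {min_id} > max_seq_id {max_id}")
    rng = criteria.get("n_heavy_range")
    if rng is not None and rng[0] > rng[1]:
        raise InvalidCriteriaError(f"empty n_heavy_range {rng}")
    ligand_ids = criteria.get("ligand_ids")

    kept = []
    for t in lib.entries:
        if ligand_ids is not None and t.ligand.ligand_id not in ligand_ids:
            continue
        if rng is not None and not (rng[0] <= t.ligand.n_heavy <= rng[1]):
            continue
        if max_id is not None or min_id is not None:
            if not t.source_sequence:
                continue
            ident, _ = sw_identity(query_seq, t.source_sequence)
            if max_id is not None and ident > max_id:
                continue
            if min_id is not None and ident < min_id:
                continue
        kept.append(t)
    return SphereLibrary(entries=kept)


def fingerprint_preselect(lib: SphereLibrary, smiles: str | None = None) -> SphereLibrary:
    """Chemical-fingerprint preselection hook (not implemented): identity."""
    return lib


def save_library(lib: SphereLibrary, out_dir: str) -> None:
    """Persist as one PDB per sphere plus an ``index.tsv``."""
    os.makedirs(out_dir, exist_ok=True)
    for t in lib.entries:
        safe = t.sphere_id.replace("/", "_")
        text = to_gemmi(t.as_structure()).make_pdb_string()
        with open(os.path.join(out_dir, f"{safe}.pdb"), "w") as fh:
            fh.write(text)
        with open(os.path.join(out_dir, f"{safe}.meta.tsv"), "w") as fh:
            fh.write("sphere_id\tsource_id\tligand_id\tkind\tsource_sequence\t"
                     "ligand_keys\tinterface_keys\n")
            lig_keys = ";".join(f"{c}:{n}:{i}" for c, n, i in t.ligand.source_residues)
            int_keys = ";".join(f"{c}:{n}:{i}" for c, n, i in sorted(t.interface_keys))
            fh.write(f"{t.sphere_id}\t{t.source_id}\t{t.ligand.ligand_id}\t"
                     f"{t.ligand.kind}\t{t.source_sequence}\t{lig_keys}\t{int_keys}\n")
    lib.index.to_csv(os.path.join(out_dir, "index.tsv"), sep="\t", index=False)


def _parse_keys(text: str) -> list[ResidueKey]:
    keys = []
    for part in text.split(";"):
        if not part:
            continue
        c, n, i = part.split(":")
        keys.append((c, int(n), i))
    return keys


def load_library(lib_dir: str) -> SphereLibrary:
    """Load a library saved by :func:`save_library`."""
    index = pd.read_csv(os.path.join(lib_dir, "index.tsv"), sep="\t")
    entries = []
    for _, row in index.iterrows():
        safe = str(row.sphere_id).replace("/", "_")
        s = read_structure_file(os.path.join(lib_dir, f"{safe}.pdb"),
                                struct_id=str(row.source_id))
        meta = pd.read_csv(os.path.join(lib_dir, f"{safe}.meta.tsv"), sep="\t",
                           keep_default_na=False)
        m = meta.iloc[0]
        lig_keys = set(_parse_keys(m.ligand_keys))
        all_res = {r.key: r for r in s.residues}
        all_res.update({r.key: r for r in s.hetero})
        lig_res = [all_res[k] for k in sorted(lig_keys, key=lambda k: (k[0], k[1], k[2]))]
        shell = [r for r in s.residues if r.key not in lig_keys]
        lig = LigandInstance(ligand_id=str(m.ligand_id), kind=str(m.kind),
                             residues=lig_res)
        entries.append(SphereTemplate(
            sphere_id=str(row.sphere_id), residues=shell,
            interface_keys=set(_parse_keys(m.interface_keys)), ligand=lig,
            source_id=str(m.source_id),
            source_sequence=str(m.source_sequence) if m.source_sequence else ""))
    return SphereLibrary(entries=entries)
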