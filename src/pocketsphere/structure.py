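"""Macromolecular structure model and PDB/mmCIF input-output.

The in-memory model is deliberately small: a :class:`Structure` is an
ordered list of polymer :class:`Residue` objects plus the hetero groups
found in the file, from which ligand instances (compounds, metals/ions and
short peptide chains) are derived. Parsing and serialisation are delegated
to gemmi; this module only applies the ligand bookkeeping rules on top:

* waters (HOH/WAT/DOD) are never ligands,
* a polymer chain of at most 25 residues bound to a longer chain is a
  peptide ligand,
* hydrogens are kept in the model but excluded from every distance
  computation and heavy-atom count,
* alternate locations are collapsed to the highest-occupancy conformer
  (ties broken by file order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, FormatError, InvalidLigandError

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})
#: polymer chains up to this many residues may act as peptide ligands
MAX_PEPTIDE_RESIDUES = 25

ResidueKey = tuple[str, int, str]


@dataclass
class Atom:
    """A single atom: label, element, position (Å) and occupancy."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """One residue identified by (chain, author number, insertion code)."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def rep_point_ca(self) -> np.ndarray | None:
        a = self.get_atom("CA")
        return a.pos if a is not None else None

    @property
    def rep_point_cb(self) -> np.ndarray | None:
        """CB position; falls back to CA (glycine, missing side chain)."""
        a = self.get_atom("CB")
        return a.pos if a is not None else self.rep_point_ca

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        heavy = self.heavy_atoms()
        if not heavy:
            return np.empty((0, 3))
        return np.array([a.pos for a in heavy])

    @property
    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.res_name)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            return code if code.isalpha() else "X"
        return "X"


@dataclass
class LigandInstance:
    """A ligand: hetero compound, metal/ion, or short peptide chain.

    ``residues`` keeps the original residue grouping (one entry for a
    compound, several for a peptide) so ligands can round-trip to PDB.
    """

    ligand_id: str
    kind: str  # compound | peptide | metal_or_ion
    residues: list[Residue]

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def source_residues(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if a.is_heavy)

    def heavy_coords(self) -> np.ndarray:
        heavy = [a.pos for a in self.atoms if a.is_heavy]
        if not heavy:
            return np.empty((0, 3))
        return np.array(heavy)


@dataclass
class Structure:
    """Polymer residues plus hetero groups of one coordinate file."""

    struct_id: str
    residues: list[Residue] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)
    ligands: list[LigandInstance] = field(default_factory=list)
    source_format: str = "PDB"

    @property
    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues}

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def sequence(self, chain_id: str | None = None) -> str:
        """One-letter sequence over observed polymer residues."""
        residues = self.residues if chain_id is None else self.chain_residues(chain_id)
        return "".join(r.one_letter for r in residues)

    def heavy_coords(self) -> np.ndarray:
        coords = [a.pos for r in self.residues for a in r.atoms if a.is_heavy]
        if not coords:
            return np.empty((0, 3))
        return np.array(coords)


def _collapse_altlocs(raw_atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by file order."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in raw_atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [best[n] for n in order]


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue:
    icode = res.seqid.icode.strip()
    atoms = [
        Atom(
            name=a.name,
            element=a.element.name,
            pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
            occupancy=float(a.occ),
        )
        for a in _collapse_altlocs(list(res))
    ]
    return Residue(chain_id=chain_id, seq_num=res.seqid.num, icode=icode,
                   res_name=res.name, atoms=atoms)


def _first_offending_line(raw: str) -> str:
    known = ("ATOM", "HETATM", "MODEL", "ENDMDL", "TER", "END", "HEADER",
             "TITLE", "REMARK", "CRYST1", "SEQRES", "HELIX", "SHEET",
             "CONECT", "ANISOU", "HET", "SSBOND", "LINK", "SCALE", "ORIGX",
             "MASTER", "COMPND", "SOURCE", "KEYWDS", "EXPDTA", "AUTHOR",
             "REVDAT", "JRNL", "DBREF", "SEQADV", "MODRES", "FORMUL")
    for line in raw.splitlines():
        if line.strip() and not line.startswith(known):
            return line.strip()[:60]
    return "<empty file>"


def parse_structure(raw: str, fmt: str = "PDB", struct_id: str = "query") -> Structure:
    """Parse PDB or mmCIF text into a :class:`Structure`.

    Hetero groups (including waters) are kept in ``hetero``; ligand
    instances are derived immediately via :func:`list_ligand_instances`.
    """
    fmt_u = fmt.upper().replace("MMCIF", "MMCIF")
    try:
        if fmt_u == "PDB":
            st = gemmi.read_pdb_string(raw)
        elif fmt_u in ("MMCIF", "CIF"):
            block = gemmi.cif.read_string(raw).sole_block()
            st = gemmi.make_structure_from_block(block)
        else:
            raise FormatError(f"unknown format {fmt!r}; expected PDB or mmCIF")
    except FormatError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise FormatError(f"unparseable {fmt} content: {exc}") from exc

    if len(st) == 0 or sum(ch.count_atom_sites() for ch in st[0]) == 0:
        if fmt_u == "PDB":
            raise FormatError(
                f"no coordinate records parsed; first offending record: "
                f"{_first_offending_line(raw)!r}")
        raise EmptyStructureError("structure contains no atomic coordinates")

    st.setup_entities()
    model = st[0]

    polymer: list[Residue] = []
    hetero: list[Residue] = []
    for chain in model:
        for res in chain:
            converted = _convert_residue(chain.name, res)
            if res.entity_type == gemmi.EntityType.Polymer:
                polymer.append(converted)
            else:
                hetero.append(converted)

    if not polymer and not hetero:
        raise EmptyStructureError("structure contains no residues")

    s = Structure(struct_id=struct_id, residues=polymer, hetero=hetero,
                  source_format="PDB" if fmt_u == "PDB" else "mmCIF")
    s.ligands = list_ligand_instances(s)
    return s


def list_ligand_instances(s: Structure) -> list[LigandInstance]:
    """Enumerate ligands: hetero compounds, metals/ions and peptide chains.

    Waters never appear. A polymer chain qualifies as a peptide ligand when
    it has at most 25 residues and the structure contains at least one other
    polymer chain (a lone short chain is the query itself, not its ligand).
    """
    ligands: list[LigandInstance] = []
    for res in s.hetero:
        if res.res_name in WATER_NAMES:
            continue
        n_heavy = len(res.heavy_atoms())
        if n_heavy == 0:
            continue
        kind = "metal_or_ion" if n_heavy == 1 else "compound"
        ligands.append(LigandInstance(ligand_id=res.res_name, kind=kind,
                                      residues=[res]))
    chain_ids = s.chain_ids
    if len(chain_ids) > 1:
        for cid in chain_ids:
            chain = s.chain_residues(cid)
            if 1 <= len(chain) <= MAX_PEPTIDE_RESIDUES:
                lig = LigandInstance(ligand_id=cid, kind="peptide", residues=chain)
                if lig.n_heavy > 0:
                    ligands.append(lig)
    return ligands


def extract_region(s: Structure, lig: LigandInstance, radius: float = 16.0) -> Structure:
    """Sub-structure of residues with any heavy atom within ``radius`` of the ligand.

    The ligand's own residues (peptide case) are excluded from the protein
    part; the ligand itself is carried along in ``ligands``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig_coords = lig.heavy_coords()
    if lig_coords.shape[0] == 0:
        raise InvalidLigandError(f"ligand {lig.ligand_id} has no heavy atoms")
    tree = cKDTree(lig_coords)
    own = set(lig.source_residues)
    kept: list[Residue] = []
    for res in s.residues:
        if res.key in own:
            continue
        coords = res.heavy_coords()
        if coords.shape[0] and np.min(tree.query(coords)[0]) <= radius:
            kept.append(res)
    return Structure(struct_id=f"{s.struct_id}|{lig.ligand_id}@{radius:g}A",
                     residues=kept, hetero=[], ligands=[lig],
                     source_format=s.source_format)


def to_gemmi(s: Structure, extra_hetero: list[Residue] | None = None) -> gemmi.Structure:
    """Build a gemmi Structure (for PDB output) from ours."""
    st = gemmi.Structure()
    st.name = s.struct_id
    model = gemmi.Model("1")
    by_chain: dict[str, list[tuple[Residue, bool]]] = {}
    for r in s.residues:
        by_chain.setdefault(r.chain_id, []).append((r, False))
    for r in list(s.hetero) + list(extra_hetero or []):
        by_chain.setdefault(r.chain_id, []).append((r, True))
    for cid, residues in by_chain.items():
        chain = gemmi.Chain(cid)
        for r, is_het in residues:
            gres = gemmi.Residue()
            gres.name = r.res_name
            gres.seqid = gemmi.SeqId(r.seq_num, r.icode if r.icode else " ")
            gres.het_flag = "H" if is_het else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(s: Structure, path=None) -> str:
    """Serialise to PDB text; optionally write it to ``path``."""
    text = to_gemmi(s).make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def ligand_inventory(structures: list[Structure]) -> pd.DataFrame:
    """Tabulate every ligand instance across structures (TSV-exportable)."""
    rows = []
    for s in structures:
        for lig in s.ligands:
            rows.append({
                "ligand_id": lig.ligand_id,
                "kind": lig.kind,
                "n_heavy": lig.n_heavy,
                "source_id": s.struct_id,
                "chain": lig.residues[0].chain_id if lig.residues else "",
            })
    return pd.DataFrame(rows, columns=["ligand_id", "kind", "n_heavy",
                                       "source_id", "chain"])


def read_structure_file(path, fmt: str | None = None, struct_id: str | None = None) -> Structure:
    """Read a structure from disk, inferring the format from the suffix."""
    path = str(path)
    if fmt is None:
        fmt = "mmCIF" if path.endswith((".cif", ".mmcif")) else "PDB"
    if struct_id is None:
        struct_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    with open(path) as fh:
        return parse_structure(fh.read(), fmt=fmt, struct_id=struct_id)
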