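"""Deterministic toy protein-ligand complexes, apo variants and decoys.

Every pipeline stage is testable without downloads: the generator builds an
idealised alpha-helix bundle (backbone N, CA, C, O plus CB) whose inner
surface forms a concave site, plants a rigid multi-atom pseudo-ligand
there, and records the exact 4.5 Å contact truth. Apo/homolog variants are
emulated by Gaussian coordinate noise plus seeded residue-type mutations
with the ligand removed; negative controls are self-avoiding random-walk
chains with no concave site.

Side chains beyond CB are not generated, so all-atom scoring on fixtures
exercises backbone+CB atom matching only; this is a limitation of the
fixtures, not of the scorer. All generators are pure functions of their
spec (seeded).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GenerationError
from .structure import Atom, LigandInstance, Residue, ResidueKey, Structure

AA3 = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
       "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
       "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
       "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}
AA1 = sorted(AA3)

HELIX_RADIUS = 2.28      # Å, CA helix radius -> 3.8 Å CA-CA spacing
HELIX_RISE = 1.5         # Å per residue
HELIX_TWIST = 100.0      # degrees per residue
BUNDLE_RADIUS = 7.0      # Å, helix axes from the bundle axis
CA_SPACING = 3.8
LIGAND_BALL_RADIUS = 2.4
LIGAND_MIN_SPACING = 1.3
LIGAND_PROTEIN_MIN = 2.6


@dataclass
class FixtureSpec:
    """Parameters of one synthetic holo complex."""

    n_res: int = 80
    topology: str = "helix-bundle-4"
    ligand_n_atoms: int = 12
    noise_sigma: float = 0.0
    mutate_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.mutate_frac <= 1:
            raise ValueError("mutate_frac must be in [0, 1]")


def _build_backbone(ca: np.ndarray, outward: np.ndarray, chain_id: str,
                    seq: str, start_num: int = 1) -> list[Residue]:
    """Residues with N, CA, C, O, CB placed in the local frame of a CA trace."""
    n = ca.shape[0]
    residues = []
    for j in range(n):
        p = ca[j]
        d_prev = ca[j - 1] - p if j > 0 else p - ca[j + 1]
        d_next = ca[j + 1] - p if j < n - 1 else p - ca[j - 1]
        d_prev = d_prev / np.linalg.norm(d_prev)
        d_next = d_next / np.linalg.norm(d_next)
        out = outward[j] / np.linalg.norm(outward[j])
        n_dir = d_prev + 0.35 * out
        c_dir = d_next + 0.35 * out
        n_pos = p + 1.46 * n_dir / np.linalg.norm(n_dir)
        c_pos = p + 1.52 * c_dir / np.linalg.norm(c_dir)
        perp = np.cross(d_next, out)
        nperp = np.linalg.norm(perp)
        if nperp < 1e-9:
            perp = np.cross(d_next, np.array([0.0, 0.0, 1.0]))
            nperp = np.linalg.norm(perp)
        o_pos = c_pos + 1.23 * perp / nperp
        cb_pos = p + 1.53 * out
        atoms = [Atom("N", "N", n_pos), Atom("CA", "C", p),
                 Atom("C", "C", c_pos), Atom("O", "O", o_pos),
                 Atom("CB", "C", cb_pos)]
        residues.append(Residue(chain_id=chain_id, seq_num=start_num + j,
                                icode="", res_name=AA3[seq[j]], atoms=atoms))
    return residues


def _bundle_ca(n_res: int, n_helices: int) -> tuple[np.ndarray, np.ndarray]:
    """CA trace and outward directions for an antiparallel helix bundle."""
    per = [n_res // n_helices] * n_helices
    for k in range(n_res % n_helices):
        per[k] += 1
    ca_all, out_all = [], []
    for h in range(n_helices):
        nh = per[h]
        phi = 2.0 * np.pi * h / n_helices
        center = BUNDLE_RADIUS * np.array([np.cos(phi), np.sin(phi), 0.0])
        direction = 1.0 if h % 2 == 0 else -1.0
        z0 = -direction * (nh - 1) * HELIX_RISE / 2.0
        for j in range(nh):
            theta = np.deg2rad(HELIX_TWIST * j) + phi + np.pi  # inward-facing start
            local = np.array([HELIX_RADIUS * np.cos(theta),
                              HELIX_RADIUS * np.sin(theta),
                              z0 + direction * HELIX_RISE * j])
            ca_all.append(center + local)
            out_all.append(np.array([np.cos(theta), np.sin(theta), 0.0]))
    return np.array(ca_all), np.array(out_all)


def make_toy_complex(spec: FixtureSpec) -> tuple[Structure, dict]:
    """Build a holo helix-bundle complex and its ground truth.

    Returns ``(holo, truth)`` where truth carries the exact ligand pose and
    the brute-force 4.5 Å contact residue keys.
    """
    if spec.n_res < 30:
        raise GenerationError("n_res must be >= 30")
    if spec.ligand_n_atoms < 4:
        raise GenerationError("ligand_n_atoms must be >= 4")
    if not spec.topology.startswith("helix-bundle-"):
        raise GenerationError(f"unknown topology {spec.topology!r}")
    n_helices = int(spec.topology.rsplit("-", 1)[1])
    if n_helices < 3:
        raise GenerationError("need at least 3 helices to enclose a site")

    rng = np.random.default_rng(spec.seed)
    seq = "".join(rng.choice(AA1, size=spec.n_res))
    ca, outward = _bundle_ca(spec.n_res, n_helices)
    residues = _build_backbone(ca, outward, "A", seq)

    prot_coords = np.array([a.pos for r in residues for a in r.atoms])
    tree = cKDTree(prot_coords)
    # the site is a channel along the bundle axis: sample in a cylinder whose
    # half-height grows with the requested ligand size
    half_height = max(LIGAND_BALL_RADIUS,
                      LIGAND_MIN_SPACING * spec.ligand_n_atoms / 8.0)
    helix_half = (min(spec.n_res // n_helices, spec.n_res) * HELIX_RISE) / 2.0
    half_height = min(half_height, max(2.0, helix_half - 4.0))
    lig_pos: list[np.ndarray] = []
    tries = 0
    while len(lig_pos) < spec.ligand_n_atoms:
        tries += 1
        if tries > 20000:
            raise GenerationError("could not place ligand atoms in the site")
        p = rng.uniform(-LIGAND_BALL_RADIUS, LIGAND_BALL_RADIUS, size=3)
        p[2] = rng.uniform(-half_height, half_height)
        if np.linalg.norm(p[:2]) > LIGAND_BALL_RADIUS:
            continue
        if lig_pos and np.min(np.linalg.norm(np.array(lig_pos) - p, axis=1)) \
                < LIGAND_MIN_SPACING:
            continue
        if tree.query(p)[0] < LIGAND_PROTEIN_MIN:
            continue
        lig_pos.append(p)

    lig_res = Residue(chain_id="L", seq_num=1, icode="", res_name="LIG",
                      atoms=[Atom(f"C{k + 1}", "C", pos)
                             for k, pos in enumerate(lig_pos)])
    holo = Structure(struct_id=f"toy{spec.seed}", residues=residues,
                     hetero=[lig_res])
    holo.ligands = [LigandInstance(ligand_id="LIG", kind="compound",
                                   residues=[lig_res])]

    lig_arr = np.array(lig_pos)
    lig_tree = cKDTree(lig_arr)
    contacts: set[ResidueKey] = set()
    for r in residues:
        if float(np.min(lig_tree.query(r.heavy_coords())[0])) <= 4.5:
            contacts.add(r.key)
    truth = {"ligand_pose": lig_arr, "contact_keys": contacts}
    return holo, truth


def perturb(s: Structure, noise_sigma: float, mutate_frac: float, seed: int,
            retain_ligands: bool = False) -> Structure:
    """Apo/homolog emulation: coordinate noise + seeded residue substitutions.

    Adds i.i.d. Gaussian displacement to every atom, substitutes the
    residue type of a seeded random subset (atoms kept, CB retained as the
    side-chain representative) and drops ligands unless ``retain_ligands``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    out = copy.deepcopy(s)
    rng = np.random.default_rng(seed)
    for res in out.residues:
        for a in res.atoms:
            a.pos = a.pos + rng.normal(0.0, noise_sigma, size=3)
    if retain_ligands:
        for res in out.hetero:
            for a in res.atoms:
                a.pos = a.pos + rng.normal(0.0, noise_sigma, size=3)
    else:
        out.hetero = []
        out.ligands = []
    n_mut = int(round(mutate_frac * len(out.residues)))
    if n_mut:
        idx = rng.choice(len(out.residues), size=n_mut, replace=False)
        for i in sorted(idx):
            res = out.residues[i]
            choices = [a for a in AA1 if AA3[a] != res.res_name]
            res.res_name = AA3[rng.choice(choices)]
    out.struct_id = f"{s.struct_id}|perturbed"
    return out


def make_decoy(n_res: int, seed: int) -> Structure:
    """Self-avoiding random-walk chain with no concave site (negative control).

    CA spacing is 3.8 Å and no two non-adjacent CA come closer than 4.0 Å.
    """
    if n_res < 30:
        raise GenerationError("n_res must be >= 30")
    rng = np.random.default_rng(seed)
    for _restart in range(50):
        ca = [np.zeros(3)]
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        ok = True
        for _ in range(n_res - 1):
            placed = False
            for _try in range(200):
                nd = d + 0.8 * rng.normal(size=3)
                nd /= np.linalg.norm(nd)
                p = ca[-1] + CA_SPACING * nd
                prior = np.array(ca[:-1]) if len(ca) > 1 else None
                if prior is None or np.min(np.linalg.norm(prior - p, axis=1)) >= 4.0:
                    ca.append(p)
                    d = nd
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise GenerationError("self-avoiding walk did not converge")

    ca_arr = np.array(ca)
    centroid = ca_arr.mean(axis=0)
    outward = ca_arr - centroid
    norms = np.linalg.norm(outward, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    outward = outward / norms
    seq = "".join(rng.choice(AA1, size=n_res))
    residues = _build_backbone(ca_arr, outward, "A", seq)
    return Structure(struct_id=f"decoy{seed}", residues=residues)


def write_fixture_set(spec: FixtureSpec, out_dir: str, n_decoys: int = 5,
                      apo_noise: float = 0.3, apo_mutate: float = 0.0) -> dict:
    """Write holo.pdb, apo.pdb, decoys/*.pdb and truth.json under ``out_dir``."""
    import os

    from .structure import write_pdb
    os.makedirs(os.path.join(out_dir, "decoys"), exist_ok=True)
    holo, truth = make_toy_complex(spec)
    apo = perturb(holo, apo_noise, apo_mutate, seed=spec.seed + 1)
    write_pdb(holo, os.path.join(out_dir, "holo.pdb"))
    write_pdb(apo, os.path.join(out_dir, "apo.pdb"))
    for k in range(n_decoys):
        decoy = make_decoy(spec.n_res, seed=spec.seed + 100 + k)
        write_pdb(decoy, os.path.join(out_dir, "decoys", f"decoy{k}.pdb"))
    payload = {
        "spec": asdict(spec),
        "ligand_pose": truth["ligand_pose"].tolist(),
        "contact_keys": sorted([list(k) for k in truth["contact_keys"]]),
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
    return payload
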