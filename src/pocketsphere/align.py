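"""Sequence-independent local structural alignment and similarity scores.

The aligner superposes a sphere template onto a query structure using only
residue representative points (CA, or CB with CA fallback). It follows the
local-global family of methods: many rigid superpositions are seeded from
short gapless fragment pairs, each seed is refined by alternating
nearest-neighbour residue assignment with re-superposition, and candidates
are ranked by a combined GDT + LCS score (``lga_s``, 0-100):

* GDT: for each distance threshold, the largest fraction of aligned
  residues that fits under one rigid superposition within that threshold,
  averaged over the threshold set {1, 2, 4, 8} Å.
* LCS: the longest contiguous run of aligned residues superposable under
  an RMSD cutoff, as a fraction of the alignment, averaged over cutoffs
  {1, 2, 5} Å.
* ``lga_s = 100 * (w * GDT + (1 - w) * LCS)`` with ``w = 0.75``.

All-atom agreement is measured by GDC: heavy atoms of aligned residue
pairs are matched by atom name and the distance-threshold-weighted
fraction within 0.5..5.0 Å (step 0.5, weights 10..1) is reported on a
0-100 scale, crediting side-chain placement rather than backbone only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AlignmentInfeasibleError, DegenerateSuperpositionError
from .library import SphereTemplate
from .structure import Residue, ResidueKey, Structure

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
LCS_CUTOFFS = (1.0, 2.0, 5.0)
GDT_WEIGHT = 0.75
GDC_THRESHOLDS = tuple(0.5 * i for i in range(1, 11))
GDC_WEIGHTS = tuple(float(11 - i) for i in range(1, 11))
CONSERVED_CUTOFF = 4.0
ASSIGN_CUTOFF = 6.0
FRAGMENT_LEN = 7
QUERY_STRIDE = 2
MAX_REFINE_ROUNDS = 20


@dataclass
class RigidTransform:
    """Proper rotation + translation, applied as ``R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass
class AlignmentResult:
    """Residue correspondence, transform and the similarity score bundle."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    transform: RigidTransform
    nc: int
    rmsd: float
    seq_id: float
    lga_s: float
    gdt_fractions: dict[float, float]
    lcs_score: float
    gdc: float = 0.0
    conserved_pairs: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)


def kabsch_superpose(ref: np.ndarray, mov: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation superposition of ``mov`` onto ``ref``.

    Returns the transform and the residual RMSD. Raises
    :class:`DegenerateSuperpositionError` for <3 points or (near-)collinear
    geometry, where the rotation is not determined.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateSuperpositionError(f"need >= 3 points, got {n}")
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    h = (mov - cm).T @ (ref - cr)
    u, sing, vt = np.linalg.svd(h)
    scale = max(np.linalg.norm(ref - cr), np.linalg.norm(mov - cm))
    if scale > 0 and sing[1] / scale**2 < 1e-12:
        raise DegenerateSuperpositionError("collinear point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    t = RigidTransform(rot, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((t.apply(mov) - ref) ** 2, axis=1))))
    return t, rmsd


def _rep_points(residues: list[Residue], unit: str) -> tuple[np.ndarray, list[Residue]]:
    pts, kept = [], []
    for r in residues:
        p = r.rep_point_ca if unit == "CA" else r.rep_point_cb
        if p is not None:
            pts.append(p)
            kept.append(r)
    if not pts:
        return np.empty((0, 3)), []
    return np.array(pts), kept


def _fragments(residues: list[Residue], length: int, stride: int) -> list[tuple[int, int]]:
    """Start/stop index pairs of gapless (single-chain, contiguous) windows."""
    frags = []
    i = 0
    n = len(residues)
    while i + length <= n:
        window = residues[i:i + length]
        if all(window[k].chain_id == window[0].chain_id for k in range(length)):
            frags.append((i, i + length))
            i += stride
        else:
            i += 1
    return frags


def _assign_pairs(s_pts: np.ndarray, q_pts: np.ndarray,
                  s_res: list[Residue], q_res: list[Residue],
                  transform: RigidTransform,
                  cutoff: float = ASSIGN_CUTOFF) -> list[tuple[int, int]]:
    """Chain-consistent, order-monotone mutual nearest neighbours under ``transform``."""
    moved = transform.apply(s_pts)
    d = cdist(moved, q_pts)
    nn_s = np.argmin(d, axis=1)
    nn_q = np.argmin(d, axis=0)
    mutual = [(i, int(nn_s[i])) for i in range(len(s_res))
              if nn_q[nn_s[i]] == i and d[i, nn_s[i]] <= cutoff]
    if not mutual:
        return []
    # one query chain per sphere chain: keep the pairing with the most support
    by_chain: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, j in mutual:
        by_chain.setdefault((s_res[i].chain_id, q_res[j].chain_id), []).append((i, j))
    chosen: dict[str, list[tuple[int, int]]] = {}
    for (sc, _qc), pairs in by_chain.items():
        if sc not in chosen or len(pairs) > len(chosen[sc]):
            chosen[sc] = pairs
    out: list[tuple[int, int]] = []
    for pairs in chosen.values():
        pairs.sort()
        out.extend(_longest_increasing(pairs))
    out.sort()
    return out


def _longest_increasing(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest subsequence with strictly increasing query index (pairs sorted)."""
    if not pairs:
        return []
    tails: list[int] = []
    links: list[int] = [-1] * len(pairs)
    idx_at: list[int] = []
    import bisect
    seq = [j for _, j in pairs]
    for k, v in enumerate(seq):
        pos = bisect.bisect_left([seq[i] for i in idx_at], v)
        if pos == len(idx_at):
            idx_at.append(k)
        else:
            idx_at[pos] = k
        links[k] = idx_at[pos - 1] if pos > 0 else -1
    out = []
    k = idx_at[-1]
    while k >= 0:
        out.append(pairs[k])
        k = links[k]
    return out[::-1]


def score_lga_s(s_pts: np.ndarray, q_pts: np.ndarray,
                transform: RigidTransform,
                gdt_thresholds=GDT_THRESHOLDS,
                lcs_cutoffs=LCS_CUTOFFS,
                w: float = GDT_WEIGHT,
                n_total: int | None = None) -> tuple[float, dict[float, float], float]:
    """Combined GDT + LCS score for matched representative points.

    ``s_pts``/``q_pts`` are the aligned pairs in alignment order;
    ``transform`` is the starting superposition (refined per threshold).
    Fractions are taken over ``n_total`` residues (the full template size
    when scoring a template-query alignment, so partial alignments cannot
    outscore complete ones); it defaults to the number of pairs. Returns
    ``(lga_s, gdt_fractions, lcs_score)``, all on a 0-100 scale except the
    per-threshold fractions (0-1).
    """
    n = s_pts.shape[0]
    if n == 0:
        return 0.0, {d: 0.0 for d in gdt_thresholds}, 0.0
    n_total = max(n_total or n, n)

    gdt_fractions: dict[float, float] = {}
    for thr in gdt_thresholds:
        best = _gdt_fraction(s_pts, q_pts, transform, thr, n_total)
        gdt_fractions[thr] = best
    gdt_component = float(np.mean(list(gdt_fractions.values())))

    lcs_fracs = [_lcs_fraction(s_pts, q_pts, c, n_total) for c in lcs_cutoffs]
    lcs_score = 100.0 * float(np.mean(lcs_fracs))

    lga_s = 100.0 * (w * gdt_component + (1.0 - w) * (lcs_score / 100.0))
    return lga_s, gdt_fractions, lcs_score


def _gdt_fraction(s_pts: np.ndarray, q_pts: np.ndarray,
                  transform: RigidTransform, thr: float, n_total: int) -> float:
    """Max fraction of pairs within ``thr`` over iteratively refined superpositions."""
    dist = np.linalg.norm(transform.apply(s_pts) - q_pts, axis=1)
    best = float(np.sum(dist <= thr)) / n_total
    subset = dist <= thr
    for _ in range(10):
        if np.sum(subset) < 3:
            break
        try:
            t, _ = kabsch_superpose(q_pts[subset], s_pts[subset])
        except DegenerateSuperpositionError:
            break
        dist = np.linalg.norm(t.apply(s_pts) - q_pts, axis=1)
        new_subset = dist <= thr
        best = max(best, float(np.sum(new_subset)) / n_total)
        if np.array_equal(new_subset, subset):
            break
        subset = new_subset
    return best


def _window_rmsd_ok(s_pts: np.ndarray, q_pts: np.ndarray, cutoff: float) -> bool:
    try:
        _, rmsd = kabsch_superpose(q_pts, s_pts)
    except DegenerateSuperpositionError:
        return False
    return rmsd <= cutoff


def _lcs_fraction(s_pts: np.ndarray, q_pts: np.ndarray, cutoff: float,
                  n_total: int) -> float:
    """Longest contiguous run (alignment order) superposable at <= cutoff RMSD."""
    n = s_pts.shape[0]
    if n < 3:
        return n / n_total if n > 0 else 0.0
    best = 2  # any 2 points superpose exactly
    lo, hi = 3, n
    while lo <= hi:
        mid = (lo + hi) // 2
        ok = any(_window_rmsd_ok(s_pts[i:i + mid], q_pts[i:i + mid], cutoff)
                 for i in range(n - mid + 1))
        if ok:
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best / n_total


def score_gdc(sphere_res: list[Residue], query_res: list[Residue],
              pairs: list[tuple[int, int]], transform: RigidTransform,
              thresholds=GDC_THRESHOLDS, weights=GDC_WEIGHTS) -> float:
    """All-atom distance-threshold-weighted similarity over conserved pairs.

    Heavy atoms are matched by identical name within each residue pair;
    an atom name present in only one residue counts as outside every
    threshold. Returns 0-100.
    """
    total = 0
    matched_dists: list[float] = []
    for i, j in pairs:
        sa = {a.name: a.pos for a in sphere_res[i].heavy_atoms()}
        qa = {a.name: a.pos for a in query_res[j].heavy_atoms()}
        names = set(sa) | set(qa)
        total += len(names)
        common = set(sa) & set(qa)
        if common:
            sp = transform.apply(np.array([sa[n] for n in common]))
            qp = np.array([qa[n] for n in common])
            matched_dists.extend(np.linalg.norm(sp - qp, axis=1).tolist())
    if total == 0:
        return 0.0
    if not matched_dists:
        return 0.0
    dists = np.array(matched_dists)
    fracs = np.array([np.sum(dists <= d) / total for d in thresholds])
    wsum = float(np.sum(weights))
    return float(100.0 * np.sum(np.array(weights) * fracs) / wsum)


def structural_align(sphere: SphereTemplate, query: Structure, unit: str = "CA",
                     conserved_cutoff: float = CONSERVED_CUTOFF,
                     assign_cutoff: float = ASSIGN_CUTOFF,
                     fragment_len: int = FRAGMENT_LEN,
                     query_stride: int = QUERY_STRIDE,
                     compute_gdc: bool = True) -> AlignmentResult:
    """Align a sphere template onto a query by seeded fragment superposition.

    Seeds are Kabsch superpositions of every gapless ``fragment_len``-mer
    of the sphere onto every ``query_stride``-strided gapless window of the
    query; each seed is refined by alternating residue assignment and
    re-superposition. The candidate with the best ``lga_s`` wins (ties:
    larger conserved-pair count, then lower RMSD).
    """
    if unit not in ("CA", "CB"):
        raise ValueError("unit must be CA or CB")
    s_pts, s_res = _rep_points(sphere.residues, unit)
    q_pts, q_res = _rep_points(query.residues, unit)
    if len(s_res) < 3 or len(q_res) < 3:
        raise AlignmentInfeasibleError(
            f"need >= 3 representative points (sphere {len(s_res)}, query {len(q_res)})")

    s_frags = _fragments(s_res, fragment_len, 1)
    q_frags = _fragments(q_res, fragment_len, query_stride)
    if not s_frags or not q_frags:
        # too short for fragment seeding: fall back to a whole-set seed
        s_frags = [(0, min(len(s_res), len(q_res)))]
        q_frags = [(0, min(len(s_res), len(q_res)))]

    seen_pairsets: set[frozenset] = set()
    candidates: list[tuple[tuple, list[tuple[int, int]], RigidTransform, float,
                           dict[float, float], float]] = []

    def consider(pairs: list[tuple[int, int]], transform: RigidTransform) -> bool:
        """Score a converged pair set; returns True on a perfect self-match."""
        key = frozenset(pairs)
        if len(pairs) < 3 or key in seen_pairsets:
            return False
        seen_pairsets.add(key)
        sp = s_pts[[i for i, _ in pairs]]
        qp = q_pts[[j for _, j in pairs]]
        try:
            t_final, _ = kabsch_superpose(qp, sp)
        except DegenerateSuperpositionError:
            return False
        lga, gdt_fr, lcs = score_lga_s(sp, qp, t_final, n_total=len(s_res))
        dist = np.linalg.norm(t_final.apply(sp) - qp, axis=1)
        nc = int(np.sum(dist <= conserved_cutoff))
        rmsd_all = float(np.sqrt(np.mean(dist ** 2)))
        candidates.append(((lga, nc, -rmsd_all), pairs, t_final, lcs, gdt_fr, lga))
        return lga > 99.999 and nc == len(s_res)

    done = False
    for si, sj in s_frags:
        if done:
            break
        for qi, qj in q_frags:
            if sj - si != qj - qi:
                continue
            try:
                t, frag_rmsd = kabsch_superpose(q_pts[qi:qj], s_pts[si:sj])
            except DegenerateSuperpositionError:
                continue
            if frag_rmsd > 3.0:
                continue
            pairs = [(si + k, qi + k) for k in range(sj - si)]
            prev: frozenset = frozenset()
            for _ in range(MAX_REFINE_ROUNDS):
                pairs = _assign_pairs(s_pts, q_pts, s_res, q_res, t, assign_cutoff)
                key = frozenset(pairs)
                if len(pairs) < 3 or key == prev:
                    break
                prev = key
                try:
                    t, _ = kabsch_superpose(q_pts[[j for _, j in pairs]],
                                            s_pts[[i for i, _ in pairs]])
                except DegenerateSuperpositionError:
                    break
            if len(pairs) >= 3 and consider(pairs, t):
                done = True
                break

    if not candidates:
        return AlignmentResult(pairs=[], transform=RigidTransform.identity(),
                               nc=0, rmsd=0.0, seq_id=0.0, lga_s=0.0,
                               gdt_fractions={d: 0.0 for d in GDT_THRESHOLDS},
                               lcs_score=0.0, gdc=0.0)

    candidates.sort(key=lambda c: c[0], reverse=True)
    _, pairs, transform, lcs, gdt_fr, lga = candidates[0]

    dist = np.linalg.norm(
        transform.apply(s_pts[[i for i, _ in pairs]]) - q_pts[[j for _, j in pairs]],
        axis=1)
    conserved = [p for p, d in zip(pairs, dist) if d <= conserved_cutoff]
    if len(conserved) >= 3:
        # report transform/RMSD re-fit on the conserved set
        transform, rmsd = kabsch_superpose(
            q_pts[[j for _, j in conserved]], s_pts[[i for i, _ in conserved]])
    else:
        rmsd = float(np.sqrt(np.mean(dist ** 2))) if len(dist) else 0.0

    nc = len(conserved)
    if nc:
        ident = sum(1 for i, j in conserved
                    if s_res[i].res_name == q_res[j].res_name)
        seq_id = 100.0 * ident / nc
    else:
        seq_id = 0.0

    gdc = 0.0
    if compute_gdc and conserved:
        gdc = score_gdc(s_res, q_res, conserved, transform)

    key_pairs = [(s_res[i].key, q_res[j].key) for i, j in pairs]
    key_conserved = [(s_res[i].key, q_res[j].key) for i, j in conserved]
    return AlignmentResult(pairs=key_pairs, transform=transform, nc=nc,
                           rmsd=rmsd, seq_id=seq_id, lga_s=lga,
                           gdt_fractions=gdt_fr, lcs_score=lcs, gdc=gdc,
                           conserved_pairs=key_conserved)
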