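"""Rigid superposition, the fragment aligner and the GDT/LCS/GDC scores."""

import copy

import numpy as np
import pytest

from pocketsphere import (kabsch_superpose, score_gdc, score_lga_s,
                          structural_align)
from pocketsphere.align import RigidTransform
from pocketsphere.errors import DegenerateSuperpositionError
from pocketsphere.structure import Atom, Residue
from pocketsphere.synthetic import perturb


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _rigidly_move(structure, seed=3, shift=(12.0, -7.0, 4.0)):
    q = _random_rotation(seed)
    t = np.asarray(shift)
    moved = copy.deepcopy(structure)
    for r in moved.residues + moved.hetero:
        for a in r.atoms:
            a.pos = q @ a.pos + t
    return moved


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        t, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)
        assert rmsd < 1e-9

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        t, rmsd = kabsch_superpose(pts, pts + np.array([5.0, 0.0, 0.0]))
        assert rmsd < 1e-9
        np.testing.assert_allclose(t.translation, [-5.0, 0.0, 0.0], atol=1e-9)

    def test_recovers_random_rotation(self):
        pts = np.random.default_rng(2).normal(size=(20, 3))
        q = _random_rotation(7)
        t, rmsd = kabsch_superpose(pts, pts @ q.T)
        assert rmsd <= 1e-9
        np.testing.assert_allclose(t.rotation @ q, np.eye(3), atol=1e-9)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_roundtrip_inverse(self):
        pts = np.random.default_rng(3).normal(size=(6, 3))
        t, _ = kabsch_superpose(pts, pts @ _random_rotation(9).T + 2.0)
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-6)

    @pytest.mark.parametrize("bad", [
        np.zeros((2, 3)),                                   # too few points
        np.outer(np.arange(5.0), np.array([1.0, 0, 0])),    # collinear
    ])
    def test_degenerate_geometry_rejected(self, bad):
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_superpose(bad, bad)


class TestStructuralAlign:
    def test_self_match_is_exact(self, toy):
        holo, _, sphere = toy
        aln = structural_align(sphere, holo)
        assert aln.nc == sphere.ns
        assert aln.rmsd <= 1e-6
        assert aln.seq_id == pytest.approx(100.0)
        assert aln.lga_s == pytest.approx(100.0)
        assert aln.gdc == pytest.approx(100.0)
        # identity correspondence
        assert all(a == b for a, b in aln.conserved_pairs)

    def test_noise_recovery(self, toy):
        holo, _, sphere = toy
        noisy = perturb(holo, 0.3, 0.0, seed=42, retain_ligands=True)
        aln = structural_align(sphere, noisy)
        identity = sum(a == b for a, b in aln.conserved_pairs)
        assert identity >= 0.95 * sphere.ns
        assert aln.rmsd <= 0.6

    def test_rigid_motion_invariance_of_scores(self, toy):
        holo, _, sphere = toy
        moved = _rigidly_move(holo, seed=11)
        a0 = structural_align(sphere, holo)
        a1 = structural_align(sphere, moved)
        assert a1.nc == a0.nc
        assert a1.rmsd == pytest.approx(a0.rmsd, abs=1e-6)
        assert a1.lga_s == pytest.approx(a0.lga_s, abs=1e-6)
        assert a1.gdc == pytest.approx(a0.gdc, abs=1e-6)

    def test_monotone_degradation_with_noise(self, toy):
        holo, _, sphere = toy
        lga, gdc = [], []
        for sigma in (0.0, 0.3, 0.6, 1.0):
            noisy = perturb(holo, sigma, 0.0, seed=100, retain_ligands=True)
            aln = structural_align(sphere, noisy)
            lga.append(aln.lga_s)
            gdc.append(aln.gdc)
        tol = 1.0  # sampling tolerance at fixed seed
        assert all(lga[i] >= lga[i + 1] - tol for i in range(3))
        assert all(gdc[i] >= gdc[i + 1] - tol for i in range(3))

    def test_cb_unit_self_match(self, toy):
        holo, _, sphere = toy
        aln = structural_align(sphere, holo, unit="CB")
        assert aln.nc == sphere.ns
        assert aln.rmsd <= 1e-6


class TestScoreLgaS:
    def test_perfect_pairs_score_100(self):
        pts = np.random.default_rng(0).normal(size=(20, 3)) * 5
        lga, gdt, lcs = score_lga_s(pts, pts, RigidTransform.identity())
        assert lga == pytest.approx(100.0)
        assert all(f == 1.0 for f in gdt.values())
        assert lcs == pytest.approx(100.0)

    def test_all_beyond_thresholds_score_0(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        # every pair displaced far beyond the largest threshold, incoherently
        far = pts + rng.normal(scale=200.0, size=(12, 3))
        lga, gdt, lcs = score_lga_s(pts, far, RigidTransform.identity())
        assert all(f == 0.0 for f in gdt.values())
        assert lga <= 25.0 * (2 / 12)  # only the trivial 2-point LCS remains

    def test_half_perfect_half_far(self):
        """Contiguous half at distance 0, half beyond all thresholds."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3)) * 4
        b = a.copy()
        # second half displaced incoherently, far beyond 8 A
        b[5:] += rng.normal(scale=300.0, size=(5, 3)) + 50.0
        lga, gdt, lcs = score_lga_s(a, b, RigidTransform.identity())
        assert all(f == pytest.approx(0.5) for f in gdt.values())
        assert lcs == pytest.approx(50.0)
        assert lga == pytest.approx(100.0 * (0.75 * 0.5 + 0.25 * 0.5))

    def test_empty_alignment_scores_0(self):
        lga, _, lcs = score_lga_s(np.empty((0, 3)), np.empty((0, 3)),
                                  RigidTransform.identity())
        assert lga == 0.0 and lcs == 0.0


def _res(name, atom_specs, chain="A", num=1):
    return Residue(chain, num, "", name,
                   [Atom(n, e, np.asarray(p, dtype=float))
                    for n, e, p in atom_specs])


class TestScoreGdc:
    def test_identical_residues_score_100(self):
        r = _res("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                         ("CB", "C", (2, 1, 0))])
        gdc = score_gdc([r], [r], [(0, 0)], RigidTransform.identity())
        assert gdc == pytest.approx(100.0)

    def test_all_beyond_5A_scores_0(self):
        r0 = _res("ALA", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
        r1 = _res("ALA", [("CA", "C", (10, 0, 0)), ("CB", "C", (11.5, 0, 0))])
        gdc = score_gdc([r0], [r1], [(0, 0)], RigidTransform.identity())
        assert gdc == 0.0

    def test_half_at_zero_half_beyond(self):
        """f_i = 0.5 at every threshold forces gdc = 50 under linear weights."""
        r0 = _res("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                          ("C", "C", (3, 0, 0)), ("O", "O", (4.5, 0, 0))])
        r1 = _res("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                          ("C", "C", (3, 0, 9)), ("O", "O", (4.5, 0, 9))])
        gdc = score_gdc([r0], [r1], [(0, 0)], RigidTransform.identity())
        assert gdc == pytest.approx(50.0)

    def test_missing_atoms_count_as_not_within(self):
        r0 = _res("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                          ("CB", "C", (2, 1, 0)), ("O", "O", (3, 0, 0))])
        r1 = _res("GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0))])
        # 2 matched at distance 0 out of a 4-name universe -> f_i = 0.5
        gdc = score_gdc([r0], [r1], [(0, 0)], RigidTransform.identity())
        assert gdc == pytest.approx(50.0)

    def test_matches_brute_force_scorer(self, toy):
        """Weighted-fraction identity against an independent direct evaluation."""
        holo, _, sphere = toy
        noisy = perturb(holo, 0.5, 0.0, seed=77, retain_ligands=True)
        aln = structural_align(sphere, noisy)
        pairs_idx = []
        s_res = sphere.residues
        q_map = {r.key: r for r in noisy.residues}
        q_res = [q_map[qk] for _, qk in aln.conserved_pairs]
        for k, (sk, _) in enumerate(aln.conserved_pairs):
            i = next(i for i, r in enumerate(s_res) if r.key == sk)
            pairs_idx.append((i, k))
        got = score_gdc(s_res, q_res, pairs_idx, aln.transform)

        # brute force: per-threshold counts over the union-name universe
        total, dists = 0, []
        for i, k in pairs_idx:
            sa = {a.name: a.pos for a in s_res[i].heavy_atoms()}
            qa = {a.name: a.pos for a in q_res[k].heavy_atoms()}
            total += len(set(sa) | set(qa))
            for n in set(sa) & set(qa):
                moved = aln.transform.rotation @ sa[n] + aln.transform.translation
                dists.append(float(np.linalg.norm(moved - qa[n])))
        num = sum((11 - i) * sum(d <= 0.5 * i for d in dists)
                  for i in range(1, 11))
        expected = 100.0 * num / (55 * total)
        assert got == pytest.approx(expected, abs=1e-9)
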