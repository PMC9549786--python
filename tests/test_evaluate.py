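"""UBS references, MCC/F scoring, pocket similarity and affinity concordance."""

import math

import numpy as np
import pytest

from pocketsphere import (affinity_concordance, build_sphere, build_ubs,
                          confusion_counts, exclusive_cluster, extract_region,
                          ligand_contacts, map_to_reference, mcc_f,
                          pocket_similarity)
from pocketsphere.errors import EmptyReferenceError
from pocketsphere.evaluate import UBSReference
from pocketsphere.synthetic import FixtureSpec, make_toy_complex, perturb


def _keys(*nums):
    return {("A", n, "") for n in nums}


def _ubs(*nums):
    return UBSReference("fam", [], _keys(*nums))


class TestBuildUbs:
    def test_singleton_union(self, toy):
        holo, truth, _ = toy
        ubs = build_ubs([(holo, truth["contact_keys"])])
        assert ubs.ubs_keys == truth["contact_keys"]

    def test_union_of_two_members(self, toy):
        holo, _, _ = toy
        ubs = build_ubs([(holo, _keys(5, 7)), (holo, _keys(7, 11))])
        assert ubs.ubs_keys == _keys(5, 7, 11)

    def test_no_contacts_anywhere_rejected(self, toy):
        with pytest.raises(EmptyReferenceError):
            build_ubs([(toy[0], set())])

    def test_family_of_perturbed_copies_matches_contact_oracle(self, toy):
        """UBS over noisy holo copies equals the brute-force union of scans."""
        holo, _, _ = toy
        members = []
        for seed in (21, 22, 23):
            m = perturb(holo, 0.3, 0.0, seed=seed, retain_ligands=True)
            members.append((m, ligand_contacts(m, m.ligands[0])))
        ubs = build_ubs(members)
        expected = set()
        for m, _ in members:
            lig = m.ligands[0].heavy_coords()
            for r in m.residues:
                dmin = min(np.linalg.norm(a.pos - lp)
                           for a in r.heavy_atoms() for lp in lig)
                if dmin <= 4.5:
                    expected.add(r.key)
        assert ubs.ubs_keys == expected


class TestConfusionAndMccF:
    def test_perfect_prediction(self):
        tp, fp, tn, fn = confusion_counts(_keys(1, 2, 3), _ubs(1, 2, 3),
                                          _keys(*range(1, 11)))
        assert (fp, fn) == (0, 0)
        sc = mcc_f(tp, fp, tn, fn)
        assert sc.mcc == pytest.approx(1.0) and sc.f == pytest.approx(1.0)

    def test_disjoint_sets(self):
        tp, fp, tn, fn = confusion_counts(_keys(1, 2), _ubs(3, 4),
                                          _keys(*range(1, 11)))
        assert tp == 0
        sc = mcc_f(tp, fp, tn, fn)
        assert sc.f == 0.0

    def test_hand_evaluated_case(self):
        sc = mcc_f(6, 2, 88, 4)
        assert sc.mcc == pytest.approx(520 / math.sqrt(8 * 10 * 90 * 92))
        assert sc.mcc == pytest.approx(0.639, abs=5e-4)
        assert sc.f == pytest.approx(2 * 6 / (2 * 6 + 2 + 4)) == pytest.approx(
            0.667, abs=5e-4)

    def test_zero_denominator_flagged(self):
        sc = mcc_f(0, 0, 10, 0)  # empty prediction, empty reference
        assert sc.mcc == 0.0 and sc.mcc_undefined

    def test_exhaustive_small_universe_against_set_oracle(self):
        """All (predicted, reference) subset pairs of a 6-residue universe."""
        universe = _keys(*range(1, 7))
        elems = sorted(universe)
        for pn in range(2 ** 6):
            predicted = {elems[i] for i in range(6) if pn >> i & 1}
            for rn in range(2 ** 6):
                ref = {elems[i] for i in range(6) if rn >> i & 1}
                tp, fp, tn, fn = confusion_counts(
                    predicted, UBSReference("f", [], ref), universe)
                assert tp == len(predicted & ref)
                assert fp == len(predicted - ref)
                assert fn == len(ref - predicted)
                assert tp + fp + tn + fn == 6

    def test_permutation_invariance(self):
        """Relabeling residues changes neither MCC nor F."""
        pred, ref, uni = _keys(1, 2, 3), _ubs(2, 3, 4), _keys(*range(1, 9))
        sc1 = mcc_f(*confusion_counts(pred, ref, uni))
        shift = lambda ks: {("B", n + 100, "") for _, n, _ in ks}
        sc2 = mcc_f(*confusion_counts(shift(pred),
                                      UBSReference("f", [], shift(ref.ubs_keys)),
                                      shift(uni)))
        assert (sc1.mcc, sc1.f) == (sc2.mcc, sc2.f)


@pytest.fixture(scope="module")
def pocket_pair():
    """Two 16 Å pocket representations: original and a noisy homolog."""
    holo, _ = make_toy_complex(FixtureSpec(seed=3))
    lig = holo.ligands[0]
    region_a = extract_region(holo, lig, 16.0)
    sphere_a = build_sphere(holo, lig)
    noisy = perturb(holo, 0.4, 0.1, seed=31, retain_ligands=True)
    lig_b = noisy.ligands[0]
    region_b = extract_region(noisy, lig_b, 16.0)
    sphere_b = build_sphere(noisy, lig_b)
    return (region_a, sphere_a), (region_b, sphere_b)


class TestPocketSimilarity:
    def test_self_similarity_exact(self, pocket_pair):
        (ra, sa), _ = pocket_pair
        gdc, lga, cdist, ok = pocket_similarity(ra, sa, ra, sa)
        assert ok and gdc == pytest.approx(100.0)
        assert cdist <= 1e-6

    def test_approximate_symmetry(self, pocket_pair):
        (ra, sa), (rb, sb) = pocket_pair
        _, lga_ab, _, _ = pocket_similarity(ra, sa, rb, sb)
        _, lga_ba, _, _ = pocket_similarity(rb, sb, ra, sa)
        assert abs(lga_ab - lga_ba) <= 1.0

    def test_noise_degrades_similarity(self, pocket_pair):
        (ra, sa), (rb, sb) = pocket_pair
        gdc_ab, _, _, _ = pocket_similarity(ra, sa, rb, sb)
        assert gdc_ab < 100.0
        # heavier noise degrades further
        holo, _ = make_toy_complex(FixtureSpec(seed=3))
        worse = perturb(holo, 1.0, 0.1, seed=32, retain_ligands=True)
        rw = extract_region(worse, worse.ligands[0], 16.0)
        sw = build_sphere(worse, worse.ligands[0])
        gdc_aw, _, _, _ = pocket_similarity(ra, sa, rw, sw)
        assert gdc_aw < gdc_ab


class TestExclusiveCluster:
    def _sim(self, entries):
        import pandas as pd
        return pd.DataFrame(entries, columns=["a", "b", "gdc"])

    def test_all_above_threshold_one_cluster(self):
        sim = self._sim([("x", "y", 90), ("y", "z", 85), ("x", "z", 80)])
        assert exclusive_cluster(sim, threshold=70) == [["x", "y", "z"]]

    def test_all_below_threshold_singletons(self):
        sim = self._sim([("x", "y", 30), ("y", "z", 20), ("x", "z", 10)])
        assert sorted(exclusive_cluster(sim, threshold=70)) == [["x"], ["y"], ["z"]]

    def test_block_matrix_three_components(self):
        blocks = {"a": ["a1", "a2", "a3"], "b": ["b1", "b2"], "c": ["c1", "c2"]}
        entries = []
        for members in blocks.values():
            for i, x in enumerate(members):
                for y in members[i + 1:]:
                    entries.append((x, y, 95))
        entries += [("a1", "b1", 40), ("b1", "c1", 30), ("a1", "c1", 20)]
        comps = exclusive_cluster(self._sim(entries), threshold=70)
        assert sorted(map(tuple, comps)) == [("a1", "a2", "a3"), ("b1", "b2"),
                                             ("c1", "c2")]

    def test_threshold_extremes(self):
        sim = self._sim([("x", "y", 50), ("y", "z", 10)])
        assert len(exclusive_cluster(sim, threshold=0)) == 1
        assert len(exclusive_cluster(sim, threshold=101)) == 3

    def test_symmetrised_by_max(self):
        sim = self._sim([("x", "y", 60), ("y", "x", 80)])
        assert exclusive_cluster(sim, threshold=70) == [["x", "y"]]


class TestAffinityConcordance:
    def test_identical_affinities_perfect(self):
        pairs = [(99.0, 0.1, v, v) for v in (5.0, 6.0, 7.0, 8.0)]
        r2, rho, n, ok = affinity_concordance(pairs)
        assert ok and n == 4
        assert r2 == pytest.approx(1.0) and rho == pytest.approx(1.0)

    def test_gdc_filter_boundary(self):
        pairs = [(96.0, 0.1, 5, 5), (94.0, 0.1, 6, 6), (96.0, 0.1, 7, 7.1),
                 (96.0, 0.1, 8, 8.2)]
        _, _, n, _ = affinity_concordance(pairs, min_gdc=95.0)
        assert n == 3  # the gdc=94 pair is dropped

    def test_centroid_filter(self):
        pairs = [(99.0, 0.4, 5, 5), (99.0, 0.6, 6, 6), (99.0, 0.5, 7, 7),
                 (99.0, 0.2, 8, 8)]
        _, _, n, _ = affinity_concordance(pairs)
        assert n == 3  # 0.6 A exceeds the 0.5 A cutoff; 0.5 is inclusive

    def test_relaxed_constraints_admit_more(self):
        pairs = [(92.0, 0.8, 5, 5), (91.0, 0.9, 6, 6.4), (97.0, 0.3, 7, 7),
                 (90.5, 1.0, 8, 7.6)]
        _, _, n_strict, _ = affinity_concordance(pairs)
        _, _, n_relaxed, ok = affinity_concordance(pairs, min_gdc=90.0,
                                                   max_centroid=1.0)
        assert n_strict <= n_relaxed == 4 and ok

    def test_statistics_match_textbook_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(4, 9, size=30)
        b = a + rng.normal(scale=0.5, size=30)
        pairs = [(99.0, 0.1, x, y) for x, y in zip(a, b)]
        r2, rho, n, ok = affinity_concordance(pairs)
        assert ok and n == 30
        r_oracle = np.corrcoef(a, b)[0, 1]
        assert r2 == pytest.approx(r_oracle ** 2, abs=1e-12)
        ranks = lambda v: np.argsort(np.argsort(v))
        rho_oracle = np.corrcoef(ranks(a), ranks(b))[0, 1]
        assert rho == pytest.approx(rho_oracle, abs=1e-12)

    def test_too_few_pairs_flagged(self):
        r2, rho, n, ok = affinity_concordance([(99.0, 0.1, 5, 5)])
        assert not ok and n == 1 and math.isnan(r2)


def test_map_to_reference_handles_mutations(toy):
    holo, _, _ = toy
    other = perturb(holo, 0.0, 0.2, seed=9)
    mapping = map_to_reference(holo, other)
    # same length, no indels: the map is the identity on keys
    assert len(mapping) == len(holo.residues)
    assert all(k == v for k, v in mapping.items())
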