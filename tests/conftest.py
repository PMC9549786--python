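"""Shared fixtures: toy complexes, spheres and fabricated pocket matches."""

from __future__ import annotations

import numpy as np
import pytest

from pocketsphere import (PocketMatch, build_sphere, make_toy_complex)
from pocketsphere.align import AlignmentResult, RigidTransform
from pocketsphere.synthetic import FixtureSpec


@pytest.fixture(scope="session")
def toy():
    """Default holo complex with its truth and planted sphere (seed 0)."""
    holo, truth = make_toy_complex(FixtureSpec(seed=0))
    sphere = build_sphere(holo, holo.ligands[0])
    return holo, truth, sphere


@pytest.fixture(scope="session")
def toy_factory():
    """Factory of (holo, truth, sphere) triples for arbitrary seeds."""
    cache = {}

    def make(seed: int):
        if seed not in cache:
            holo, truth = make_toy_complex(FixtureSpec(seed=seed))
            cache[seed] = (holo, truth, build_sphere(holo, holo.ligands[0]))
        return cache[seed]

    return make


def make_match(sphere_id: str, ligand_id: str, contacts: set,
               centroid, gdc: float = 80.0, nc: int = 30,
               accepted: bool = True) -> PocketMatch:
    """Fabricate a PocketMatch for clustering tests."""
    aln = AlignmentResult(pairs=[], transform=RigidTransform.identity(),
                          nc=nc, rmsd=0.5, seq_id=50.0, lga_s=90.0,
                          gdt_fractions={}, lcs_score=90.0, gdc=gdc)
    return PocketMatch(sphere_id=sphere_id, ligand_id=ligand_id, ns=40,
                       alignment=aln, ligand_atoms=[],
                       contact_keys=set(contacts), clash_keys=set(),
                       centroid_all=np.asarray(centroid, dtype=float),
                       centroid_core=None, accepted=accepted,
                       high_confidence=False)


@pytest.fixture
def match_factory():
    return make_match
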