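"""Shared fixtures: independent brute-force oracles and toy inputs."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from raseff.structure import read_structure_string
from raseff.synthetic import PlantedComplexSpec, synth_complex


def brute_force_contacts(structure, gtpase_chain: str, effector_chain: str,
                         cutoff: float = 4.0,
                         model_index: int = 0) -> dict[tuple[int, int], float]:
    """All-atom-pair O(n^2) contact scan, independent of the package path.

    Returns (gtpase seq_number, effector seq_number) -> min distance for
    every intermolecular residue pair within the cutoff.  Heavy atoms
    only; nothing shared with extract_contacts beyond gemmi accessors.
    """
    model = structure[model_index]
    chains = {c.name: c for c in model}
    out: dict[tuple[int, int], float] = {}
    for res_a, res_b in itertools.product(chains[gtpase_chain],
                                          chains[effector_chain]):
        best = np.inf
        for atom_a in res_a:
            if atom_a.element.name in ("H", "D"):
                continue
            for atom_b in res_b:
                if atom_b.element.name in ("H", "D"):
                    continue
                d = atom_a.pos.dist(atom_b.pos)
                if d < best:
                    best = d
        if best <= cutoff:
            out[(res_a.seqid.num, res_b.seqid.num)] = best
    return out


def random_planted_spec(rng: np.random.Generator,
                        max_residues: int = 60) -> PlantedComplexSpec:
    """A random feasible planted-contact spec (matching on the effector side)."""
    n_g = int(rng.integers(3, max_residues + 1))
    n_e = int(rng.integers(3, max_residues + 1))
    n_contacts = int(rng.integers(0, min(n_g, n_e, 8) + 1))
    effectors = rng.choice(n_e, size=n_contacts, replace=False)
    gtpases = rng.integers(0, n_g, size=n_contacts)
    distances = rng.uniform(1.5, 3.95, size=n_contacts)
    planted = tuple(
        (int(g), int(e), float(d))
        for g, e, d in zip(gtpases, effectors, distances)
    )
    return PlantedComplexSpec(
        n_gtpase_residues=n_g, n_effector_residues=n_e,
        planted_contacts=planted,
    )


@pytest.fixture
def toy_structure():
    """A parsed toy complex with three planted contacts."""
    spec = PlantedComplexSpec(12, 15, ((3, 7, 3.5), (4, 8, 3.9), (3, 9, 2.0)))
    return spec, read_structure_string(synth_complex(spec))
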