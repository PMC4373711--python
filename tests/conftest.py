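"""Shared fixtures and the independent brute-force oracle.

The oracle deliberately avoids the vectorized production path: it is a
plain double loop over atom pairs using scalar distance, binning and policy
logic, so agreement with the package is a meaningful check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from starpot import default_binning, default_registry
from starpot.potential import PairingPolicy
from starpot.structure_io import TypedAtom
from starpot.synthetic import GeneratorConfig, toy_library


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_eligible(atom_i: TypedAtom, atom_j: TypedAtom, policy: PairingPolicy,
                    res_ordinal: dict) -> bool:
    ci, cj = atom_i.residue_key[0], atom_j.residue_key[0]
    if ci != cj:
        return policy.cross_chain == "include"
    return abs(res_ordinal[atom_i.residue_key] - res_ordinal[atom_j.residue_key]) >= (
        policy.min_residue_separation
    )


def _residue_ordinals(atoms) -> dict:
    ordinals: dict = {}
    per_chain: dict = {}
    for a in atoms:
        ch = a.residue_key[0]
        if a.residue_key not in ordinals:
            ordinals[a.residue_key] = per_chain.get(ch, 0)
            per_chain[ch] = per_chain.get(ch, 0) + 1
    return ordinals


def oracle_bin(d: float, edges) -> int | None:
    if d >= edges[-1]:
        return None
    for k in range(len(edges) - 1):
        if edges[k] <= d < edges[k + 1]:
            return k
    return None


def brute_force_counts(atoms, binning=None, policy=None) -> Counter:
    """Counter {(a<=b, bin): count} from an explicit double loop."""
    binning = binning or default_binning()
    policy = policy or PairingPolicy()
    ordinals = _residue_ordinals(atoms)
    counts: Counter = Counter()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if not oracle_eligible(atoms[i], atoms[j], policy, ordinals):
                continue
            d = math.dist(atoms[i].coords, atoms[j].coords)
            r = oracle_bin(d, binning.edges)
            if r is None:
                continue
            a, b = sorted((atoms[i].type_index, atoms[j].type_index))
            counts[(a, b, r)] += 1
    return counts


def brute_force_score(atoms, table, policy=None) -> tuple[float, int]:
    """(score, n_pairs) by scalar summation over eligible pairs."""
    policy = policy or PairingPolicy()
    ordinals = _residue_ordinals(atoms)
    total = 0.0
    n = 0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if not oracle_eligible(atoms[i], atoms[j], policy, ordinals):
                continue
            d = math.dist(atoms[i].coords, atoms[j].coords)
            r = oracle_bin(d, table.binning.edges)
            if r is None:
                continue
            total += table.scores[atoms[i].type_index, atoms[j].type_index, r]
            n += 1
    return total, n


def random_typed_atoms(rng: np.random.Generator, n_atoms: int,
                       box: float = 25.0, n_chains: int = 1) -> list[TypedAtom]:
    """Random synthetic atom cloud with registry types and residue structure."""
    registry = default_registry()
    atoms = []
    res_counter = 0
    i = 0
    while i < n_atoms:
        chain = chr(ord("A") + int(rng.integers(n_chains)))
        res_counter += 1
        key = (chain, str(res_counter))
        for _ in range(int(rng.integers(1, 6))):
            if i >= n_atoms:
                break
            atoms.append(
                TypedAtom(
                    type_index=int(rng.integers(registry.size)),
                    coords=tuple(rng.uniform(0, box, size=3)),
                    residue_key=key,
                )
            )
            i += 1
    return atoms


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def binning():
    return default_binning()


@pytest.fixture(scope="session")
def small_library():
    """Ten clean repeat arrays with their entries (seeded)."""
    return toy_library(10, GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_potential(small_library):
    """Potential built from the ten-array panel (default smoothing)."""
    from starpot.potential import build_potential, count_pairs, merge_counts
    from starpot.structure_io import typed_atoms

    tensors = []
    for _, model in small_library:
        atoms, _ = typed_atoms(model)
        tensors.append(count_pairs(atoms))
    return build_potential(merge_counts(tensors))
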