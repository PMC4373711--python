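"""Pair counting, log-odds table construction and scoring."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import brute_force_counts, brute_force_score, random_typed_atoms
from starpot import default_binning, default_registry
from starpot.errors import IncompatibilityError, InputError
from starpot.potential import (
    PairCountTensor,
    PairingPolicy,
    build_potential,
    count_pairs,
    merge_counts,
    read_potential,
    score_structure,
    write_potential,
)
from starpot.structure_io import TypedAtom, typed_atoms
from starpot.synthetic import ideal_helix


def _atom(t, xyz, res, chain="A"):
    return TypedAtom(type_index=t, coords=xyz, residue_key=(chain, str(res)))


def toy_counts():
    """Two-type toy: pair (0,0) counts {bin0:3, bin1:1}; (0,1) {bin0:1, bin1:3}."""
    counts = np.zeros((2, 2, 18), dtype=np.int64)
    counts[0, 0, 0] = 3
    counts[0, 0, 1] = 1
    counts[0, 1, 0] = 1
    counts[0, 1, 1] = 3
    return PairCountTensor(counts=counts, binning=default_binning(), registry_version="toy")


class TestCountPairs:
    def test_single_close_pair(self):
        atoms = [_atom(3, (0.0, 0.0, 0.0), 1), _atom(5, (2.0, 0.0, 0.0), 2)]
        t = count_pairs(atoms)
        assert t.n_total == 1
        assert t.get(3, 5, 0) == 1 and t.get(5, 3, 0) == 1

    def test_pair_beyond_cutoff_not_counted(self):
        atoms = [_atom(3, (0.0, 0.0, 0.0), 1), _atom(5, (25.0, 0.0, 0.0), 2)]
        assert count_pairs(atoms).n_total == 0

    def test_intra_residue_pair_excluded_by_default(self):
        atoms = [_atom(3, (0.0, 0.0, 0.0), 1), _atom(5, (2.0, 0.0, 0.0), 1)]
        assert count_pairs(atoms).n_total == 0

    def test_cross_chain_policy(self):
        atoms = [_atom(3, (0.0, 0.0, 0.0), 1, "A"), _atom(5, (2.0, 0.0, 0.0), 1, "B")]
        assert count_pairs(atoms).n_total == 0
        inc = count_pairs(atoms, policy=PairingPolicy(cross_chain="include"))
        assert inc.n_total == 1

    def test_marginals_are_consistent(self):
        rng = np.random.default_rng(5)
        atoms = random_typed_atoms(rng, 80)
        t = count_pairs(atoms)
        assert t.n_total == t.n_obs_r().sum() == t.n_obs_ab().sum()


class TestMergeCounts:
    def test_identity_and_zero(self):
        rng = np.random.default_rng(6)
        atoms = random_typed_atoms(rng, 40)
        t = count_pairs(atoms)
        zero = PairCountTensor(
            counts=np.zeros_like(t.counts), binning=t.binning,
            registry_version=t.registry_version,
        )
        assert np.array_equal(merge_counts([t]).counts, t.counts)
        assert np.array_equal(merge_counts([t, zero]).counts, t.counts)

    def test_total_is_conserved(self):
        rng = np.random.default_rng(7)
        parts = [count_pairs(random_typed_atoms(rng, 30)) for _ in range(3)]
        assert merge_counts(parts).n_total == sum(p.n_total for p in parts)

    def test_mismatched_binning_rejected(self):
        from starpot.binning import DistanceBinning

        t = toy_counts()
        other = PairCountTensor(
            counts=np.zeros((2, 2, 2), dtype=np.int64),
            binning=DistanceBinning(edges=(0.0, 5.0, 10.0)),
            registry_version="toy",
        )
        with pytest.raises(IncompatibilityError):
            merge_counts([t, other])


class TestBuildPotential:
    def test_hand_computed_log_odds(self):
        table = build_potential(toy_counts(), smoothing="none")
        assert math.isclose(table.score_of(0, 0, 0), -math.log(1.5), rel_tol=1e-12)
        assert math.isclose(table.score_of(0, 0, 1), math.log(2.0), rel_tol=1e-12)
        assert math.isclose(table.score_of(0, 1, 0), math.log(2.0), rel_tol=1e-12)
        assert table.score_of(0, 1, 0) == table.score_of(1, 0, 0)  # symmetry

    def test_proportional_counts_give_zero_potential(self):
        counts = np.zeros((3, 3, 18), dtype=np.int64)
        dist = np.array([4, 2] + [0] * 16)  # same shape for every pair class
        for a in range(3):
            for b in range(a, 3):
                counts[a, b] = dist * (a + b + 1)
        t = PairCountTensor(counts=counts, binning=default_binning(), registry_version="toy")
        table = build_potential(t, smoothing="none")
        assert np.allclose(table.scores, 0.0)

    def test_smoothing_keeps_all_scores_finite(self):
        table = build_potential(toy_counts(), smoothing="laplace", alpha=1.0)
        assert np.isfinite(table.scores).all()

    def test_smoothed_distributions_normalize(self, small_potential):
        tri = np.triu_indices(small_potential.scores.shape[0])
        smoothed = small_potential.counts[tri] + small_potential.smoothing_alpha / 18
        probs = smoothed / smoothed.sum(axis=1, keepdims=True)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_empty_library_rejected(self):
        empty = PairCountTensor(
            counts=np.zeros((2, 2, 18), dtype=np.int64),
            binning=default_binning(), registry_version="toy",
        )
        with pytest.raises(InputError):
            build_potential(empty)


class TestScoreStructure:
    def test_single_pair_lookup(self):
        table = build_potential(toy_counts(), smoothing="none")
        atoms = [_atom(0, (0.0, 0.0, 0.0), 1), _atom(0, (2.0, 0.0, 0.0), 2)]
        rep = score_structure(atoms, table, registry=_ToyRegistry())
        assert rep.n_pairs_counted == 1
        assert math.isclose(rep.raw_score, -math.log(1.5), rel_tol=1e-12)

    def test_no_eligible_pairs_scores_zero(self):
        table = build_potential(toy_counts(), smoothing="none")
        atoms = [_atom(0, (0.0, 0.0, 0.0), 1), _atom(0, (50.0, 0.0, 0.0), 2)]
        rep = score_structure(atoms, table, registry=_ToyRegistry())
        assert rep.raw_score == 0.0 and rep.n_pairs_counted == 0
        assert rep.per_pair_score is None

    def test_registry_mismatch_rejected(self, small_potential):
        atoms = [_atom(0, (0.0, 0.0, 0.0), 1)]
        with pytest.raises(IncompatibilityError):
            score_structure(atoms, small_potential, registry=_ToyRegistry())

    def test_rigid_motion_invariance(self, small_potential):
        atoms, _ = typed_atoms(ideal_helix(12))
        base = score_structure(atoms, small_potential).raw_score
        rng = np.random.default_rng(42)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-50, 50, size=3)
            moved = [
                TypedAtom(a.type_index, tuple(rot @ np.array(a.coords) + shift), a.residue_key)
                for a in atoms
            ]
            score = score_structure(moved, small_potential).raw_score
            assert abs(score - base) <= 1e-9 * abs(base)

    def test_self_consistency_pairs_equal_counts(self):
        atoms, _ = typed_atoms(ideal_helix(8))
        counts = count_pairs(atoms)
        table = build_potential(counts, smoothing="none")
        rep = score_structure(atoms, table)
        assert rep.n_pairs_counted == counts.n_total
        assert np.isfinite(rep.raw_score)  # only observed (finite) cells touched

    def test_additivity_of_disconnected_assemblies(self, small_potential):
        atoms, _ = typed_atoms(ideal_helix(8))
        far = [
            TypedAtom(a.type_index, (a.coords[0] + 100.0, a.coords[1], a.coords[2]),
                      ("A", f"x{a.residue_key[1]}"))
            for a in atoms
        ]
        # two copies >20 Å apart in one model: residue keys disjoint
        combined = atoms + far
        s_combined = score_structure(combined, small_potential).raw_score
        s_parts = (
            score_structure(atoms, small_potential).raw_score
            + score_structure(far, small_potential).raw_score
        )
        assert math.isclose(s_combined, s_parts, rel_tol=1e-9)


class _ToyRegistry:
    version = "toy"
    size = 2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_counts_and_scores_match_brute_force(self, seed, small_potential):
        rng = np.random.default_rng(seed)
        atoms = random_typed_atoms(rng, int(rng.integers(20, 120)), n_chains=2)
        policy = PairingPolicy(min_residue_separation=int(rng.integers(1, 3)))
        t = count_pairs(atoms, policy=policy)
        expected = brute_force_counts(atoms, policy=policy)
        got = {
            (a, b, r): int(t.counts[a, b, r])
            for a, b, r in zip(*np.nonzero(t.counts))
        }
        assert got == dict(expected)
        score, n = brute_force_score(atoms, small_potential, policy=policy)
        rep = score_structure(atoms, small_potential, policy=policy)
        assert rep.n_pairs_counted == n
        assert math.isclose(rep.raw_score, score, rel_tol=1e-9, abs_tol=1e-9)


class TestPotentialFile:
    def test_round_trip_and_byte_determinism(self, small_potential, tmp_path):
        p1 = tmp_path / "pot1.tsv"
        p2 = tmp_path / "pot2.tsv"
        write_potential(small_potential, p1)
        write_potential(small_potential, p2)
        assert p1.read_bytes() == p2.read_bytes()
        with open(p1) as fh:
            assert fh.readline().rstrip() == "#format starpot-potential 1"
        loaded = read_potential(p1)
        assert loaded.n_total == small_potential.n_total
        assert loaded.binning == small_potential.binning
        assert np.array_equal(loaded.counts, small_potential.counts)
        # scores survive the 9-significant-digit round trip
        assert np.allclose(loaded.scores, small_potential.scores, rtol=1e-8, atol=1e-12)

    def test_scoring_with_loaded_table_matches(self, small_potential, tmp_path):
        path = tmp_path / "pot.tsv"
        write_potential(small_potential, path)
        loaded = read_potential(path)
        atoms, _ = typed_atoms(ideal_helix(10))
        s1 = score_structure(atoms, small_potential).raw_score
        s2 = score_structure(atoms, loaded).raw_score
        assert math.isclose(s1, s2, rel_tol=1e-8)

    def test_garbage_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("hello\n")
        with pytest.raises(InputError):
            read_potential(bad)
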