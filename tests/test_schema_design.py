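"""Contact maps, disruption scoring and crossover optimisation."""

import itertools

import numpy as np
import pytest

from splshuffle.library_model import BlockPartition, ChimeraCode
from splshuffle.schema_design import (
    ContactMap,
    build_contact_map,
    chimera_E,
    contacts_from_pdb,
    mean_library_E,
    mean_library_m,
    optimize_crossovers,
)
from splshuffle.synthetic_data import generate_parents

from conftest import parents_from_aa


def random_contacts(rng, L, n):
    pairs = set()
    while len(pairs) < n:
        i, j = sorted(rng.choice(np.arange(1, L + 1), 2, replace=False))
        if j - i >= 2:
            pairs.add((int(i), int(j)))
    return ContactMap(frozenset(pairs), 4.5, 2)


def random_parents(rng, K, L):
    return generate_parents(
        n_parents=K, length_aa=L, partition=BlockPartition(L, (L // 2,)),
        pairwise_identity_target=0.5, seed=int(rng.integers(2**31 - 1)))


class TestContactMap:
    def test_distant_atoms_no_contact(self):
        coords = {1: np.array([[0.0, 0, 0]]), 5: np.array([[10.0, 0, 0]])}
        assert len(build_contact_map(coords, cutoff=4.5, min_separation=2)) == 0

    def test_collinear_hand_computed(self):
        coords = {
            1: np.array([[0.0, 0, 0]]),
            3: np.array([[4.0, 0, 0]]),
            5: np.array([[8.0, 0, 0]]),
        }
        cm = build_contact_map(coords, cutoff=4.5, min_separation=2)
        assert cm.pairs == {(1, 3), (3, 5)}

    def test_min_separation_excludes_neighbours(self):
        coords = {1: np.array([[0.0, 0, 0]]), 2: np.array([[1.0, 0, 0]])}
        assert len(build_contact_map(coords, cutoff=4.5, min_separation=2)) == 0

    def test_atom_order_invariance(self):
        rng = np.random.default_rng(0)
        coords = {i: rng.normal(size=(4, 3)) * 3 for i in range(1, 9)}
        cm1 = build_contact_map(coords, cutoff=5.0)
        shuffled = {i: c[::-1].copy() for i, c in coords.items()}
        cm2 = build_contact_map(shuffled, cutoff=5.0)
        assert cm1.pairs == cm2.pairs

    def test_empty_coordinates_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_contact_map({}, cutoff=4.5)

    def test_pdb_input_with_mapping(self, tmp_path):
        # three single-CA residues on a line, structure numbering offset by 100
        lines = []
        for k, x in enumerate((0.0, 4.0, 8.0)):
            lines.append(
                f"ATOM  {k+1:5d}  CA  ALA A{101+2*k:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
        pdb = tmp_path / "toy.pdb"
        pdb.write_text("\n".join(lines) + "\nEND\n")
        mapping = {101: 1, 103: 3, 105: 5}
        cm = contacts_from_pdb(pdb, chain="A", mapping=mapping, cutoff=4.5)
        assert cm.pairs == {(1, 3), (3, 5)}


class TestChimeraE:
    def test_pure_parent_has_zero_disruption(self, toy_parents, toy_partition):
        cm = ContactMap(frozenset({(1, 2)}), 4.5, 1)
        for lab in toy_parents.labels:
            assert chimera_E(ChimeraCode((lab, lab)), toy_parents, toy_partition, cm) == 0

    def test_broken_pair_counts_one(self, toy_parents, toy_partition):
        cm = ContactMap(frozenset({(1, 2)}), 4.5, 1)
        assert chimera_E(ChimeraCode(("P1", "P2")), toy_parents, toy_partition, cm) == 1

    def test_identical_parents_never_disrupted(self):
        parents = parents_from_aa(["KERD", "KERD"], labels=("A", "B"))
        part = BlockPartition(4, (2,))
        cm = ContactMap(frozenset({(1, 3), (2, 4)}), 4.5, 2)
        for combo in itertools.product("AB", repeat=2):
            assert chimera_E(ChimeraCode(combo), parents, part, cm) == 0


class TestMeanE:
    def test_two_parent_hand_example(self, toy_parents, toy_partition):
        cm = ContactMap(frozenset({(1, 2)}), 4.5, 1)
        assert mean_library_E(toy_partition, toy_parents, cm) == pytest.approx(0.5)

    def test_no_cross_block_contacts_zero(self, toy_parents):
        part = BlockPartition(2, (1,))
        assert mean_library_E(part, toy_parents, ContactMap(frozenset(), 4.5, 2)) == 0.0

    def test_equals_exhaustive_average(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            K, L = int(rng.integers(2, 5)), int(rng.integers(8, 14))
            parents = random_parents(rng, K, L)
            cm = random_contacts(rng, L, 6)
            xs = tuple(sorted(int(x) for x in
                              rng.choice(np.arange(1, L), 2, replace=False)))
            part = BlockPartition(L, xs)
            exact = mean_library_E(part, parents, cm)
            total = sum(
                chimera_E(ChimeraCode(c), parents, part, cm)
                for c in itertools.product(parents.labels, repeat=part.n_blocks)
            )
            assert exact == pytest.approx(total / K ** part.n_blocks, abs=1e-9)

    def test_monotone_in_contacts(self):
        rng = np.random.default_rng(1)
        parents = random_parents(rng, 3, 12)
        part = BlockPartition(12, (4, 8))
        pairs = sorted(random_contacts(rng, 12, 8).pairs)
        prev = 0.0
        for k in range(1, len(pairs) + 1):
            cm = ContactMap(frozenset(pairs[:k]), 4.5, 2)
            val = mean_library_E(part, parents, cm)
            assert val >= prev - 1e-12
            prev = val


class TestMeanM:
    def test_identical_parents_zero(self):
        parents = parents_from_aa(["KERD", "KERD"], labels=("A", "B"))
        m, se = mean_library_m(BlockPartition(4, (2,)), parents)
        assert m == 0.0 and se == 0.0

    def test_two_opposite_parents_symmetry(self):
        # parents differ at every position; 2 equal blocks; exhaustive mean = L/4
        parents = parents_from_aa(["KEKE", "RDRD"], labels=("A", "B"))
        m, se = mean_library_m(BlockPartition(4, (2,)), parents)
        assert m == pytest.approx(1.0)  # L_aa / 4
        assert se == 0.0

    def test_sampling_agrees_with_exhaustive(self):
        rng = np.random.default_rng(3)
        parents = random_parents(rng, 3, 10)
        part = BlockPartition(10, (3, 7))
        exact, _ = mean_library_m(part, parents)
        est, se = mean_library_m(part, parents, n_samples=4000, seed=11,
                                 exhaustive_limit=0)
        assert abs(est - exact) <= max(3 * se, 1e-9)


class TestOptimizer:
    def _instance(self, seed=5, L=20, K=3, n_contacts=30):
        rng = np.random.default_rng(seed)
        return random_parents(rng, K, L), random_contacts(rng, L, n_contacts)

    def test_matches_exhaustive_search(self):
        parents, cm = self._instance()
        L = parents.length_aa
        for nx in (1, 2, 3):
            exhaustive = min(
                mean_library_E(BlockPartition(L, xs), parents, cm)
                for xs in itertools.combinations(range(1, L), nx)
            )
            ranked = optimize_crossovers(parents, cm, nx)
            assert ranked[0].mean_E == pytest.approx(exhaustive, abs=1e-9)

    def test_empty_contacts_all_feasible_scored_zero(self):
        parents, _ = self._instance()
        cm = ContactMap(frozenset(), 4.5, 2)
        ranked = optimize_crossovers(parents, cm, 2, n_best=5)
        assert all(r.mean_E == 0.0 for r in ranked)
        assert len(ranked) == 5

    def test_min_block_constraint_monotone(self):
        parents, cm = self._instance()
        e_small = optimize_crossovers(parents, cm, 2, min_block_aa=2)[0].mean_E
        e_large = optimize_crossovers(parents, cm, 2, min_block_aa=6)[0].mean_E
        assert e_large >= e_small - 1e-12

    def test_constraints_respected(self):
        parents, cm = self._instance()
        ranked = optimize_crossovers(parents, cm, 2, min_block_aa=5,
                                     min_mutations_per_block=2)
        for r in ranked:
            assert min(e - s + 1 for s, e in r.partition.blocks) >= 5

    def test_infeasible_constraints_raise(self):
        parents, cm = self._instance()
        with pytest.raises(ValueError, match="feasible"):
            optimize_crossovers(parents, cm, 3, min_block_aa=10)
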