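"""Structure-guided crossover design for recombination libraries.

The disruption score of a chimera counts residue-residue contacts (i, j)
whose amino-acid pair in the chimera occurs in no single parent ("broken"
contacts).  The library mean disruption <E> over uniform per-block parent
choices decomposes contact-wise:

    <E> = sum over contacts (i, j) in different blocks of c(i, j)

where c(i, j) is the fraction of ordered parent pairs (p, q), including
p == q, whose residue pair (aa_p[i], aa_q[j]) is absent from every parent.
Crossover placement minimising <E> under block-length and block-mutation
constraints is solved exactly by dynamic programming over boundary
positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .library_model import (
    BlockPartition,
    ChimeraCode,
    ParentSet,
    all_codes,
    assemble_chimera,
    enumerate_diversity,
    equivalence_classes,
    merged_label,
)


@dataclass(frozen=True)
class ContactMap:
    """Residue-residue contacts on the parent alignment (1-based, i < j)."""

    pairs: frozenset[tuple[int, int]]
    cutoff_angstrom: float
    min_separation: int

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"contact pair ({i}, {j}) must satisfy i < j")
            if j - i < self.min_separation:
                raise ValueError(f"contact pair ({i}, {j}) violates min_separation")

    def __len__(self) -> int:
        return len(self.pairs)


def build_contact_map(
    coords: Mapping[int, np.ndarray],
    cutoff: float = 4.5,
    min_separation: int = 2,
) -> ContactMap:
    """Contacts between residues with any heavy atoms within ``cutoff`` angstroms.

    Parameters
    ----------
    coords
        Heavy-atom coordinates per residue, keyed by 1-based alignment
        position; each value an ``(n_atoms, 3)`` array (a single ``(3,)``
        point is accepted).
    cutoff
        Distance threshold in angstroms (default 4.5, the convention of
        structure-guided recombination scoring).
    min_separation
        Minimum sequence separation ``j - i`` for a pair to count.
    """
    if not coords:
        raise ValueError("empty coordinate set")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pts, res = [], []
    for pos, xyz in coords.items():
        if pos < 1:
            raise ValueError(f"residue position {pos} outside the alignment (must be >= 1)")
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        pts.append(xyz)
        res.extend([pos] * len(xyz))
    atoms = np.vstack(pts)
    res = np.asarray(res)
    tree = cKDTree(atoms)
    pairs = set()
    for a, b in tree.query_pairs(cutoff):
        i, j = sorted((int(res[a]), int(res[b])))
        if j - i >= min_separation:
            pairs.add((i, j))
    return ContactMap(frozenset(pairs), cutoff_angstrom=cutoff, min_separation=min_separation)


def contacts_from_pdb(
    path,
    chain: str | None = None,
    mapping: Mapping[int, int] | None = None,
    cutoff: float = 4.5,
    min_separation: int = 2,
) -> ContactMap:
    """Build a contact map from a PDB file.

    ``mapping`` translates structure residue numbers to alignment columns;
    structure residues without a mapping entry are skipped.  With no
    mapping, structure numbering is used as-is (it must then already be
    1-based alignment numbering).
    """
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    coords: dict[int, list] = {}
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for residue in ch:
            if residue.id[0].strip():  # skip heteroatoms/water
                continue
            num = residue.id[1]
            pos = mapping.get(num) if mapping is not None else num
            if pos is None or pos < 1:
                continue
            for atom in residue:
                if atom.element != "H":
                    coords.setdefault(pos, []).append(atom.coord)
    return build_contact_map(
        {p: np.array(v) for p, v in coords.items()}, cutoff, min_separation
    )


def read_mapping_tsv(path) -> dict[int, int]:
    """Read a structure-residue -> alignment-column mapping TSV."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["structure_residue"].astype(int), df["alignment_column"].astype(int)))


def broken_fraction(parents: ParentSet, i: int, j: int) -> float:
    """c(i, j): fraction of ordered parent pairs whose residue pair at columns
    (i, j) occurs in no single parent."""
    cols_i = [aa[i - 1] for aa in parents.aa_seqs]
    cols_j = [aa[j - 1] for aa in parents.aa_seqs]
    present = set(zip(cols_i, cols_j))
    K = parents.n_parents
    broken = sum(1 for a in cols_i for b in cols_j if (a, b) not in present)
    return broken / (K * K)


def disruption_weights(parents: ParentSet, contacts: ContactMap) -> dict[tuple[int, int], float]:
    """c(i, j) for every contact pair."""
    return {(i, j): broken_fraction(parents, i, j) for i, j in contacts.pairs}


def chimera_E(
    code: ChimeraCode,
    parents: ParentSet,
    partition: BlockPartition,
    contacts: ContactMap,
) -> int:
    """Number of broken contacts in one chimera."""
    chimera = assemble_chimera(parents, partition, code, "aa")
    E = 0
    for i, j in contacts.pairs:
        pair = (chimera[i - 1], chimera[j - 1])
        present = {(aa[i - 1], aa[j - 1]) for aa in parents.aa_seqs}
        if pair not in present:
            E += 1
    return E


def mean_library_E(
    partition: BlockPartition,
    parents: ParentSet,
    contacts: ContactMap,
    weights: Mapping[tuple[int, int], float] | None = None,
) -> float:
    """Exact library-average disruption <E> for one partition."""
    partition.check_compatible(parents)
    if weights is None:
        weights = disruption_weights(parents, contacts)
    total = 0.0
    for (i, j), c in weights.items():
        if partition.block_of(i) != partition.block_of(j):
            total += c
    return total


def _block_mismatches(parents: ParentSet, partition: BlockPartition) -> np.ndarray:
    """d[b, p, q]: amino-acid mismatches between parents p and q within block b."""
    K, B = parents.n_parents, partition.n_blocks
    d = np.zeros((B, K, K), dtype=int)
    for b, (s, e) in enumerate(partition.blocks):
        segs = [aa[s - 1 : e] for aa in parents.aa_seqs]
        for p in range(K):
            for q in range(p + 1, K):
                m = sum(x != y for x, y in zip(segs[p], segs[q]))
                d[b, p, q] = d[b, q, p] = m
    return d


def mean_library_m(
    partition: BlockPartition,
    parents: ParentSet,
    n_samples: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = 10_000,
) -> tuple[float, float]:
    """Mean amino-acid distance of a uniform random chimera to its closest parent.

    Returns ``(mean, standard_error)``.  When the library's diversity is at
    most ``exhaustive_limit`` the exact expectation over all per-block
    parent-choice combinations is returned (standard error 0); otherwise a
    Monte-Carlo estimate over ``n_samples`` chimeras.
    """
    partition.check_compatible(parents)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    K, B = parents.n_parents, partition.n_blocks
    d = _block_mismatches(parents, partition)

    def nearest(choice: Sequence[int]) -> int:
        dist = d[range(B), choice, :].sum(axis=0)
        return int(dist.min())

    if enumerate_diversity(parents, partition, "aa") <= exhaustive_limit:
        # enumerate equivalence-class combinations, weighted by class sizes
        classes = equivalence_classes(parents, partition, "aa")
        reps = [
            [(parents.index(g[0]), len(g) / K) for g in groups] for groups in classes
        ]
        total = 0.0
        for combo in itertools.product(*reps):
            w = 1.0
            for _, wk in combo:
                w *= wk
            total += w * nearest([p for p, _ in combo])
        return total, 0.0

    rng = np.random.default_rng(seed)
    choices = rng.integers(0, K, size=(n_samples, B))
    vals = np.array([nearest(c) for c in choices], dtype=float)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_samples))


def conserved_columns(parents: ParentSet) -> np.ndarray:
    """Boolean array (length L_aa): True where all parents agree."""
    arr = np.array([list(aa) for aa in parents.aa_seqs])
    return (arr == arr[0]).all(axis=0)


@dataclass(frozen=True)
class RankedPartition:
    partition: BlockPartition
    mean_E: float
    inside_score: float


def optimize_crossovers(
    parents: ParentSet,
    contacts: ContactMap,
    n_crossovers: int,
    min_block_aa: int = 1,
    min_mutations_per_block: int = 0,
    n_best: int = 10,
) -> list[RankedPartition]:
    """Exact minimisation of <E> over crossover placements, by dynamic programming.

    Since the contact weights c(i, j) do not depend on the partition,
    minimising <E> is equivalent to maximising the summed weight of contacts
    kept *inside* blocks.  The DP state is (number of blocks, rightmost
    block end); each state keeps the ``n_best`` highest inside scores so a
    ranked list of optima can be reported.

    Constraints: every block spans at least ``min_block_aa`` residues and
    contains at least ``min_mutations_per_block`` non-conserved alignment
    columns.  Infeasible constraint sets raise ``ValueError``.

    Ties in <E> are broken by larger minimum block length, then by
    lexicographically smaller crossover positions.
    """
    if n_crossovers < 1:
        raise ValueError("n_crossovers must be >= 1")
    L = parents.length_aa
    weights = disruption_weights(parents, contacts)
    total_c = sum(weights.values())

    # inside[a][b] = summed weight of contacts fully within columns [a, b] (1-based)
    # built incrementally: inside(a, b) = inside(a, b-1) + sum_{i >= a} c(i, b)
    by_j: dict[int, list[tuple[int, float]]] = {}
    for (i, j), c in weights.items():
        by_j.setdefault(j, []).append((i, c))
    inside = np.zeros((L + 2, L + 1))
    for a in range(1, L + 1):
        acc = 0.0
        for b in range(a, L + 1):
            for i, c in by_j.get(b, ()):
                if i >= a:
                    acc += c
            inside[a, b] = acc

    nonconserved = ~conserved_columns(parents)
    mut_prefix = np.concatenate([[0], np.cumsum(nonconserved)])

    def feasible(a: int, b: int) -> bool:
        if b - a + 1 < min_block_aa:
            return False
        return mut_prefix[b] - mut_prefix[a - 1] >= min_mutations_per_block

    B = n_crossovers + 1
    # dp[k][x]: up to n_best (score, crossovers) for [1, x] split into k blocks
    dp: list[dict[int, list[tuple[float, tuple[int, ...]]]]] = [dict() for _ in range(B + 1)]
    for x in range(1, L + 1):
        if feasible(1, x):
            dp[1][x] = [(inside[1, x], ())]
    for k in range(2, B + 1):
        for x in range(k, L + 1):
            cands: list[tuple[float, tuple[int, ...]]] = []
            for y, prev in dp[k - 1].items():
                if y >= x or not feasible(y + 1, x):
                    continue
                add = inside[y + 1, x]
                for score, xs in prev:
                    cands.append((score + add, xs + (y,)))
            if cands:
                cands.sort(key=lambda t: (-t[0], t[1]))
                dp[k][x] = cands[:n_best]

    finals = dp[B].get(L, [])
    if not finals:
        raise ValueError(
            f"no feasible partition: L_aa={L}, n_crossovers={n_crossovers}, "
            f"min_block_aa={min_block_aa}, min_mutations_per_block={min_mutations_per_block}"
        )
    ranked = []
    for score, xs in finals:
        part = BlockPartition(L, xs)
        ranked.append(RankedPartition(part, mean_E=total_c - score, inside_score=score))

    def sort_key(rp: RankedPartition):
        min_len = min(e - s + 1 for s, e in rp.partition.blocks)
        return (round(rp.mean_E, 12), -min_len, rp.partition.crossovers)

    ranked.sort(key=sort_key)
    return ranked[:n_best]


def partitions_table(
    ranked: Sequence[RankedPartition],
    parents: ParentSet,
    n_samples_m: int = 2000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Tabulate ranked partitions with <E>, <m> and per-block mutation counts."""
    nonconserved = ~conserved_columns(parents)
    rows = []
    for rp in ranked:
        m, _ = mean_library_m(rp.partition, parents, n_samples=n_samples_m, seed=seed)
        muts = [int(nonconserved[s - 1 : e].sum()) for s, e in rp.partition.blocks]
        rows.append(
            {
                "crossovers": ",".join(map(str, rp.partition.crossovers)),
                "mean_E": rp.mean_E,
                "mean_m": m,
                "block_mutations": ",".join(map(str, muts)),
                "min_block_aa": min(e - s + 1 for s, e in rp.partition.blocks),
            }
        )
    return pd.DataFrame(rows)
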