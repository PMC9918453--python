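"""Core data model for block-shuffled chimeric protein libraries.

A shuffling library is defined by a set of aligned parent proteins (here:
the six Staphylococcus aureus Spl serine proteases, or synthetic stand-ins),
a partition of the alignment into contiguous blocks, and chimera codes that
name, for every block, the parent the block was inherited from.  Parents
that are indistinguishable within a block (identical sequence over that
block) are collapsed into a merged label such as ``D/F``.

Coordinates are 1-based inclusive on the amino-acid alignment; nucleotide
coordinates of block *k* spanning residues ``[s, e]`` are ``[3(s-1)+1, 3e]``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

Level = Literal["aa", "nt"]

GAP_CHARS = set("-.")


def translate(nt: str) -> str:
    """Translate a coding nucleotide sequence under the standard code."""
    if len(nt) % 3:
        raise ValueError(f"nucleotide sequence length {len(nt)} is not a multiple of 3")
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class ParentSet:
    """Aligned parent proteins with their coding nucleotide sequences.

    Parameters
    ----------
    labels
        Unique short identifiers, e.g. ``("A", "B", "C", "D", "E", "F")``.
    aa_seqs
        Equal-length, gap-free amino-acid strings (one per parent).
    nt_seqs
        Coding sequences; each must translate exactly to its amino-acid
        sequence.
    """

    labels: tuple[str, ...]
    aa_seqs: tuple[str, ...]
    nt_seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.aa_seqs) == len(self.nt_seqs)):
            raise ValueError("labels, aa_seqs and nt_seqs must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("parent labels must be unique")
        if not self.labels:
            raise ValueError("at least one parent required")
        L = len(self.aa_seqs[0])
        if L < 2:
            raise ValueError("alignment length must be >= 2")
        for lab, aa, nt in zip(self.labels, self.aa_seqs, self.nt_seqs):
            if "/" in lab or "-" in lab:
                raise ValueError(f"parent label {lab!r} may not contain '/' or '-'")
            if len(aa) != L:
                raise ValueError(f"parent {lab}: alignment length mismatch")
            if GAP_CHARS & set(aa):
                raise ValueError(
                    f"parent {lab}: gapped alignments are not supported; "
                    "provide gap-free equal-length parents"
                )
            if len(nt) != 3 * L:
                raise ValueError(f"parent {lab}: nt length must be 3x aa length")
            if translate(nt) != aa:
                raise ValueError(f"parent {lab}: nt sequence does not translate to aa sequence")

    @property
    def n_parents(self) -> int:
        return len(self.labels)

    @property
    def length_aa(self) -> int:
        return len(self.aa_seqs[0])

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown parent label {label!r}") from None

    def aa(self, label: str) -> str:
        return self.aa_seqs[self.index(label)]

    def nt(self, label: str) -> str:
        return self.nt_seqs[self.index(label)]

    def block_seq(self, label: str, start_aa: int, end_aa: int, level: Level = "aa") -> str:
        """Sequence of one parent over residues [start_aa, end_aa], 1-based inclusive."""
        if level == "aa":
            return self.aa(label)[start_aa - 1 : end_aa]
        return self.nt(label)[3 * (start_aa - 1) : 3 * end_aa]

    @classmethod
    def from_fasta(cls, aa_fasta, nt_fasta) -> "ParentSet":
        """Load parents from a protein and a coding-sequence multi-FASTA (ids = labels)."""
        aa = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(aa_fasta), "fasta")}
        nt = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(nt_fasta), "fasta")}
        if set(aa) != set(nt):
            raise ValueError("aa and nt FASTA files must contain the same record ids")
        labels = tuple(aa)
        return cls(labels, tuple(aa[l] for l in labels), tuple(nt[l] for l in labels))

    def to_fasta(self, aa_path, nt_path) -> None:
        for path, seqs in ((aa_path, self.aa_seqs), (nt_path, self.nt_seqs)):
            with open(path, "w") as fh:
                for lab, s in zip(self.labels, seqs):
                    fh.write(f">{lab}\n{s}\n")


@dataclass(frozen=True)
class BlockPartition:
    """Crossover positions partitioning an alignment of length ``L_aa`` into blocks.

    A crossover at position ``x`` places a block boundary between residues
    ``x`` and ``x + 1``; ``n`` crossovers define ``n + 1`` blocks that tile
    ``[1, L_aa]`` exactly.  Blocks are numbered 1-based.
    """

    L_aa: int
    crossovers: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.L_aa < 2:
            raise ValueError("L_aa must be >= 2")
        xs = self.crossovers
        if any(not (1 <= x < self.L_aa) for x in xs):
            raise ValueError("crossovers must satisfy 1 <= x < L_aa")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("crossovers must be strictly increasing")

    @property
    def n_blocks(self) -> int:
        return len(self.crossovers) + 1

    @property
    def blocks(self) -> tuple[tuple[int, int], ...]:
        """1-based inclusive (start, end) per block."""
        bounds = (0,) + self.crossovers + (self.L_aa,)
        return tuple((a + 1, b) for a, b in zip(bounds, bounds[1:]))

    def block_of(self, pos: int) -> int:
        """1-based block number containing alignment column ``pos``."""
        if not 1 <= pos <= self.L_aa:
            raise ValueError(f"position {pos} outside [1, {self.L_aa}]")
        for k, (s, e) in enumerate(self.blocks, start=1):
            if s <= pos <= e:
                return k
        raise AssertionError("unreachable")

    def nt_blocks(self) -> tuple[tuple[int, int], ...]:
        return tuple((3 * (s - 1) + 1, 3 * e) for s, e in self.blocks)

    @classmethod
    def from_blocks(cls, blocks: Sequence[tuple[int, int]]) -> "BlockPartition":
        blocks = sorted(blocks)
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 != e1 + 1:
                raise ValueError("blocks must tile the alignment contiguously")
        if blocks[0][0] != 1:
            raise ValueError("first block must start at 1")
        return cls(L_aa=blocks[-1][1], crossovers=tuple(e for _, e in blocks[:-1]))

    @classmethod
    def from_tsv(cls, path) -> "BlockPartition":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("block_index")
        return cls.from_blocks(list(zip(df["start_aa"], df["end_aa"])))

    def to_tsv(self, path) -> None:
        rows = [
            {"block_index": k, "start_aa": s, "end_aa": e}
            for k, (s, e) in enumerate(self.blocks, start=1)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def check_compatible(self, parents: ParentSet) -> None:
        if self.L_aa != parents.length_aa:
            raise ValueError(
                f"partition length {self.L_aa} != parent alignment length {parents.length_aa}"
            )


def merged_label(labels: Iterable[str]) -> str:
    """Canonical rendering of a set of indistinguishable parents, e.g. ``D/F``."""
    return "/".join(sorted(set(labels)))


@dataclass(frozen=True)
class ChimeraCode:
    """Per-block parent labels of one chimera; labels may be merged (``D/F``)."""

    labels_per_block: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels_per_block:
            raise ValueError("a chimera code needs at least one block")

    @property
    def n_blocks(self) -> int:
        return len(self.labels_per_block)

    def render(self) -> str:
        """String form: concatenated for single-character labels, '-'-joined otherwise."""
        if all(len(l) == 1 for l in self.labels_per_block):
            return "".join(self.labels_per_block)
        return "-".join(self.labels_per_block)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "ChimeraCode":
        if "-" in text:
            return cls(tuple(text.split("-")))
        return cls(tuple(text))

    def members(self, block: int) -> tuple[str, ...]:
        """Parent labels named at 1-based ``block`` (splitting merged labels)."""
        return tuple(self.labels_per_block[block - 1].split("/"))


def equivalence_classes(
    parents: ParentSet, partition: BlockPartition, level: Level = "aa"
) -> list[list[tuple[str, ...]]]:
    """Group parents with byte-identical block sequences, per block.

    Returns one list of groups per block (block order); each group is a
    sorted tuple of parent labels, groups sorted by their first member.
    """
    partition.check_compatible(parents)
    out: list[list[tuple[str, ...]]] = []
    for s, e in partition.blocks:
        by_seq: dict[str, list[str]] = {}
        for lab in parents.labels:
            by_seq.setdefault(parents.block_seq(lab, s, e, level), []).append(lab)
        groups = sorted(tuple(sorted(g)) for g in by_seq.values())
        out.append(groups)
    return out


def class_label_maps(
    parents: ParentSet, partition: BlockPartition, level: Level = "aa"
) -> list[dict[str, str]]:
    """Per block, map each parent label to its merged equivalence-class label."""
    maps = []
    for groups in equivalence_classes(parents, partition, level):
        m: dict[str, str] = {}
        for g in groups:
            lab = merged_label(g)
            for member in g:
                m[member] = lab
        maps.append(m)
    return maps


def enumerate_diversity(
    parents: ParentSet, partition: BlockPartition, level: Level = "aa"
) -> int:
    """Number of distinct chimera sequences: product of per-block class counts.

    Blocks combine independently, so the count of distinct full-length
    chimeras is the product over blocks of the number of distinct block
    sequences among the parents.
    """
    return math.prod(len(g) for g in equivalence_classes(parents, partition, level))


def _resolve(parents: ParentSet, label: str) -> str:
    """A concrete parent label for a possibly merged label."""
    for member in label.split("/"):
        if member in parents.labels:
            return member
    raise KeyError(f"label {label!r} does not name any parent")


def assemble_chimera(
    parents: ParentSet,
    partition: BlockPartition,
    code: ChimeraCode,
    level: Level = "aa",
) -> str:
    """Concatenate the coded parents' block subsequences into a chimera sequence."""
    partition.check_compatible(parents)
    if code.n_blocks != partition.n_blocks:
        raise ValueError(
            f"code has {code.n_blocks} blocks, partition has {partition.n_blocks}"
        )
    parts = []
    for (s, e), lab in zip(partition.blocks, code.labels_per_block):
        parts.append(parents.block_seq(_resolve(parents, lab), s, e, level))
    return "".join(parts)


def canonicalize_code(
    parents: ParentSet,
    partition: BlockPartition,
    code: ChimeraCode,
    level: Level = "aa",
) -> ChimeraCode:
    """Replace every block label by its equivalence-class merged label."""
    maps = class_label_maps(parents, partition, level)
    labels = []
    for m, lab in zip(maps, code.labels_per_block):
        labels.append(m[_resolve(parents, lab)])
    return ChimeraCode(tuple(labels))


def validate_code(parents: ParentSet, partition: BlockPartition, code: ChimeraCode) -> None:
    """Check the merged-label invariant: merged parents must be identical in that block.

    Raises ``ValueError`` when a merged label names parents whose sequences
    differ over the block (at amino-acid level).
    """
    for k, ((s, e), lab) in enumerate(zip(partition.blocks, code.labels_per_block), start=1):
        members = lab.split("/")
        seqs = {parents.block_seq(_resolve(parents, m), s, e, "aa") for m in members}
        if len(seqs) > 1:
            raise ValueError(
                f"block {k}: merged label {lab!r} names parents with distinct block sequences"
            )


def all_codes(
    parents: ParentSet, partition: BlockPartition, level: Level = "aa"
) -> Iterable[ChimeraCode]:
    """Yield every distinct chimera code (one per equivalence-class combination)."""
    per_block = [
        [merged_label(g) for g in groups]
        for groups in equivalence_classes(parents, partition, level)
    ]
    for combo in itertools.product(*per_block):
        yield ChimeraCode(tuple(combo))
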