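"""Synthetic study generator: parents, shuffled libraries, concatemeric reads, selection.

Every input the analysis pipeline consumes can be produced here with known
ground truth: a set of aligned parent genes (emulating the six Spl
proteases, two of which are indistinguishable within designated blocks), a
biased barcoded chimera library with vector-background and
restriction-site-retaining contaminants, rolling-circle-style concatemeric
reads with nanopore-like substitution/indel noise, and multi-round
capture-based selection whose outcome is controlled by the parent identity
at one designated "determinant" block.

All randomness flows from one master seed through named substreams, so
every artefact is reproducible from ``(seed, parameters)`` alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import edlib
from scipy.optimize import brentq
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .library_model import (
    BlockPartition,
    ChimeraCode,
    ParentSet,
    assemble_chimera,
    canonicalize_code,
    class_label_maps,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"

#: Constant segment placed at the start of every repeat unit in a concatemeric
#: read; stands in for the display-anchor (aga2) gene segment used to locate
#: repeat boundaries.
DEFAULT_ANCHOR = "GCACTCGCTCGAGCGAGTCAATGACTCGTATTCACACGTGAGAATAGGTATTGCCGGCGA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


# one codon table shared by generation and validation
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for _codons in _CODONS_BY_AA.values():
    _codons.sort()


def default_partition(length_aa: int = 230, n_blocks: int = 6) -> BlockPartition:
    """Equal-size block partition (the study layout: six blocks)."""
    xs = tuple(round(k * length_aa / n_blocks) for k in range(1, n_blocks))
    return BlockPartition(length_aa, xs)


def _mutation_rate_for_identity(target: float) -> float:
    """Per-column mutation probability giving the requested mean pairwise identity.

    Two parents match at a column when neither mutated away from the shared
    ancestor, or both mutated to the same residue:
    identity = (1 - m)^2 + m^2 / 19.
    """
    f = lambda m: (1 - m) ** 2 + m**2 / 19.0 - target
    return brentq(f, 1e-9, 0.95)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def generate_parents(
    n_parents: int = 6,
    length_aa: int = 230,
    partition: BlockPartition | None = None,
    pairwise_identity_target: float = 0.7,
    identical_blocks: Mapping[tuple[str, str], Sequence[int]] | None = None,
    labels: Sequence[str] | None = None,
    seed: int = 0,
) -> ParentSet:
    """Generate aligned parents with controlled identity and identical-block structure.

    ``identical_blocks`` maps a pair of labels to 1-based block numbers over
    which the two parents are made byte-identical (amino acid and
    nucleotide); everywhere else all parents are guaranteed pairwise
    distinct within every block.  Coding sequences avoid the BsaI site
    (GGTCTC) on both strands, as a Golden-Gate-domesticated gene set would.
    """
    if not 0.0 < pairwise_identity_target < 1.0:
        raise ValueError("pairwise_identity_target must be in (0, 1)")
    if n_parents < 1:
        raise ValueError("n_parents must be >= 1")
    if partition is None:
        partition = default_partition(length_aa)
    if partition.L_aa != length_aa:
        raise ValueError("partition.L_aa must equal length_aa")
    if labels is None:
        if n_parents > 26:
            raise ValueError("provide explicit labels for more than 26 parents")
        labels = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:n_parents])
    labels = tuple(labels)
    identical_blocks = {
        _pair_key(*pair): tuple(blks) for pair, blks in (identical_blocks or {}).items()
    }
    for (a, b), blks in identical_blocks.items():
        if a not in labels or b not in labels:
            raise ValueError(f"identical_blocks pair ({a}, {b}) names unknown parents")
        if a == b:
            raise ValueError("identical_blocks pair must name two distinct parents")
        if any(not 1 <= k <= partition.n_blocks for k in blks):
            raise ValueError("identical_blocks block index out of range")

    rng = substream(seed, "parents")
    target = pairwise_identity_target

    def locked_partner(lab: str, block: int) -> str | None:
        for (a, b), blks in identical_blocks.items():
            if block in blks:
                if lab == a:
                    return b
                if lab == b:
                    return a
        return None

    for attempt in range(4):
        m = _mutation_rate_for_identity(target)
        ancestor = rng.choice(list(AMINO_ACIDS), size=length_aa)
        aa = {
            lab: [
                (
                    rng.choice([x for x in AMINO_ACIDS if x != anc])
                    if rng.random() < m
                    else anc
                )
                for anc in ancestor
            ]
            for lab in labels
        }
        # impose the identical-block structure (first label is the template)
        for (a, b), blks in identical_blocks.items():
            for k in blks:
                s, e = partition.blocks[k - 1]
                aa[b][s - 1 : e] = aa[a][s - 1 : e]
        # enforce pairwise distinctness in every non-designated block
        for _ in range(200):
            clash = None
            for k, (s, e) in enumerate(partition.blocks, start=1):
                for i, p in enumerate(labels):
                    for q in labels[i + 1 :]:
                        if k in identical_blocks.get(_pair_key(p, q), ()):
                            continue
                        if aa[p][s - 1 : e] == aa[q][s - 1 : e]:
                            clash = (k, s, e, q)
                            break
                    if clash:
                        break
                if clash:
                    break
            if clash is None:
                break
            k, s, e, q = clash
            col = int(rng.integers(s - 1, e))
            new = rng.choice([x for x in AMINO_ACIDS if x != aa[q][col]])
            aa[q][col] = new
            partner = locked_partner(q, k)
            if partner is not None:
                aa[partner][col] = new
        else:
            raise ValueError("could not satisfy distinctness constraints")

        realized = np.mean(
            [
                np.mean([a == b for a, b in zip(aa[p], aa[q])])
                for i, p in enumerate(labels)
                for q in labels[i + 1 :]
            ]
        ) if n_parents > 1 else 1.0
        # sampling noise and the distinctness constraints dominate tiny
        # alignments, so the +/- 5 point band is only meaningful (and only
        # enforced) for study-scale instances
        n_pairs = max(1, n_parents * (n_parents - 1) // 2)
        tol = max(0.05, 1.5 / np.sqrt(length_aa * n_pairs))
        if n_parents == 1 or length_aa < 30 or abs(realized - pairwise_identity_target) <= tol:
            break
        # recalibrate against the constraint-induced shift and retry
        target = max(0.02, min(0.98, target - (realized - pairwise_identity_target)))
    else:
        raise ValueError("could not reach the requested pairwise identity")

    # coding sequences: random synonymous codons, BsaI-domesticated
    codons = {
        lab: [str(rng.choice(_CODONS_BY_AA[x])) for x in aa[lab]] for lab in labels
    }

    def scrub(lab: str, protected: set[int]) -> None:
        for _ in range(300):
            s = "".join(codons[lab])
            hit = min(
                (p for p in (s.find(BSAI_SITE), s.find(BSAI_SITE_RC)) if p >= 0),
                default=-1,
            )
            if hit < 0:
                return
            span = [c for c in range(hit // 3, (hit + 5) // 3 + 1) if c < length_aa]
            editable = [
                c for c in span if c not in protected and len(_CODONS_BY_AA[aa[lab][c]]) > 1
            ]
            if not editable:
                raise ValueError("cannot domesticate sequence (restriction site locked)")
            c = int(rng.choice(editable))
            alternatives = [x for x in _CODONS_BY_AA[aa[lab][c]] if x != codons[lab][c]]
            codons[lab][c] = str(rng.choice(alternatives))

    copied_into: dict[str, set[int]] = {lab: set() for lab in labels}
    for (a, b), blks in identical_blocks.items():
        for k in blks:
            s, e = partition.blocks[k - 1]
            copied_into[b].update(range(s - 1, e))
    for lab in labels:
        if not copied_into[lab]:
            scrub(lab, set())
    for (a, b), blks in identical_blocks.items():
        for k in blks:
            s, e = partition.blocks[k - 1]
            codons[b][s - 1 : e] = codons[a][s - 1 : e]
    for lab in labels:
        if copied_into[lab]:
            scrub(lab, copied_into[lab])

    return ParentSet(
        labels,
        tuple("".join(aa[lab]) for lab in labels),
        tuple("".join(codons[lab]) for lab in labels),
    )


def default_study(seed: int = 0, length_aa: int = 230) -> tuple[ParentSet, BlockPartition]:
    """The default study conditions: six parents, six blocks, parents D and F
    identical within blocks 2, 3, 4 and 6."""
    partition = default_partition(length_aa, 6)
    parents = generate_parents(
        n_parents=6,
        length_aa=length_aa,
        partition=partition,
        pairwise_identity_target=0.7,
        identical_blocks={("D", "F"): (2, 3, 4, 6)},
        seed=seed,
    )
    return parents, partition


def control_sequence(parents: ParentSet, label: str = "B") -> str:
    """Unshuffled vector-background control: one parent gene carrying a single
    active-site-knockout-style codon substitution (kept in frame)."""
    nt = parents.nt(label)
    pos = int(round(0.68 * parents.length_aa)) - 1
    codon = "GCT" if parents.aa(label)[pos] != "A" else "TCT"
    return nt[: 3 * pos] + codon + nt[3 * pos + 3 :]


@dataclass(frozen=True)
class LibrarySpec:
    """Composition of a synthetic shuffled library.

    ``bias_weights`` gives, per block, non-negative sampling weights over
    parent labels; ``None`` draws a Dirichlet(2) weight vector per block
    from the seed, emulating the uncharacterised assembly bias of a real
    Golden Gate library.
    """

    partition: BlockPartition
    total_molecules: int = 1000
    bias_weights: tuple[Mapping[str, float], ...] | None = None
    background_fraction: float = 0.03
    site_retainer_fraction: float = 0.05
    barcode_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_molecules < 1:
            raise ValueError("total_molecules must be >= 1")
        for f in (self.background_fraction, self.site_retainer_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.background_fraction + self.site_retainer_fraction > 1.0:
            raise ValueError("background_fraction + site_retainer_fraction must be <= 1")
        if self.bias_weights is not None:
            if len(self.bias_weights) != self.partition.n_blocks:
                raise ValueError("bias_weights must provide one mapping per block")
            for w in self.bias_weights:
                if any(v < 0 for v in w.values()):
                    raise ValueError("bias weights must be non-negative")
                if not any(v > 0 for v in w.values()):
                    raise ValueError("bias weights must not all be zero within a block")


def sample_barcodes(
    n: int, length: int, rng: np.random.Generator, min_distance: int = 3
) -> list[str]:
    """Random barcodes with pairwise edit distance >= ``min_distance``."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 500 * n:
            raise ValueError(
                f"barcode space exhausted: cannot place {n} barcodes of length "
                f"{length} at pairwise distance >= {min_distance}"
            )
        cand = "".join(rng.choice(bases, size=length))
        ok = all(
            edlib.align(cand, b, mode="NW", k=min_distance - 1)["editDistance"] == -1
            for b in out
        )
        if ok:
            out.append(cand)
    return out


def generate_library(parents: ParentSet, spec: LibrarySpec) -> pd.DataFrame:
    """Sample a barcoded chimera library with known per-molecule ground truth.

    Returns a table with one row per molecule: ``molecule_id``, canonical
    truth ``code`` (merged labels where parents are indistinguishable at
    nucleotide level), the concrete sampled ``code_raw``, ``barcode``,
    ``nt_seq``, integer ``abundance`` (amplification-skew stand-in, drawn
    log-normally), and QC ground-truth flags ``is_background`` /
    ``has_site``.  Background molecules carry the unshuffled control
    sequence and no code.
    """
    spec.partition.check_compatible(parents)
    rng = substream(spec.seed, "library")
    labels = parents.labels
    B = spec.partition.n_blocks

    if spec.bias_weights is None:
        weights = [
            dict(zip(labels, rng.dirichlet(np.full(len(labels), 2.0)))) for _ in range(B)
        ]
    else:
        weights = [dict(w) for w in spec.bias_weights]
    probs = []
    for w in weights:
        unknown = set(w) - set(labels)
        if unknown:
            raise ValueError(f"bias weights name unknown parents: {sorted(unknown)}")
        vec = np.array([w.get(l, 0.0) for l in labels], dtype=float)
        probs.append(vec / vec.sum())

    n = spec.total_molecules
    n_bg = int(round(spec.background_fraction * n))
    n_site = int(round(spec.site_retainer_fraction * n))
    order = rng.permutation(n)
    bg_ids = set(order[:n_bg])
    site_ids = set(order[n_bg : n_bg + n_site])

    barcodes = sample_barcodes(n, spec.barcode_length, rng)
    control = control_sequence(parents)
    maps_nt = class_label_maps(parents, spec.partition, "nt")

    rows = []
    for i in range(n):
        mol = f"M{i:06d}"
        abundance = max(1, int(round(rng.lognormal(mean=2.0, sigma=0.8))))
        if i in bg_ids:
            rows.append(
                dict(
                    molecule_id=mol,
                    code=None,
                    code_raw=None,
                    barcode=barcodes[i],
                    nt_seq=control,
                    abundance=abundance,
                    is_background=True,
                    has_site=False,
                )
            )
            continue
        raw = tuple(labels[rng.choice(len(labels), p=p)] for p in probs)
        nt = assemble_chimera(parents, spec.partition, ChimeraCode(raw), "nt")
        has_site = i in site_ids
        if has_site:
            c = int(rng.integers(0, parents.length_aa - 1))
            nt = nt[: 3 * c] + BSAI_SITE + nt[3 * c + 6 :]
        canonical = ChimeraCode(tuple(m[l] for m, l in zip(maps_nt, raw)))
        rows.append(
            dict(
                molecule_id=mol,
                code=canonical.render(),
                code_raw=ChimeraCode(raw).render(),
                barcode=barcodes[i],
                nt_seq=nt,
                abundance=abundance,
                is_background=False,
                has_site=has_site,
            )
        )
    return pd.DataFrame(rows)


class FastqRead(NamedTuple):
    id: str
    seq: str
    qual: str  # Phred+33


def write_fastq(reads: Sequence[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def apply_errors(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> str:
    """Independent per-base substitutions, insertions (after a base) and deletions."""
    if not seq:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for k, b in enumerate(b"ACGT"):
        lut[b] = k
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if sub_rate > 0:
        mask = rng.random(arr.size) < sub_rate
        k = int(mask.sum())
        if k:
            arr[mask] = bases[(lut[arr[mask]] + 1 + rng.integers(0, 3, size=k)) % 4]
    if del_rate > 0:
        arr = arr[rng.random(arr.size) >= del_rate]
    if ins_rate > 0 and arr.size:
        pos = np.nonzero(rng.random(arr.size) < ins_rate)[0]
        if pos.size:
            arr = np.insert(arr, pos + 1, bases[rng.integers(0, 4, size=pos.size)])
    return arr.tobytes().decode()


def generate_reads(
    library: pd.DataFrame,
    anchor: str = DEFAULT_ANCHOR,
    copies: int | Callable[[np.random.Generator], int] | None = None,
    sub_rate: float = 0.05,
    ins_rate: float = 0.03,
    del_rate: float = 0.03,
    fraction_reverse: float = 0.5,
    reads_per_molecule: int = 1,
    seed: int = 0,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Concatemeric reads (anchor + barcode + gene, tandem-repeated) with noise.

    ``copies`` draws the tandem copy number per read: an integer for a
    constant, a callable ``rng -> int``, or ``None`` for the default
    shifted Poisson ``1 + Poisson(4)`` (mean 5).  Returns the reads and a
    truth table linking ``read_id`` to ``molecule_id``.
    """
    for name, r in (("sub_rate", sub_rate), ("ins_rate", ins_rate), ("del_rate", del_rate)):
        if not 0.0 <= r <= 0.2:
            raise ValueError(f"{name} must lie in [0, 0.2]")
    if callable(copies):
        draw = copies
    elif copies is None:
        draw = lambda rng: 1 + int(rng.poisson(4.0))
    else:
        if copies < 1:
            raise ValueError("copies must be >= 1")
        draw = lambda rng, c=int(copies): c
    rng = substream(seed, "reads")
    p_err = sub_rate + ins_rate + del_rate
    q = 40 if p_err == 0 else int(np.clip(round(-10 * np.log10(p_err)), 2, 40))
    qchar = chr(33 + q)

    reads: list[FastqRead] = []
    truth = []
    i = 0
    for row in library.itertuples(index=False):
        unit = anchor + row.barcode + row.nt_seq
        for _ in range(reads_per_molecule):
            n = draw(rng)
            if n < 1:
                raise ValueError("copies distribution produced a value < 1")
            seq = apply_errors(unit * n, sub_rate, ins_rate, del_rate, rng)
            strand = "-" if rng.random() < fraction_reverse else "+"
            if strand == "-":
                seq = revcomp(seq)
            rid = f"r{i:06d}"
            i += 1
            reads.append(FastqRead(rid, seq, qchar * len(seq)))
            truth.append(
                dict(read_id=rid, molecule_id=row.molecule_id, n_copies=n, strand=strand)
            )
    return reads, pd.DataFrame(truth)


SUBSTRATES = ("VWLY", "WELQ", "RWLL")
_COGNATE = {"VWLY": "A", "WELQ": "B", "RWLL": "F"}


def default_activity_table(
    labels: Sequence[str] = ("A", "B", "C", "D", "E", "F"),
    k_cognate: float = 0.5,
) -> dict[str, dict[str, float]]:
    """Per-substrate capture rate constants (1/h) keyed by determinant-block label.

    Each substrate is cleaved by exactly one cognate parent subdomain
    (substrate mnemonics follow the parents' preferred cleavage sites);
    every other label is inactive (k = 0) and is captured only through the
    nonspecific background term of the selection model.
    """
    return {
        sub: {lab: (k_cognate if lab == _COGNATE[sub] else 0.0) for lab in labels}
        for sub in SUBSTRATES
    }


@dataclass(frozen=True)
class SelectionSpec:
    """Phenomenological capture-selection model.

    A molecule whose determinant-block label has rate constant ``k`` is
    captured in one round with probability
    ``1 - (1 - background_capture) * exp(-k * t)``: single-hit kinetics
    plus a time-independent nonspecific background.  Survivors are
    resampled to ``capture_depth`` molecules per round.
    """

    determinant_block: int = 5
    activity_table: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_activity_table
    )
    incubation_time: float = 3.0  # hours
    rounds: int = 2
    capture_depth: int = 3000
    background_capture: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.incubation_time < 0:
            raise ValueError("incubation_time must be >= 0")
        if not 0.0 <= self.background_capture < 1.0:
            raise ValueError("background_capture must lie in [0, 1)")
        for sub, table in self.activity_table.items():
            if any(k < 0 for k in table.values()):
                raise ValueError(f"negative rate constant in activity table for {sub}")


def _capture_probability(k: float, t: float, p_bg: float) -> float:
    return 1.0 - (1.0 - p_bg) * np.exp(-k * t)


def simulate_selection(
    library: pd.DataFrame, spec: SelectionSpec, substrate: str
) -> pd.DataFrame:
    """Simulate ``spec.rounds`` rounds of capture selection with one substrate.

    Returns a long table (round, molecule_id, code, count, frequency);
    round 0 is the input population (library abundances).  The rate
    constant of a molecule is looked up by its concrete parent label at the
    determinant block; background molecules are inactive (k = 0).
    """
    if substrate not in spec.activity_table:
        raise ValueError(f"no activity table for substrate {substrate!r}")
    table = spec.activity_table[substrate]
    rng = substream(spec.seed, f"selection-{substrate}")
    b = spec.determinant_block

    ks = []
    for row in library.itertuples(index=False):
        if not isinstance(row.code_raw, str):  # background molecules carry no code
            ks.append(0.0)
            continue
        label = ChimeraCode.parse(row.code_raw).labels_per_block[b - 1]
        members = label.split("/")
        vals = {table.get(m) for m in members}
        if None in vals:
            raise ValueError(f"activity table lacks an entry for label {label!r}")
        if len(vals) > 1:
            raise ValueError(f"merged label {label!r} has conflicting rate constants")
        ks.append(vals.pop())
    ks = np.array(ks, dtype=float)
    p = _capture_probability(ks, spec.incubation_time, spec.background_capture)

    counts = library["abundance"].to_numpy(dtype=np.int64)
    out = []

    def record(rnd: int, cnt: np.ndarray) -> None:
        total = cnt.sum()
        keep = cnt > 0
        out.append(
            pd.DataFrame(
                {
                    "round": rnd,
                    "molecule_id": library["molecule_id"].to_numpy()[keep],
                    "code": library["code"].to_numpy()[keep],
                    "count": cnt[keep],
                    "frequency": cnt[keep] / total,
                }
            )
        )

    record(0, counts)
    for rnd in range(1, spec.rounds + 1):
        survivors = rng.binomial(counts, p)
        total = survivors.sum()
        if total == 0:
            raise RuntimeError(f"population extinct in selection round {rnd}")
        counts = rng.multinomial(spec.capture_depth, survivors / total)
        record(rnd, counts)
    return pd.concat(out, ignore_index=True)


def synthetic_structure(
    length: int, seed: int = 0, bond: float = 3.8, radius: float | None = None
) -> dict[int, np.ndarray]:
    """Compact confined random-walk fold: one pseudo-atom per residue.

    Stands in for a real crystal structure when exercising contact-map
    construction and crossover optimisation; with a single point per
    residue a contact cutoff around 8 angstroms approximates heavy-atom
    contacts at 4.5.
    """
    rng = substream(seed, "structure")
    if radius is None:
        radius = bond * max(2.0, 0.8 * length ** (1 / 3) * 2.0)
    pos = np.zeros(3)
    coords = {1: pos.copy()}
    for i in range(2, length + 1):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= bond / np.linalg.norm(step)
            cand = pos + step
            if np.linalg.norm(cand) <= radius:
                pos = cand
                break
        coords[i] = pos.copy()
    return {i: c[None, :] for i, c in coords.items()}
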