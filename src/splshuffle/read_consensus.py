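"""Rolling-circle concatemer consensus calling.

Long reads of circularised, rolling-circle-amplified molecules contain the
repeat unit (anchor + barcode + gene) in tandem.  The constant anchor
sequence is located on the read by tolerant infix alignment; the segments
between anchor hits (plus full-length flanking units) are the tandem
copies of the barcode + gene unit.  Reads providing fewer copies than the
configured minimum (default 3) or mutually inconsistent segment lengths
are rejected.  Accepted segments are collapsed into a consensus by
combining two candidate callers — star-alignment majority voting (seeded
from each segment) and an iterated partial-order-graph consensus — with a
greedy single-edit refinement and a difference-wise merge, all scored by
the summed edit distance of the candidate to the segments.

Mean read quality is computed on the error-probability scale (mean of
``10^(-Q/10)``, converted back to Phred), the convention of common
long-read filtering tools; an arithmetic mean of Phred scores would be
systematically higher.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import edlib

from .poa import poa_consensus
from .synthetic_data import FastqRead, revcomp


def read_fastq(path) -> list[FastqRead]:
    """Plain or gzipped FASTQ; malformed records are reported with their id."""
    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        lines = [l.rstrip("\n") for l in fh]
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for k in range(0, len(lines), 4):
        head, seq, plus, qual = lines[k : k + 4]
        rid = head[1:].split()[0] if head.startswith("@") else head
        if not head.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record {rid!r}")
        reads.append(FastqRead(rid, seq.upper(), qual))
    return reads


def mean_quality(qual: str) -> float:
    """Phred-scale mean computed via mean error probability."""
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33.0
    p = np.power(10.0, -q / 10.0)
    return float(-10.0 * np.log10(p.mean()))


def filter_reads(
    reads: Iterable[FastqRead],
    min_mean_quality: float = 9.0,
    min_length: int = 3000,
) -> list[FastqRead]:
    """Retain reads with mean quality >= threshold and length >= min_length."""
    out = []
    for r in reads:
        if len(r.seq) >= min_length and mean_quality(r.qual) >= min_mean_quality:
            out.append(r)
    return out


@dataclass(frozen=True)
class Segmentation:
    accepted: bool
    segments: tuple[str, ...]
    strand: str
    n_anchors: int
    reason: str | None = None


def _find_anchor_hits(seq: str, anchor: str, max_dist: int) -> list[tuple[int, int, int]]:
    """All non-overlapping anchor occurrences as (start, end_exclusive, distance).

    Iterative best-hit masking: repeatedly take the best infix alignment of
    the anchor and blank it out until no hit within ``max_dist`` remains.
    """
    hits = []
    work = seq
    for _ in range(1 + len(seq) // max(1, len(anchor) // 2)):
        res = edlib.align(anchor, work, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            break
        s, e = res["locations"][0]
        e += 1
        hits.append((s, e, res["editDistance"]))
        work = work[:s] + "#" * (e - s) + work[e:]
    hits.sort()
    return hits


def segment_by_anchor(
    seq: str,
    anchor: str,
    min_copies: int = 3,
    max_anchor_divergence: float = 0.3,
    length_tolerance: float = 0.25,
) -> Segmentation:
    """Split a concatemeric read into repeat-unit segments at anchor hits.

    The strand with more anchor hits (ties: smaller total edit distance,
    then forward) is used; on the minus strand the read is
    reverse-complemented first.  Segments are the sequences between
    consecutive anchor hits; a leading or trailing flank is additionally
    counted as a copy when its length matches the median inter-anchor
    segment within ``length_tolerance`` (a concatemer of N exact units
    beginning with the anchor yields N - 1 inter-anchor segments plus one
    full trailing unit).  Rejection (too few copies, inconsistent segment
    lengths, no anchor) is a tagged outcome, not an error.
    """
    if len(anchor) >= len(seq):
        return Segmentation(False, (), "+", 0, "read shorter than anchor")
    max_dist = int(max_anchor_divergence * len(anchor))
    fwd = _find_anchor_hits(seq, anchor, max_dist)
    rc = revcomp(seq)
    rev = _find_anchor_hits(rc, anchor, max_dist)
    f_score = (len(fwd), -sum(h[2] for h in fwd))
    r_score = (len(rev), -sum(h[2] for h in rev))
    if r_score > f_score:
        strand, hits, oriented = "-", rev, rc
    else:
        strand, hits, oriented = "+", fwd, seq
    if not hits:
        return Segmentation(False, (), strand, 0, "no anchor found")
    inner = [
        oriented[hits[k][1] : hits[k + 1][0]] for k in range(len(hits) - 1)
    ]
    inner = [s for s in inner if s]
    if not inner:
        return Segmentation(False, (), strand, len(hits), "insufficient copies")
    med = median(len(s) for s in inner)
    if any(abs(len(s) - med) > length_tolerance * med for s in inner):
        return Segmentation(
            False, tuple(inner), strand, len(hits), "inconsistent segment lengths"
        )
    segments = list(inner)
    for flank in (oriented[hits[-1][1] :], oriented[: hits[0][0]]):
        if flank and abs(len(flank) - med) <= length_tolerance * med:
            segments.append(flank)
    if len(segments) < min_copies:
        return Segmentation(False, tuple(segments), strand, len(hits), "insufficient copies")
    return Segmentation(True, tuple(segments), strand, len(hits))


@dataclass(frozen=True)
class ConsensusRecord:
    sequence: str
    copy_number: int
    read_id: str
    mean_segment_identity: float
    strand: str
    length_consistent: bool


def _collect_votes(segments: Sequence[str], template: str):
    """Align every segment to the template; per-column base/gap/insertion votes."""
    L = len(template)
    base: list[dict[str, int]] = [dict() for _ in range(L)]
    dels = np.zeros(L, dtype=int)
    ins: list[dict[str, int]] = [dict() for _ in range(L + 1)]
    for seg in segments:
        if seg == template:
            for k, b in enumerate(template):
                base[k][b] = base[k].get(b, 0) + 1
            continue
        res = edlib.align(seg, template, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, seg, template)
        pos = 0
        pending = ""
        for qb, tb in zip(nice["query_aligned"], nice["target_aligned"]):
            if tb == "-":
                if qb != "-":
                    pending += qb
                continue
            if pending:
                ins[pos][pending] = ins[pos].get(pending, 0) + 1
                pending = ""
            if qb == "-":
                dels[pos] += 1
            else:
                base[pos][qb] = base[pos].get(qb, 0) + 1
            pos += 1
        if pending:
            ins[pos][pending] = ins[pos].get(pending, 0) + 1
    return base, dels, ins


def _vote_consensus(segments: Sequence[str], template: str) -> str:
    """Star-alignment majority vote against one template.

    Per template column the majority base wins, ties favouring the
    template's base; columns deleted in more than half the segments are
    dropped; insertions between columns need strict majority support.
    """
    n = len(segments)
    base, dels, ins = _collect_votes(segments, template)
    half = n / 2.0
    out = []
    L = len(template)
    for k in range(L + 1):
        if ins[k] and sum(ins[k].values()) > half:
            out.append(max(ins[k].items(), key=lambda kv: (kv[1], kv[0]))[0])
        if k == L:
            break
        if dels[k] > half:
            continue
        votes = base[k]
        if not votes:
            continue
        best = max(votes.values())
        winners = sorted(b for b, v in votes.items() if v == best)
        out.append(template[k] if template[k] in winners else winners[0])
    return "".join(out)


def _distances(candidate: str, segments: Sequence[str], bounds=None) -> list[int]:
    """Edit distance of the candidate to every segment (k-bounded when possible)."""
    out = []
    for i, s in enumerate(segments):
        k = -1 if bounds is None else bounds[i] + 1
        d = edlib.align(candidate, s, mode="NW", k=k)["editDistance"]
        if d < 0:
            d = bounds[i] + 2
        out.append(d)
    return out


def _steiner_star(segments: Sequence[str]) -> str:
    """Best star-vote consensus under the total-edit-distance objective."""
    cands = {_vote_consensus(segments, t) for t in segments}
    cands = {c for c in cands if c} or set(segments)
    best = min(cands, key=lambda c: sum(_distances(c, segments)))
    best_d = sum(_distances(best, segments))
    while True:
        nxt = _vote_consensus(segments, best)
        if not nxt:
            break
        nd = sum(_distances(nxt, segments))
        if nd < best_d:
            best, best_d = nxt, nd
        else:
            break
    return best


def _local_fix(candidate: str, segments: Sequence[str], max_rounds: int = 80) -> str:
    """Greedy single-edit refinement of a consensus candidate.

    Candidate edits are taken from weak-majority columns of the star
    alignment (near-tied substitutions, minority deletions, sub-majority
    insertions); an edit is kept when it lowers the summed edit distance
    to the segments.  A single edit changes each per-segment distance by
    at most one, so evaluations use k-bounded alignments.
    """
    n = len(segments)
    cur = candidate
    ds = _distances(cur, segments)
    cur_d = sum(ds)
    for _ in range(max_rounds):
        base, dels, ins = _collect_votes(segments, cur)
        cands = []
        for k in range(len(cur)):
            if dels[k] > 0 and (max(base[k].values(), default=0) - dels[k]) <= 1:
                cands.append(("del", k, None))
            if len(base[k]) > 1:
                vs = sorted(base[k].items(), key=lambda kv: -kv[1])
                if vs[0][1] - vs[1][1] <= 1:
                    cands.append(("sub", k, vs[1][0] if cur[k] == vs[0][0] else vs[0][0]))
        for k in range(len(cur) + 1):
            if ins[k] and 2 <= sum(ins[k].values()) <= n / 2 + 1:
                s = max(ins[k].items(), key=lambda kv: kv[1])[0]
                cands.append(("ins", k, s))
        best = None
        best_d = cur_d
        for op, k, arg in cands:
            if op == "del":
                cc = cur[:k] + cur[k + 1 :]
            elif op == "sub":
                cc = cur[:k] + arg + cur[k + 1 :]
            else:
                cc = cur[:k] + arg + cur[k:]
            nds = _distances(cc, segments, ds)
            t = sum(nds)
            if t < best_d:
                best_d, best = t, (cc, nds)
        if best is None:
            break
        cur, ds = best
        cur_d = best_d
    return cur


def _arbitrate(c1: str, c2: str, segments: Sequence[str]) -> str:
    """Merge two consensus candidates difference-by-difference.

    The candidates are aligned; each run of disagreeing columns is flipped
    to the alternative version when that lowers the summed edit distance
    to the segments (greedy, left to right).
    """
    if c1 == c2 or not c2:
        return c1
    if not c1:
        return c2
    res = edlib.align(c1, c2, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, c1, c2)
    a, b = list(nice["query_aligned"]), list(nice["target_aligned"])
    diffs = []
    i = 0
    while i < len(a):
        if a[i] != b[i]:
            j = i
            while j < len(a) and a[j] != b[j]:
                j += 1
            diffs.append((i, j))
            i = j
        else:
            i += 1
    cur = a
    seq = "".join(c for c in cur if c != "-")
    ds = _distances(seq, segments)
    cur_d = sum(ds)
    for i, j in diffs:
        trial = cur[:i] + b[i:j] + cur[j:]
        t = "".join(c for c in trial if c != "-")
        nds = _distances(t, segments, ds)
        td = sum(nds)
        if td < cur_d:
            cur, cur_d, ds = trial, td, nds
    return "".join(c for c in cur if c != "-")


def consensus_call(
    segments: Sequence[str],
    read_id: str = "",
    strand: str = "+",
    min_copies: int = 3,
) -> ConsensusRecord:
    """Consensus of the tandem repeat segments of one concatemeric read.

    Two candidate consensi are produced — a star-alignment majority vote
    seeded from each segment (per column the majority base wins, ties
    favouring the template's base; majority-deleted columns dropped;
    insertions need majority support) and an iterated partial-order-graph
    consensus — then refined by greedy single-edit search and merged,
    always scored by the summed edit distance of the candidate to all
    segments (the star/Steiner objective).  Identical segments reproduce
    the unit exactly.
    """
    if len(segments) < min_copies:
        raise ValueError(f"need >= {min_copies} segments, got {len(segments)}")
    n = len(segments)
    star = _local_fix(_steiner_star(segments), segments)
    if all(s == segments[0] for s in segments):
        final = segments[0]
    else:
        poa = _local_fix(poa_consensus(list(segments)), segments)
        final = _arbitrate(star, poa, segments)

    identities = [
        1.0 - d / max(len(final), len(s))
        for d, s in zip(_distances(final, segments), segments)
    ]
    med_len = median(len(s) for s in segments)
    return ConsensusRecord(
        sequence=final,
        copy_number=n,
        read_id=read_id,
        mean_segment_identity=float(np.mean(identities)),
        strand=strand,
        length_consistent=abs(len(final) - med_len) <= 0.2 * med_len,
    )


def consensus_pipeline(
    reads: Iterable[FastqRead],
    anchor: str,
    min_copies: int = 3,
    min_mean_quality: float = 9.0,
    min_length: int = 3000,
    max_anchor_divergence: float = 0.3,
) -> tuple[list[ConsensusRecord], pd.DataFrame]:
    """Filter reads, segment at the anchor and call consensus per read.

    Returns the accepted consensus records and a sidecar table with one row
    per input read (read_id, outcome, copy_number, strand, reason).
    """
    records: list[ConsensusRecord] = []
    side = []
    for r in reads:
        if len(r.seq) < min_length or mean_quality(r.qual) < min_mean_quality:
            side.append(dict(read_id=r.id, outcome="filtered", copy_number=0,
                             strand=".", reason="quality/length filter"))
            continue
        seg = segment_by_anchor(r.seq, anchor, min_copies, max_anchor_divergence)
        if not seg.accepted:
            side.append(dict(read_id=r.id, outcome="rejected", copy_number=len(seg.segments),
                             strand=seg.strand, reason=seg.reason))
            continue
        rec = consensus_call(seg.segments, read_id=r.id, strand=seg.strand,
                             min_copies=min_copies)
        records.append(rec)
        side.append(dict(read_id=r.id, outcome="consensus", copy_number=rec.copy_number,
                         strand=rec.strand, reason=None))
    return records, pd.DataFrame(side)


def write_consensus_fasta(records: Sequence[ConsensusRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.read_id} copies={rec.copy_number} strand={rec.strand}\n")
            fh.write(rec.sequence + "\n")
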