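"""Partial-order alignment graph for tandem-repeat consensus.

Sequences are aligned one by one to a growing directed acyclic graph
seeded with a zero-weight linear scaffold (the scaffold orders columns but
casts no votes).  Matches and mismatches vote on existing nodes, deletions
cast gap votes, and insertions create new nodes that later sequences can
traverse at no cost, so support for a base missing from the scaffold
accumulates on a single node instead of scattering across alignment
junctions.  The consensus is the heaviest path through the graph by
edge-traversal counts; run-length voting is pooled over maximal
same-base runs, where unit-cost alignments place gaps ambiguously.

Alignment uses unit costs (match 0, mismatch/indel 1).  The inner dynamic
programming row is vectorised with the standard prefix-minimum trick for
the within-row insertion recurrence.
"""

from __future__ import annotations

import numpy as np
import edlib


class POAGraph:
    """Growing partial-order graph; see module docstring."""

    def __init__(self, scaffold: str):
        if not scaffold:
            raise ValueError("scaffold must be non-empty")
        self.bases = list(scaffold)
        self.votes: list[dict[str, int]] = [dict() for _ in scaffold]
        self.preds: list[list[int]] = [[] if i == 0 else [i - 1] for i in range(len(scaffold))]
        self.has_succ = [True] * (len(scaffold) - 1) + [False]
        self.order = list(range(len(scaffold)))
        self.n_seqs = 0
        self.edges: dict[tuple[int, int], int] = {}
        self.starts: dict[int, int] = {}

    def _new_node(self, base: str, pred: int | None, order_pos: int) -> int:
        nid = len(self.bases)
        self.bases.append(base)
        self.votes.append({base: 1})
        self.preds.append([pred] if pred is not None else [])
        self.has_succ.append(False)
        if pred is not None:
            self.has_succ[pred] = True
        self.order.insert(order_pos, nid)
        return nid

    def align_add(self, q: str) -> None:
        """Align one sequence to the graph and merge it in."""
        if not q:
            raise ValueError("cannot align an empty sequence")
        L = len(q)
        order = list(self.order)
        M = len(order)
        pos_of = {nid: t for t, nid in enumerate(order)}
        qarr = np.frombuffer(q.encode(), np.uint8)
        D = np.empty((M + 1, L + 1), dtype=np.int32)
        ar = np.arange(L + 1, dtype=np.int32)
        D[0] = ar  # virtual start: leading insertions
        pred_rows: list[list[int]] = []
        for t, nid in enumerate(order):
            ps = self.preds[nid]
            rows = [pos_of[p] + 1 for p in ps] if ps else [0]
            pred_rows.append(rows)
            A = D[rows[0]] if len(rows) == 1 else np.minimum.reduce([D[r] for r in rows])
            cost = (ord(self.bases[nid]) != qarr).astype(np.int32)
            tmp = np.empty(L + 1, dtype=np.int32)
            tmp[0] = A[0] + 1
            np.minimum(A[1:] + 1, A[:-1] + cost, out=tmp[1:])
            # within-row: D[t][i] = min(tmp[i], D[t][i-1] + 1)
            u = np.minimum.accumulate(tmp - ar)
            D[t + 1] = u + ar

        ends = [t for t, nid in enumerate(order) if not self.has_succ[nid]]
        t_end = min(ends, key=lambda t: int(D[t + 1][L]))

        # backtrack (events collected right-to-left, preferring match > del > ins)
        events: list[tuple[str, int | None, str | None]] = []
        t, i = t_end, L
        while True:
            if t < 0:
                while i > 0:
                    events.append(("ins", None, q[i - 1]))
                    i -= 1
                break
            row, nid, rows = t + 1, order[t], pred_rows[t]
            val = int(D[row][i])
            moved = False
            if i > 0:
                cost = 0 if self.bases[nid] == q[i - 1] else 1
                for r in rows:
                    if val == int(D[r][i - 1]) + cost:
                        events.append(("sub", nid, q[i - 1]))
                        t, i = r - 1, i - 1
                        moved = True
                        break
            if not moved:
                for r in rows:
                    if val == int(D[r][i]) + 1:
                        events.append(("del", nid, None))
                        t = r - 1
                        moved = True
                        break
            if not moved:
                if i > 0 and val == int(D[row][i - 1]) + 1:
                    events.append(("ins", nid, q[i - 1]))
                    i -= 1
                else:  # pragma: no cover - DP/backtrack invariant
                    raise AssertionError("backtrack failed")

        self.n_seqs += 1
        events.reverse()  # forward order along the sequence

        for ev, nid, ch in events:
            if ev == "sub":
                self.votes[nid][ch] = self.votes[nid].get(ch, 0) + 1  # type: ignore[index]
            elif ev == "del":
                self.votes[nid]["-"] = self.votes[nid].get("-", 0) + 1  # type: ignore[index]

        # create insert nodes in forward order and record the traversal path
        path: list[int] = []
        chain_tail: int | None = None
        for ev, nid, ch in events:
            if ev == "sub":
                path.append(nid)  # type: ignore[arg-type]
                chain_tail = None
            elif ev == "ins":
                pred = chain_tail if chain_tail is not None else (path[-1] if path else None)
                order_pos = (self.order.index(pred) + 1) if pred is not None else 0
                new = self._new_node(ch, pred, order_pos)  # type: ignore[arg-type]
                path.append(new)
                chain_tail = new
            else:
                chain_tail = None

        if path:
            self.starts[path[0]] = self.starts.get(path[0], 0) + 1
        for a, b in zip(path, path[1:]):
            if a not in self.preds[b]:
                self.preds[b].append(a)
                self.has_succ[a] = True
            self.edges[(a, b)] = self.edges.get((a, b), 0) + 1

    def consensus(self) -> str:
        """Heaviest-path consensus with run-pooled length voting."""
        score: dict[int, float] = {}
        back: dict[int, int | None] = {}
        best_end: int | None = None
        for nid in self.order:
            sc = float(self.starts.get(nid, 0))
            bk: int | None = None
            for p in self.preds[nid]:
                cand = score.get(p, 0.0) + self.edges.get((p, nid), 0)
                if cand > sc:
                    sc, bk = cand, p
            score[nid] = sc
            back[nid] = bk
            if best_end is None or sc > score[best_end]:
                best_end = nid
        path: list[int] = []
        nid = best_end
        while nid is not None:
            path.append(nid)
            nid = back[nid]
        path.reverse()

        n = self.n_seqs
        items: list[tuple[str, int]] = []  # (majority base, base-vote count)
        for nid in path:
            v = dict(self.votes[nid])
            v.pop("-", None)
            if not v:
                continue
            best = max(v.values())
            base = sorted(b for b, c in v.items() if c == best)[0]
            items.append((base, sum(v.values())))
        out: list[str] = []
        i = 0
        while i < len(items):
            j, B = i, 0
            base = items[i][0]
            while j < len(items) and items[j][0] == base:
                B += items[j][1]
                j += 1
            out.append(base * int(round(B / n)) if n else base * (j - i))
            i = j
        return "".join(out)


def poa_consensus(segments: list[str], n_iter: int = 2) -> str:
    """Iterated POA consensus of tandem-repeat segments.

    The scaffold of the first iteration is the medoid segment (minimum
    summed edit distance to the rest); subsequent iterations re-seed the
    graph with the previous consensus until it is stable.
    """
    segs = list(segments)
    if not segs:
        raise ValueError("no segments")
    if len(segs) == 1:
        return segs[0]
    n = len(segs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = edlib.align(segs[i], segs[j], mode="NW")["editDistance"]
    order = list(np.argsort(D.sum(1), kind="stable"))
    segs = [segs[k] for k in order]
    c = segs[0]
    for _ in range(max(1, n_iter)):
        g = POAGraph(c)
        for s in segs:
            g.align_add(s)
        c2 = g.consensus()
        if c2 == c or not c2:
            break
        c = c2
    return c
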