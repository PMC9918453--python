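# Methods

This note documents the models, algorithms and design choices behind
`splshuffle`: what each component computes, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the numerical
conventions needed to reproduce results exactly.

## Disruption scoring and crossover design

A chimera inherits each alignment block from one parent. Its disruption `E`
counts residue–residue contacts `(i, j)` whose amino-acid pair in the chimera
occurs in no single parent. Contacts come from structure coordinates: residues
are in contact when any two heavy atoms lie within a cutoff (default 4.5 Å, a
common convention for this scoring; configurable and recorded in output) and
the sequence separation `j − i` is at least `min_separation` (default 2).
Structure residue numbers map to alignment columns through an explicit
table — no automatic renumbering, because structure numbering offsets are
error-prone to guess.

The library mean over uniform, independent per-block parent choices is exact
and partition-independent per contact:

    c(i, j) = (1 / K²) · #{(p, q) : (aa_p[i], aa_q[j]) in no parent}
    ⟨E⟩     = Σ over contacts with block(i) ≠ block(j) of c(i, j)

Ordered pairs include `p = q` (contributing 0), which makes `⟨E⟩` exactly the
expectation of `E` over the uniform chimera distribution; this is verified
against exhaustive per-chimera enumeration in the tests.

Minimising `⟨E⟩` over crossover placements is equivalent to maximising the
summed `c` of contacts kept inside blocks. A dynamic program over
(block count, rightmost block end) solves this exactly under two constraints:
minimum block length in residues, and a minimum number of non-conserved
alignment columns per block ("mutations per block", the only parent-intrinsic,
partition-local reading of that constraint). Each DP state retains the best
`n_best` scores so a ranked list is returned; ties in `⟨E⟩` break toward the
larger minimum block length, then lexicographically smaller crossovers.
`⟨m⟩` — the expected amino-acid distance of a random chimera to its closest
parent — is computed exhaustively when the library's diversity is ≤ 10⁴
(weighted enumeration over equivalence classes) and otherwise by Monte Carlo
with a reported standard error.

## Combinatorial accounting

Parents with byte-identical sequences over a block form an equivalence class;
the canonical merged label joins members with `/` (e.g. `D/F`). Because blocks
combine independently, the number of distinct chimeras is the product of
per-block class counts; tests verify this against exhaustive assembly and
deduplication on small instances. Both amino-acid and nucleotide levels are
exposed (nucleotide-level classes refine amino-acid-level ones); the default
study's designated identical blocks are copied at both levels, so the two
agree there.

## Read model and consensus

A simulated read is `N` tandem copies of (anchor + barcode + gene), with `N`
drawn from a shifted Poisson (`1 + Poisson(4)`, mean 5) unless specified, and
independent per-base substitutions/insertions/deletions (defaults 5%/3%/3%,
an R9-era nanopore order of magnitude; configurable and recorded). Phred
qualities are constant per read, consistent with the total error rate. Half
the reads are reverse-complemented.

Filtering retains reads with length ≥ 3000 and mean quality ≥ 9, both
inclusive bounds; the mean is computed on the error-probability scale and
converted back to Phred, matching common long-read tools (an arithmetic mean
of Phred scores would be higher, so the convention matters at the boundary).

Segmentation finds anchor occurrences on both strands by iterative best-hit
infix alignment (edit distance ≤ 30% of anchor length), orients the read to
the strand with more hits, and takes inter-anchor intervals as repeat-unit
segments. A leading or trailing flank counts as an additional copy when its
length matches the median inter-anchor segment within 25%: an exact `N`-unit
concatemer beginning with the anchor then yields `N` copies, so "minimum copy
number 3" means three repeat units, not three internal gaps. Reads with fewer
than `min_copies` segments or mutually inconsistent segment lengths (>25%
from their median) are rejected with a tagged reason.

Consensus calling is the package's most engineered component. A plain star
alignment to the medoid segment — per-column majority with medoid
tie-breaks — was measured at only ~96–98% consensus identity at 4–5 copies
under the default noise, because template errors perturb the pairwise
alignments in a self-reinforcing way. The final design combines:

1. **star-vote candidates**: the majority-vote consensus seeded from *each*
   segment as template (majority base per column, ties toward the template;
   columns deleted in a strict majority of segments dropped; insertions kept
   only with strict majority support),
2. a **partial-order-graph consensus** (`poa.py`): segments are aligned one by
   one to a DAG seeded with a zero-weight scaffold; insertions become graph
   nodes that later segments traverse at no cost, so support accumulates
   instead of scattering across junctions; the consensus is the heaviest path
   by edge-traversal counts with run-pooled length voting in homopolymers;
   the graph is re-seeded with its own consensus until stable,
3. **greedy single-edit refinement** of both candidates and a
   **difference-wise merge**, all scored by the summed edit distance of the
   candidate to the segments (the Steiner objective; a single edit changes
   each per-segment distance by at most one, so evaluations use k-bounded
   alignments).

Measured on 1 kb units at the default noise with 5 copies, ≥ 99%
consensus-to-truth identity is reached in ~97% of molecules; accuracy is
monotone in copy number, and identical segments reproduce the unit exactly.

## Block calling, demultiplexing, QC

Block references are the parents' nucleotide block sequences, one per
equivalence class, so the caller cannot output a single label where parents
are indistinguishable. Each reference is locally aligned to the consensus
with affine gaps (match +2, mismatch −3, open −5, extend −2 — BLAST-like
nucleotide scores); the best-scoring class wins, ties across distinct
references leave the block unresolved (logged with both candidates), and an
assignment requires the aligned reference fraction to exceed 0.90 (strictly —
"more than 90%"). A full code exists only when every block is assigned.

Demultiplexing infix-aligns every barcode against a window at the consensus
5′ end (the barcode sits between anchor and gene; the anchor is removed
during segmentation); the nearest barcode within edit distance 2 wins and
ties are unassigned. Barcodes are generated with pairwise edit distance ≥ 3,
so single errors decode uniquely.

QC flags: *background* when the unshuffled control gene (the inactive
single-codon-knockout control) matches the consensus at ≥ 98% identity — the
control is matched as an infix because the consensus retains the barcode,
which the control does not contain and which would otherwise consume ~1.4% of
a global identity budget; *site_retained* when the BsaI motif (GGTCTC) or its
reverse complement occurs anywhere.

## Selection model

Capture selection is modelled phenomenologically. A molecule whose label at
the designated determinant block has rate constant `k` (per hour) survives a
round with probability

    P = 1 − (1 − p_bg) · exp(−k · t)

— single-hit kinetics with a time-independent nonspecific background term
`p_bg` (default 0.05). The background term is essential: with pure
`1 − exp(−kt)` kinetics, shorter incubations *sharpen* selection (survival
ratios tend to `k₁/k₂`), whereas observed bead selections show more
background at short incubations because specific capture shrinks toward the
nonspecific floor. With `p_bg > 0` the post-selection entropy at the
determinant block decreases monotonically with incubation time, which the
tests verify over seeds; with `p_bg = 0` the model reduces to plain
single-hit kinetics. Survivors are binomially thinned and multinomially
resampled to a constant depth per round (bead/cell-count bottleneck).

The default activity table assigns each substrate exactly one cognate
determinant-block label at `k = 0.5 /h` and `k = 0` elsewhere. Secondary
(cross-reactive) activities are deliberately *not* in the defaults: an
intermediate-`k` label saturates at long incubations and makes the entropy
ordering non-monotone, contradicting the background-driven behaviour above.
Cross-reactivity can be expressed by passing an explicit table.

## Synthetic-data generator: what it emulates, what it does not

The default study is six parents of 230 aa over six equal blocks at a mean
pairwise identity of 0.70 (band ±5 points, enforced at study scale; the band
is not enforced below 30 columns, where the distinctness constraints and
sampling noise dominate), with parents D and F byte-identical in blocks 2, 3,
4 and 6 and all parents pairwise distinct within every other block — giving
equivalence-class sizes [6, 5, 5, 5, 6, 5] and a theoretical diversity of
22500. Coding sequences use random synonymous codons and are domesticated
against the BsaI site on both strands. Libraries default to 3% unshuffled
background and 5% restriction-site retainers (the motif replaces two codons,
in frame, at a random position); per-block label bias defaults to
Dirichlet(2) weights; per-molecule abundance is log-normal
(`exp(N(2, 0.8))`, rounded, ≥ 1) as a stand-in for uncharacterised assembly
and amplification skew. All randomness flows from one master seed through
named substreams, so every artefact is byte-reproducible.

Not emulated: signal-level basecalling (errors are i.i.d. per base, no
homopolymer-length bias or quality correlation), PCR chimeras, display-level
or fluorescence variation, and any real sequence homology to Spl proteases —
parents are statistical stand-ins with the *equivalence structure* of the
real gene set. Passing tests therefore demonstrate the pipeline's logic,
thresholds and statistical behaviour under a controlled error model, not
performance on real nanopore data.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive on the amino-acid alignment; nucleotide
coordinates of block `[s, e]` are `[3(s−1)+1, 3e]`. Gapped parent alignments
are rejected. Merged labels render sorted with `/`; multi-character labels
join codes with `-`. Frequencies per table sum to 1 within 1e−9; unresolved
and QC-flagged sequences are excluded from frequencies and reported
separately. Fold enrichment uses a pseudocount of 0.5/n on each side
(Haldane–Anscombe style), so absent labels give large finite ratios. The
specificity ranking uses the mean pairwise Jensen–Shannon divergence in bits
(base 2, in [0, 1]) with ties broken by block index. Chosen problem sizes in
the analysis drivers (hundreds of molecules, thousands of selection reads)
keep every driver and the test suite at desk scale while leaving all
statistical margins comfortable.

## Known limitations

- The consensus caller's greedy refinement optimises total edit distance;
  errors that are exactly objective-neutral (typically in repeats) can
  survive; accuracy at 3–4 copies is materially below 5+ copies.
- The block caller assumes chimeras are full-length; structural variants
  (large internal deletions) surface only as unresolved blocks.
- The selection model ignores competition for substrate and display-level
  variation; enrichment magnitudes are not calibrated to any real capture
  chemistry, only the qualitative behaviours documented above.
- The crossover optimizer's constraint "mutations per block" counts
  non-conserved columns, not pairwise differences; other readings would
  change the feasible set.
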