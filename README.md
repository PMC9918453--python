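# splshuffle

Design, simulation and sequence analysis of structure-guided domain-shuffling
protease libraries read out by rolling-circle nanopore consensus sequencing.

## The problem

The six *Staphylococcus aureus* Spl serine proteases (SplA–F, 47–95% amino-acid
identity) share a fold but cleave different substrate motifs. Shuffling their
genes block-wise produces chimeric proteases whose per-block parentage can be
read out by sequencing, and selecting the shuffled library against different
substrates reveals which block carries substrate specificity. This package
implements the computational core of such a study, end to end:

1. **Crossover design** — a residue–residue contact map is built from structure
   coordinates; the disruption of a chimera is the number of contacts `(i, j)`
   whose residue pair occurs in no single parent. The library average over
   uniform per-block parent choices decomposes contact-wise,

   `⟨E⟩ = Σ_{(i,j): block(i) ≠ block(j)} c(i,j)`,

   where `c(i,j)` is the fraction of ordered parent pairs `(p, q)` whose pair
   `(aa_p[i], aa_q[j])` is absent from every parent. Crossover placement
   minimising `⟨E⟩` under block-length and per-block mutation constraints is
   solved exactly by dynamic programming; `⟨m⟩`, the mean mutational distance
   of a chimera to its closest parent, is computed alongside.
2. **Combinatorial accounting** — parents that are byte-identical within a
   block merge into one label (e.g. `D/F`); the number of distinct chimeras is
   the product of per-block equivalence-class counts.
3. **Read consensus** — concatemeric rolling-circle reads (anchor + barcode +
   gene, tandem-repeated) are quality/length filtered, segmented at the anchor,
   and collapsed into per-molecule consensus sequences (star voting plus a
   partial-order-graph consensus, merged under the total-edit-distance
   objective; minimum three copies).
4. **Block calling** — each consensus is classified block-by-block by local
   alignment against every parent's block reference (best hit, >90% aligned
   reference length), demultiplexed by barcode, and QC-flagged (unshuffled
   vector background, retained BsaI site).
5. **Enrichment statistics** — per-block label frequencies per population,
   fold enrichment against the input library, diversity/skew of the library,
   and a ranking of block positions by cross-condition Jensen–Shannon
   divergence that identifies the specificity-determining block.
6. **Synthetic data** — a generator produces all of the above inputs with known
   ground truth: six ~230-aa parents with a designated identical-block
   structure, a biased barcoded library with background and restriction-site
   contaminants, nanopore-like noisy concatemer reads, and multi-round
   capture selections whose outcome is controlled by one designated block.

## Worked example

```python
from splshuffle import (default_study, enumerate_diversity, equivalence_classes)

parents, partition = default_study(seed=0)
sizes = [len(g) for g in equivalence_classes(parents, partition, "aa")]
print(sizes)                                            # [6, 5, 5, 5, 6, 5]
print(enumerate_diversity(parents, partition, "aa"))    # 22500
```

Six parents over six blocks, with parents D and F identical within blocks 2,
3, 4 and 6, give 6 x 5 x 5 x 5 x 6 x 5 = 22500 distinct protein chimeras.

The numbered drivers under `analysis/` run the full study on synthetic data
and print what they find:

```text
$ python analysis/04_selection_enrichment.py
substrate VWLY: dominant block-5 label after 2 rounds: A (0.97)
substrate WELQ: dominant block-5 label after 2 rounds: B (0.97)
substrate RWLL: dominant block-5 label after 2 rounds: F (0.99)

cross-condition divergence per block:
 block  mean_jsd  rank
     5  0.929404     1
     1  0.036293     2
     ...

finding: block 5 is the most condition-divergent block (designed determinant block: 5).
```

(`01` designs crossovers on a synthetic fold, `02` simulates the library and
reads, `03` runs consensus + block calling against ground truth, `04` runs the
three-substrate selection and the divergence ranking. Values shown are from
the fixed default seed; block-5 frequencies depend on the seed.)

A `splshuffle` command-line tool exposes the shell-facing steps
(`simulate`, `consensus`, `call`, `enrich`); see `splshuffle --help`.

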