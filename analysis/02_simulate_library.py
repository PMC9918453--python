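"""Simulate the sequencing study: library, concatemeric reads, truth tables.

Generates the default six-parent / six-block study system, a biased
barcoded library with vector-background and restriction-site contaminants,
and noisy rolling-circle concatemer reads.  Large per-molecule artefacts
(FASTQ, full library table) go to scratch/; summary tables to results/.

Run from the repository root:  python analysis/02_simulate_library.py
"""

from pathlib import Path

import pandas as pd

from splshuffle.enrichment_stats import diversity_and_skew
from splshuffle.library_model import enumerate_diversity
from splshuffle.synthetic_data import (
    DEFAULT_ANCHOR,
    LibrarySpec,
    default_study,
    generate_library,
    generate_reads,
    write_fastq,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH, RESULTS = ROOT / "scratch", ROOT / "results"
SEED = 0
N_MOLECULES = 800


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    parents, partition = default_study(seed=SEED)
    theo = enumerate_diversity(parents, partition, "aa")
    print(f"parents: {parents.n_parents} x {parents.length_aa} aa, "
          f"theoretical diversity {theo}")

    spec = LibrarySpec(partition, total_molecules=N_MOLECULES, seed=SEED)
    library = generate_library(parents, spec)
    shuffled = library[~library.is_background]
    stats = diversity_and_skew(
        shuffled.groupby("code")["abundance"].sum(), theoretical_diversity=theo)
    print(f"library: {len(library)} molecules, "
          f"{library.is_background.sum()} background, "
          f"{library.has_site.sum()} with retained restriction site")
    print(f"observed {stats['unique_variants']} distinct codes "
          f"({100 * stats['coverage']:.1f}% of theoretical), "
          f"abundance skew {stats['skew']:.1f}x over the median")

    reads, truth = generate_reads(library, seed=SEED)  # default 5/3/3% noise
    parents.to_fasta(SCRATCH / "parents_aa.fasta", SCRATCH / "parents_nt.fasta")
    partition.to_tsv(RESULTS / "blocks.tsv")
    library.to_csv(SCRATCH / "library.tsv", sep="\t", index=False)
    write_fastq(reads, SCRATCH / "reads.fastq")
    truth.to_csv(SCRATCH / "read_truth.tsv", sep="\t", index=False)
    (SCRATCH / "anchor.fasta").write_text(f">anchor\n{DEFAULT_ANCHOR}\n")

    summary = pd.DataFrame([{
        "molecules": len(library),
        "background": int(library.is_background.sum()),
        "site_retainers": int(library.has_site.sum()),
        "unique_codes": stats["unique_variants"],
        "coverage_of_theoretical": round(stats["coverage"], 4),
        "abundance_skew": round(stats["skew"], 2),
        "reads": len(reads),
        "mean_read_length": int(sum(len(r.seq) for r in reads) / len(reads)),
    }])
    summary.to_csv(RESULTS / "library_summary.tsv", sep="\t", index=False)
    print(f"wrote reads and truth tables to {SCRATCH}, summary to "
          f"{RESULTS / 'library_summary.tsv'}")


if __name__ == "__main__":
    main()
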