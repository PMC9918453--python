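"""Consensus calling and block classification of the simulated reads.

Consumes the reads written by 02_simulate_library.py (regenerating them if
absent), collapses concatemers into per-molecule consensus sequences,
classifies every consensus into a six-block chimera code, demultiplexes by
barcode, applies QC flags, and scores everything against the generator's
ground truth.

Run from the repository root:  python analysis/03_consensus_and_call.py
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from splshuffle.block_caller import call_population
from splshuffle.library_model import BlockPartition, ParentSet
from splshuffle.read_consensus import consensus_pipeline, read_fastq
from splshuffle.synthetic_data import DEFAULT_ANCHOR, control_sequence

ROOT = Path(__file__).resolve().parents[1]
SCRATCH, RESULTS = ROOT / "scratch", ROOT / "results"


def main() -> None:
    if not (SCRATCH / "reads.fastq").exists():
        print("reads not found; running 02_simulate_library.py first")
        subprocess.run([sys.executable, str(ROOT / "analysis/02_simulate_library.py")],
                       check=True)
    parents = ParentSet.from_fasta(SCRATCH / "parents_aa.fasta",
                                   SCRATCH / "parents_nt.fasta")
    partition = BlockPartition.from_tsv(RESULTS / "blocks.tsv")
    library = pd.read_csv(SCRATCH / "library.tsv", sep="\t")
    truth = pd.read_csv(SCRATCH / "read_truth.tsv", sep="\t")

    reads = read_fastq(SCRATCH / "reads.fastq")
    records, sidecar = consensus_pipeline(reads, DEFAULT_ANCHOR)
    outcomes = sidecar["outcome"].value_counts().to_dict()
    print(f"reads: {len(reads)}; outcomes: {outcomes}")

    calls = call_population(
        records, parents, partition,
        barcode_table=pd.DataFrame(
            {"sample_id": library.molecule_id, "barcode": library.barcode}),
        control_seq=control_sequence(parents))
    merged = (calls.merge(truth, on="read_id")
                   .merge(library, on="molecule_id", suffixes=("_called", "_true")))
    nonbg = merged[~merged.is_background]
    correct = (nonbg.code_called == nonbg.code_true).mean()
    print(f"accepted consensus: {len(merged)}; resolved: {merged.resolved.mean():.3f}")
    print(f"true code recovered for {100 * correct:.2f}% of accepted "
          f"non-background consensus sequences")
    print(f"demultiplexing to the correct molecule: "
          f"{(merged.sample_id == merged.molecule_id).mean():.3f}")
    bg = merged[merged.is_background]
    print(f"background flagged: {bg.background.mean() if len(bg) else float('nan'):.3f}; "
          f"site flags match truth: {(merged.site_retained == merged.has_site).mean():.3f}")

    calls.to_csv(SCRATCH / "block_calls.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "reads": len(reads),
        **{f"outcome_{k}": v for k, v in outcomes.items()},
        "resolved_fraction": round(float(merged.resolved.mean()), 4),
        "true_code_recovery": round(float(correct), 4),
        "demux_accuracy": round(float((merged.sample_id == merged.molecule_id).mean()), 4),
    }]).to_csv(RESULTS / "calling_summary.tsv", sep="\t", index=False)
    print(f"wrote {SCRATCH / 'block_calls.tsv'} and {RESULTS / 'calling_summary.tsv'}")


if __name__ == "__main__":
    main()
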