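"""Ground-truthed generators: parents, libraries, reads, selection."""

import numpy as np
import pandas as pd
import pytest
import edlib

from splshuffle.library_model import BlockPartition, ChimeraCode, equivalence_classes
from splshuffle.enrichment_stats import block_frequencies, block_entropy
from splshuffle.synthetic_data import (
    BSAI_SITE,
    BSAI_SITE_RC,
    DEFAULT_ANCHOR,
    LibrarySpec,
    SelectionSpec,
    apply_errors,
    control_sequence,
    default_partition,
    default_study,
    generate_library,
    generate_parents,
    generate_reads,
    revcomp,
    simulate_selection,
    substream,
)


class TestGenerateParents:
    def test_deterministic(self):
        a = generate_parents(seed=42)
        b = generate_parents(seed=42)
        assert a == b

    def test_study_equivalence_structure(self, study):
        parents, partition = study
        sizes = [len(g) for g in equivalence_classes(parents, partition, "aa")]
        assert sizes == [6, 5, 5, 5, 6, 5]
        sizes_nt = [len(g) for g in equivalence_classes(parents, partition, "nt")]
        assert sizes_nt == [6, 5, 5, 5, 6, 5]

    def test_identity_within_band(self, study):
        parents, _ = study
        ids = [
            np.mean([a == b for a, b in zip(parents.aa_seqs[i], parents.aa_seqs[j])])
            for i in range(6) for j in range(i + 1, 6)
        ]
        assert abs(np.mean(ids) - 0.7) <= 0.05

    def test_no_spec_all_blocks_distinct(self):
        part = default_partition(100, 4)
        parents = generate_parents(4, 100, part, 0.5, seed=9)
        for groups in equivalence_classes(parents, part, "aa"):
            assert all(len(g) == 1 for g in groups)

    def test_parents_are_bsai_free(self, study):
        parents, _ = study
        for nt in parents.nt_seqs:
            assert BSAI_SITE not in nt and BSAI_SITE_RC not in nt

    def test_invalid_identity_target(self):
        with pytest.raises(ValueError):
            generate_parents(pairwise_identity_target=1.0)

    def test_unknown_label_in_spec(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_parents(identical_blocks={("D", "Z"): (2,)})


class TestGenerateLibrary:
    def test_background_one_flags_everything(self, study):
        parents, partition = study
        spec = LibrarySpec(partition, total_molecules=30, background_fraction=1.0,
                           site_retainer_fraction=0.0, seed=1)
        lib = generate_library(parents, spec)
        assert lib.is_background.all()
        assert (lib.nt_seq == control_sequence(parents)).all()

    def test_uniform_bias_frequencies(self, study):
        parents, partition = study
        uniform = tuple({l: 1.0 for l in parents.labels} for _ in range(6))
        spec = LibrarySpec(partition, total_molecules=900, bias_weights=uniform,
                           background_fraction=0.0, site_retainer_fraction=0.0, seed=2)
        lib = generate_library(parents, spec)
        labels = [ChimeraCode.parse(c).labels_per_block[0] for c in lib.code_raw]
        counts = pd.Series(labels).value_counts()
        n, p = len(lib), 1 / 6
        sd = np.sqrt(n * p * (1 - p))
        assert all(abs(counts.get(l, 0) - n * p) <= 3 * sd for l in parents.labels)

    def test_zero_weight_label_absent(self, study):
        parents, partition = study
        w = [{l: 1.0 for l in parents.labels} for _ in range(6)]
        w[2] = {l: (0.0 if l == "C" else 1.0) for l in parents.labels}
        spec = LibrarySpec(partition, total_molecules=200, bias_weights=tuple(w),
                           background_fraction=0.0, site_retainer_fraction=0.0, seed=3)
        lib = generate_library(parents, spec)
        assert all(ChimeraCode.parse(c).labels_per_block[2] != "C" for c in lib.code_raw)

    def test_composition_and_site_motif(self, study):
        parents, partition = study
        spec = LibrarySpec(partition, total_molecules=200, seed=4)
        lib = generate_library(parents, spec)
        assert lib.is_background.sum() == round(0.03 * 200)
        assert lib.has_site.sum() == round(0.05 * 200)
        for row in lib.itertuples():
            assert (BSAI_SITE in row.nt_seq) == row.has_site or row.is_background
        # site embedded in frame: sequence length unchanged
        assert lib.nt_seq.str.len().nunique() == 1

    def test_barcodes_min_pairwise_distance(self, study):
        parents, partition = study
        lib = generate_library(parents, LibrarySpec(partition, total_molecules=60, seed=5))
        bcs = list(lib.barcode)
        for i in range(len(bcs)):
            for j in range(i + 1, len(bcs)):
                assert edlib.align(bcs[i], bcs[j], mode="NW")["editDistance"] >= 3

    def test_invalid_fractions(self, study):
        _, partition = study
        with pytest.raises(ValueError):
            LibrarySpec(partition, background_fraction=0.6, site_retainer_fraction=0.6)


class TestGenerateReads:
    def test_zero_noise_exact_concatemer(self, study):
        parents, partition = study
        lib = generate_library(parents, LibrarySpec(partition, total_molecules=5, seed=6))
        reads, truth = generate_reads(lib, copies=3, sub_rate=0, ins_rate=0,
                                      del_rate=0, fraction_reverse=0.0, seed=6)
        for read, t in zip(reads, truth.itertuples()):
            row = lib[lib.molecule_id == t.molecule_id].iloc[0]
            unit = DEFAULT_ANCHOR + row.barcode + row.nt_seq
            assert read.seq == unit * 3
            assert len(read.seq) == 3 * len(unit)

    def test_reverse_strand_reads_are_reverse_complements(self, study):
        parents, partition = study
        lib = generate_library(parents, LibrarySpec(partition, total_molecules=10, seed=6))
        fwd, _ = generate_reads(lib, copies=3, sub_rate=0, ins_rate=0, del_rate=0,
                                fraction_reverse=0.0, seed=6)
        both, truth = generate_reads(lib, copies=3, sub_rate=0, ins_rate=0, del_rate=0,
                                     fraction_reverse=1.0, seed=6)
        for f, b in zip(fwd, both):
            assert b.seq == revcomp(f.seq)
        assert set(truth.strand) == {"-"}

    def test_substitution_rate_within_3sd(self):
        rng = substream(1, "errtest")
        unit = "".join(rng.choice(list("ACGT"), 3000))
        noisy = apply_errors(unit, 0.05, 0.0, 0.0, rng)
        mismatches = sum(a != b for a, b in zip(noisy, unit))
        n, p = len(unit), 0.05
        assert abs(mismatches - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_fixed_seed_reproducible(self, study):
        parents, partition = study
        lib = generate_library(parents, LibrarySpec(partition, total_molecules=8, seed=7))
        r1, t1 = generate_reads(lib, seed=7)
        r2, t2 = generate_reads(lib, seed=7)
        assert r1 == r2 and t1.equals(t2)

    def test_rate_bounds_enforced(self, study):
        parents, partition = study
        lib = generate_library(parents, LibrarySpec(partition, total_molecules=2, seed=8))
        with pytest.raises(ValueError):
            generate_reads(lib, sub_rate=0.5)


def _final_round_table(sel, spec):
    last = sel[(sel["round"] == spec.rounds) & sel.code.notna()]
    return block_frequencies(last.code, weights=last["count"])


@pytest.fixture(scope="module")
def library(study):
    parents, partition = study
    return generate_library(
        parents, LibrarySpec(partition, total_molecules=400, seed=10))


class TestSelection:
    def test_molecule_identity_conserved(self, library):
        sel = simulate_selection(library, SelectionSpec(seed=0), "WELQ")
        assert set(sel.molecule_id) <= set(library.molecule_id)

    def test_zero_time_no_enrichment(self, library):
        spec = SelectionSpec(incubation_time=0.0, rounds=1, capture_depth=4000,
                             background_capture=0.5, seed=1)
        sel = simulate_selection(library, spec, "WELQ")
        f_in = block_frequencies(
            library[~library.is_background].code,
            weights=library[~library.is_background].abundance)
        f_out = _final_round_table(sel, spec)
        for lab, fo in f_out.frequencies(5).items():
            fi = f_in.frequencies(5).get(lab, 0.0)
            assert abs(fo - fi) <= 3 * np.sqrt(max(fi * (1 - fi), 1e-4) / 4000) + 0.02

    def test_single_active_label_dominates_at_long_time(self, library):
        table = {"WELQ": {l: (5.0 if l == "B" else 0.0) for l in "ABCDEF"}}
        spec = SelectionSpec(activity_table=table, incubation_time=12.0, rounds=2,
                             background_capture=0.001, capture_depth=3000, seed=2)
        sel = simulate_selection(library, spec, "WELQ")
        freqs = _final_round_table(sel, spec).frequencies(5)
        assert freqs.get("B", 0.0) > 0.95

    def test_equal_rates_preserve_frequencies(self, library):
        table = {"WELQ": {l: 1.0 for l in "ABCDEF"}}
        spec = SelectionSpec(activity_table=table, rounds=1, capture_depth=4000, seed=3)
        sel = simulate_selection(library, spec, "WELQ")
        f_in = block_frequencies(
            library[~library.is_background].code,
            weights=library[~library.is_background].abundance)
        f_out = _final_round_table(sel, spec)
        for b in range(1, 7):
            for lab, fo in f_out.frequencies(b).items():
                fi = f_in.frequencies(b).get(lab, 0.0)
                assert abs(fo - fi) <= 3 * np.sqrt(max(fi * (1 - fi), 1e-4) / 4000) + 0.02

    def test_missing_activity_entry_raises(self, library):
        with pytest.raises(ValueError, match="activity"):
            simulate_selection(
                library,
                SelectionSpec(activity_table={"WELQ": {"A": 1.0}}, seed=4),
                "WELQ")

    def test_shorter_incubation_noisier_determinant_block(self, study):
        """Mean post-selection entropy at the determinant block decreases with
        incubation time (nonspecific background dominates short incubations)."""
        parents, partition = study
        ents = {1.0: [], 3.0: [], 12.0: []}
        for seed in range(6):
            lib = generate_library(
                parents, LibrarySpec(partition, total_molecules=400, seed=50 + seed))
            for t in ents:
                spec = SelectionSpec(incubation_time=t, capture_depth=3000,
                                     seed=60 + seed)
                sel = simulate_selection(lib, spec, "WELQ")
                ents[t].append(block_entropy(_final_round_table(sel, spec), 5))
        means = {t: np.mean(v) for t, v in ents.items()}
        assert means[1.0] > means[3.0] > means[12.0]
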