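import math

import numpy as np
import pytest

from helpers import intervals_disjoint_with_gaps, rc

from bsmethyl import synthdata
from bsmethyl.core import Genome, MethylationTruth, MotifSpec
from bsmethyl.regions import upstream_interval


class TestGenerateGenome:
    def test_pure_gc(self):
        g = synthdata.generate_genome(1000, gc_fraction=1.0, seed=1)
        assert set(g.sequence) <= {"G", "C"}

    def test_gc_fraction_large(self):
        g = synthdata.generate_genome(10**6, gc_fraction=0.70, seed=7)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g)
        assert abs(gc - 0.70) < 0.005

    def test_seeded_determinism(self):
        a = synthdata.generate_genome(2000, 0.7, seed=42)
        b = synthdata.generate_genome(2000, 0.7, seed=42)
        assert a.sequence == b.sequence
        c = synthdata.generate_genome(2000, 0.7, seed=43)
        assert c.sequence != a.sequence

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            synthdata.generate_genome(0, 0.7, seed=1)

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            synthdata.generate_genome(10, 1.5, seed=1)


class TestGenerateAnnotation:
    def test_zero_genes(self, small_genome):
        assert synthdata.generate_annotation(small_genome, 0) == []

    def test_disjoint_with_gaps(self, small_genome):
        genes = synthdata.generate_annotation(
            small_genome, 4, gene_length=(300, 600), min_gap=150, seed=3
        )
        assert len(genes) == 4
        assert intervals_disjoint_with_gaps(
            [(g.start, g.end) for g in genes], min_gap=150
        )
        for g in genes:
            assert 0 <= g.start < g.end <= len(small_genome)

    def test_strand_counts_binomial(self):
        genome = synthdata.generate_genome(400_000, 0.7, seed=5)
        genes = synthdata.generate_annotation(
            genome, 200, gene_length=(900, 1500), min_gap=100, seed=11
        )
        n_plus = sum(g.strand == "+" for g in genes)
        sigma = math.sqrt(200 * 0.25)
        assert abs(n_plus - 100) <= 3 * sigma

    def test_translation_start_strandedness(self, small_genome):
        genes = synthdata.generate_annotation(
            small_genome, 3, gene_length=(200, 400), min_gap=100, seed=9
        )
        for g in genes:
            expected = g.start if g.strand == "+" else g.end - 1
            assert g.translation_start == expected

    def test_infeasible_packing_errors(self, tiny_genome):
        with pytest.raises(ValueError, match="cannot place"):
            synthdata.generate_annotation(
                tiny_genome, 10, gene_length=(100, 100), min_gap=50, seed=1
            )


class TestPlantMethylome:
    def test_nothing_planted(self, small_genome):
        genes = synthdata.generate_annotation(
            small_genome, 3, gene_length=(300, 500), min_gap=100, seed=2
        )
        edited, truth = synthdata.plant_methylome(
            small_genome, genes, genes_with_motif_fraction=0.0, background_rates={}
        )
        assert len(truth) == 0
        assert edited.sequence == small_genome.sequence

    def test_planted_substring_and_anchor(self, small_genome):
        genes = synthdata.generate_annotation(
            small_genome, 3, gene_length=(300, 500), min_gap=100, seed=2
        )
        motif = MotifSpec("GGCCGG", anchor=4)
        edited, truth = synthdata.plant_methylome(
            small_genome, genes, motifs=[motif], genes_with_motif_fraction=1.0, seed=4
        )
        assert len(truth) == 3  # GGCCGG is not its own reverse complement
        for row in truth.table.itertuples():
            if row.strand == "+":
                planted_start = row.pos - 3  # anchor 4 -> 3 bases before
                assert edited.sequence[planted_start : planted_start + 6] == "GGCCGG"
            else:
                planted_start = row.pos - 2  # anchor maps to offset k - anchor
                assert (
                    edited.sequence[planted_start : planted_start + 6]
                    == rc("GGCCGG")
                )
            assert edited.base_at(row.pos, row.strand) == "C"

    def test_palindromic_motif_marks_both_strands(self, small_genome):
        genes = synthdata.generate_annotation(
            small_genome, 2, gene_length=(300, 500), min_gap=100, seed=2
        )
        motif = MotifSpec("GCCGGC", anchor=3)  # true palindrome
        edited, truth = synthdata.plant_methylome(
            small_genome, genes, motifs=[motif], genes_with_motif_fraction=1.0, seed=8
        )
        assert len(truth) == 4  # two anchors per instance
        assert set(truth.table["strand"]) == {"+", "-"}
        edited2, truth2 = synthdata.plant_methylome(
            small_genome,
            genes,
            motifs=[motif],
            genes_with_motif_fraction=1.0,
            seed=8,
            methylate_palindrome_partner=False,
        )
        assert len(truth2) == 2

    def test_sites_inside_upstream_regions(self):
        genome = synthdata.generate_genome(400_000, 0.7, seed=6)
        genes = synthdata.generate_annotation(
            genome, 200, gene_length=(900, 1500), min_gap=100, seed=7
        )
        edited, truth = synthdata.plant_methylome(
            genome, genes, genes_with_motif_fraction=0.5, seed=13
        )
        planted = truth.table[truth.table["provenance"] == "motif-planted"]
        assert len(planted) == 100  # round(0.5 * 200), no palindromic motifs
        regions = [
            upstream_interval(g.translation_start, g.strand, 500, 100, len(genome))
            for g in genes
        ]
        for pos in planted["pos"]:
            assert any(start <= pos < end for start, end, _ in regions)

    def test_motifs_findable_by_string_search(self):
        genome = synthdata.generate_genome(400_000, 0.7, seed=6)
        genes = synthdata.generate_annotation(
            genome, 100, gene_length=(900, 1500), min_gap=100, seed=7
        )
        motif = MotifSpec("GCCCG", anchor=4)
        edited, truth = synthdata.plant_methylome(
            genome, genes, motifs=[motif], genes_with_motif_fraction=1.0, seed=21
        )
        n_found = edited.sequence.count("GCCCG") + edited.sequence.count(rc("GCCCG"))
        assert n_found >= len(truth)

    def test_truth_consistency(self, small_genome):
        genes = synthdata.generate_annotation(
            small_genome, 3, gene_length=(300, 500), min_gap=100, seed=2
        )
        edited, truth = synthdata.plant_methylome(
            small_genome,
            genes,
            genes_with_motif_fraction=1.0,
            background_rates={"CG": 0.05, "CHH": 0.02},
            seed=5,
        )
        truth.validate_against(edited)  # raises on violation

    def test_background_rates_validated(self, small_genome):
        with pytest.raises(ValueError, match="unknown context"):
            synthdata.plant_methylome(
                small_genome, [], background_rates={"CXX": 0.1}
            )


class TestSimulateReads:
    def test_read_count_formula(self, tiny_genome):
        truth = MethylationTruth()
        reads = synthdata.simulate_reads(
            tiny_genome, truth, coverage=3.3, read_length=100, seed=1
        )
        assert len(reads) == math.ceil(3.3 * 400 / 100)

    def test_full_protection_reads_match_genome(self, tiny_genome):
        sites = [
            (i, "+", 1.0, "background")
            for i, b in enumerate(tiny_genome.sequence)
            if b == "C"
        ] + [
            (i, "-", 1.0, "background")
            for i, b in enumerate(tiny_genome.sequence)
            if b == "G"
        ]
        truth = MethylationTruth.from_sites(sites)
        reads = synthdata.simulate_reads(
            tiny_genome, truth, coverage=5, read_length=80, error_rate=0.0, seed=2
        )
        for read in reads:
            ref = tiny_genome.sequence[read.origin_pos : read.origin_pos + 80]
            if read.origin_strand == "OT":
                assert read.bases == ref
            else:
                assert read.bases == rc(ref)

    def test_full_conversion_no_c_left(self, tiny_genome):
        truth = MethylationTruth()
        reads = synthdata.simulate_reads(
            tiny_genome,
            truth,
            coverage=5,
            read_length=80,
            conversion_rate=1.0,
            error_rate=0.0,
            seed=3,
        )
        for read in reads:
            ref = tiny_genome.sequence[read.origin_pos : read.origin_pos + 80]
            if read.origin_strand == "OT":
                for r, q in zip(ref, read.bases):
                    assert not (r == "C" and q == "C")
                    if r == "C":
                        assert q == "T"

    def test_unconverted_fraction_matches_rate(self):
        genome = synthdata.generate_genome(20_000, 0.7, seed=4)
        truth = MethylationTruth()
        conversion = 0.95
        reads = synthdata.simulate_reads(
            genome,
            truth,
            coverage=10,
            read_length=100,
            conversion_rate=conversion,
            error_rate=0.0,
            seed=5,
        )
        n_c = 0
        n_tot = 0
        for read in reads[:1000]:
            if read.origin_strand != "OT":
                continue
            ref = genome.sequence[read.origin_pos : read.origin_pos + 100]
            for r, q in zip(ref, read.bases):
                if r == "C":
                    n_tot += 1
                    n_c += q == "C"
        frac = n_c / n_tot
        sigma = math.sqrt((1 - conversion) * conversion / n_tot)
        assert abs(frac - (1 - conversion)) <= 3 * sigma

    def test_seeded_determinism(self, tiny_genome):
        truth = MethylationTruth()
        a = synthdata.simulate_reads(tiny_genome, truth, coverage=2, read_length=50, seed=9)
        b = synthdata.simulate_reads(tiny_genome, truth, coverage=2, read_length=50, seed=9)
        assert [(r.read_id, r.bases) for r in a] == [(r.read_id, r.bases) for r in b]

    def test_read_length_exceeds_genome(self, tiny_genome):
        with pytest.raises(ValueError, match="exceeds genome length"):
            synthdata.simulate_reads(
                tiny_genome, MethylationTruth(), coverage=1, read_length=401
            )
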