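"""Synthetic-data generator: packing, determinism, density, selection, reads."""

import math

import numpy as np
import pytest

from tnfit.genome import reverse_complement
from tnfit.profiles import InsertionProfile
from tnfit.simulate import (
    EffectMap,
    GeneEffect,
    SizingError,
    apply_selection,
    emit_reads,
    expected_unique_sites,
    generate_genome,
    random_effects,
    simulate_library,
)


class TestGenerateGenome:
    def test_genes_within_bounds_and_disjoint(self):
        g = generate_genome(50_000, 40, gc_fraction=0.5, seed=1)
        assert len(g) == 50_000 and len(g.genes) == 40
        prev_end = 0
        for gene in g.genes:
            assert 1 <= gene.start <= gene.end <= len(g)
            assert gene.start > prev_end, "genes must not overlap and need >=1 bp gaps"
            prev_end = gene.end

    def test_gene_free_genome(self):
        g = generate_genome(1_000, 0, gc_fraction=0.5, seed=1)
        assert len(g) == 1_000 and g.genes == []

    def test_deterministic_fasta_gff3(self, tmp_path):
        out = []
        for run in range(2):
            g = generate_genome(10_000, 8, gc_fraction=0.4, seed=5)
            fa, gff = tmp_path / f"g{run}.fa", tmp_path / f"g{run}.gff3"
            g.write_fasta(fa)
            g.write_gff3(gff)
            out.append((fa.read_bytes(), gff.read_bytes()))
        assert out[0] == out[1]

    def test_gc_fraction_respected(self):
        g = generate_genome(100_000, 0, gc_fraction=0.7, seed=3)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g)
        assert abs(gc - 0.7) < 0.01

    def test_impossible_packing_raises(self):
        with pytest.raises(SizingError):
            generate_genome(3_000, 100, gc_fraction=0.5, seed=1)


class TestSimulateLibrary:
    def test_zero_density_gives_empty_profile(self, small_genome, small_effects):
        p = simulate_library(small_genome, small_effects, insertions_per_bp=0.0, seed=1)
        assert p.n_sites == 0 and p.total_reads == 0

    def test_unique_site_count_matches_binomial_expectation(self):
        """At one insertion per 10.3 bp the site count is Binomial(L, p)."""
        g = generate_genome(4_600_000, 0, gc_fraction=0.5, seed=2)
        p = simulate_library(g, EffectMap({}), insertions_per_bp=1 / 10.3,
                             mean_reads_per_site=10, nb_dispersion=0.3, seed=2)
        mean, sd = expected_unique_sites(len(g), 1 / 10.3)
        assert abs(p.n_sites - mean) < 3 * sd

    def test_essential_genes_receive_no_insertions(self, small_genome, small_effects):
        p = simulate_library(small_genome, small_effects, seed=3)
        pos, _, _ = p.arrays()
        for gene in small_genome.genes:
            if small_effects[gene.gene_id].essential:
                inside = (pos >= gene.start) & (pos <= gene.end)
                assert not inside.any()

    def test_no_zero_counts_and_total_consistency(self, small_genome, small_effects):
        p = simulate_library(small_genome, small_effects, seed=4)
        assert all(c >= 1 for c in p.counts.values())
        assert p.total_reads == sum(p.counts.values())

    def test_edge_margin_keeps_ends_clear(self, small_genome, small_effects):
        p = simulate_library(small_genome, small_effects, seed=5, edge_margin=100)
        pos, _, _ = p.arrays()
        assert pos.min() > 100 and pos.max() <= len(small_genome) - 100

    def test_missing_gene_in_effect_map_raises(self, small_genome):
        with pytest.raises(ValueError, match="effect map"):
            simulate_library(small_genome, EffectMap({"gX": GeneEffect()}), seed=1)


class TestApplySelection:
    def test_total_reads_conserved_and_subset(self, small_genome, small_effects):
        lib = simulate_library(small_genome, small_effects, seed=6)
        sel = apply_selection(lib, small_genome, small_effects, seed=7)
        assert sel.total_reads == lib.total_reads
        assert set(sel.counts) <= set(lib.counts)

    def test_neutral_selection_preserves_proportions(self, small_genome):
        lib = simulate_library(small_genome, EffectMap.neutral(small_genome), seed=8)
        sel = apply_selection(lib, small_genome, EffectMap.neutral(small_genome), seed=9)
        # expected count per site equals control count; check total deviation
        pos, _, c0 = lib.arrays()
        c1 = np.array([sel.counts.get((int(p), s), 0)
                       for (p, s) in lib.sorted_sites()])
        # chi-square-ish sanity: mean relative deviation small at depth ~10/site
        assert abs(c1.sum() - c0.sum()) == 0
        assert np.corrcoef(c0, c1)[0, 1] > 0.8

    def test_depleted_gene_share_matches_closed_form(self, small_genome):
        """One gene at effect -3: its expected treated read share is the
        control share scaled by 2^-3 and renormalized."""
        neutral = EffectMap.neutral(small_genome)
        lib = simulate_library(small_genome, neutral, seed=10)
        target = small_genome.genes[5]
        effects = EffectMap.neutral(small_genome)
        effects.effects[target.gene_id] = GeneEffect(fitness_log2=-3.0)

        pos, _, cnt = lib.arrays()
        in_gene = (pos >= target.start) & (pos <= target.end)
        share0 = cnt[in_gene].sum() / cnt.sum()
        expected_share = share0 * 2**-3 / (1 - share0 + share0 * 2**-3)

        shares = []
        for seed in range(20):
            sel = apply_selection(lib, small_genome, effects, seed=100 + seed)
            p1, _, c1 = sel.arrays()
            hit = (p1 >= target.start) & (p1 <= target.end)
            shares.append(c1[hit].sum() / c1.sum())
        # binomial SE of the mean share over 20 resamplings
        se = math.sqrt(expected_share * (1 - expected_share) / lib.total_reads / 20)
        assert abs(np.mean(shares) - expected_share) < 4 * se

    def test_hard_kill_gene_gets_zero_reads(self, small_genome):
        neutral = EffectMap.neutral(small_genome)
        lib = simulate_library(small_genome, neutral, seed=11)
        target = small_genome.genes[0]
        effects = EffectMap.neutral(small_genome)
        effects.effects[target.gene_id] = GeneEffect(fitness_log2=float("-inf"))
        sel = apply_selection(lib, small_genome, effects, seed=12)
        p1, _, _ = sel.arrays()
        assert not ((p1 >= target.start) & (p1 <= target.end)).any()

    def test_empty_control_rejected(self, small_genome, small_effects):
        empty = InsertionProfile("x", small_genome.replicon_id, {})
        with pytest.raises(ValueError):
            apply_selection(empty, small_genome, small_effects, seed=1)


class TestEmitReads:
    def test_error_free_reads_reconstruct_junction(self, toy_genome):
        profile = InsertionProfile("s1", "toy", {(100, "+"): 3})
        reads = list(emit_reads(profile, toy_genome, tag_seq="TGTTA", barcode="ACGT",
                                read_length=50, error_rate=0.0, seed=1))
        assert len(reads) == 3
        junction_len = 50 - 4 - 5
        expected = "ACGT" + "TGTTA" + toy_genome.sequence[99 : 99 + junction_len]
        for _, seq, qual in reads:
            assert seq == expected
            assert qual == "?" * len(seq)

    def test_minus_strand_reads_are_reverse_complement(self, toy_genome):
        profile = InsertionProfile("s1", "toy", {(2030, "-"): 1})
        [(_, seq, _)] = emit_reads(profile, toy_genome, tag_seq="TGTTA", barcode="ACGT",
                                   read_length=50, error_rate=0.0, seed=1)
        junction_len = 50 - 9
        expected = reverse_complement(toy_genome.sequence[2030 - junction_len : 2030])
        assert seq == "ACGT" + "TGTTA" + expected

    def test_read_count_conservation(self, small_genome, small_effects):
        lib = simulate_library(small_genome, small_effects, seed=13, edge_margin=75)
        n = sum(1 for _ in emit_reads(lib, small_genome, seed=14))
        assert n == lib.total_reads

    def test_truncation_at_replicon_end(self, toy_genome):
        profile = InsertionProfile("s1", "toy", {(2995, "+"): 1, (3, "-"): 1})
        reads = dict()
        for rid, seq, _ in emit_reads(profile, toy_genome, tag_seq="TGTTA",
                                      barcode="ACGT", read_length=50, seed=1):
            reads[rid.split("|")[1]] = seq
        assert reads["2995"] == "ACGTTGTTA" + toy_genome.sequence[2994:3000]
        assert reads["3"] == "ACGTTGTTA" + reverse_complement(toy_genome.sequence[0:3])

    def test_substitution_error_rate_binomial(self, toy_genome):
        """Observed mismatches across ~50k read-bases track the error rate."""
        profile = InsertionProfile("s1", "toy", {(100, "+"): 1000})
        truth = list(emit_reads(profile, toy_genome, tag_seq="TGTTA", barcode="ACGT",
                                read_length=59, error_rate=0.0, seed=2))[0][1]
        n_bases = 0
        mism = 0
        for _, seq, _ in emit_reads(profile, toy_genome, tag_seq="TGTTA", barcode="ACGT",
                                    read_length=59, error_rate=0.01, seed=2):
            n_bases += len(seq)
            mism += sum(a != b for a, b in zip(seq, truth))
        mean = n_bases * 0.01
        sd = math.sqrt(n_bases * 0.01 * 0.99)
        assert abs(mism - mean) < 3 * sd
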