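"""Generator contracts: truth tables exactly describe the emitted sequences."""

import numpy as np
import pandas as pd
import pytest

from genomesurvey import synthetic as syn


class TestGenerateGenome:
    def test_empty_spec_gives_background_only(self):
        genome, truth = syn.generate_genome(
            syn.SyntheticGenomeSpec(genome_length=5_000, seed=3)
        )
        (seq,) = genome.values()
        assert len(seq) == 5_000
        assert truth.repeats.empty and truth.tandems.empty
        assert truth.numts.empty and truth.genes.empty

    def test_exact_repeat_copies_recoverable_by_substring_search(self):
        spec = syn.SyntheticGenomeSpec(
            genome_length=100_000,
            repeat_families=(syn.RepeatFamilySpec("fam1", 500, 100, 0.0),),
            seed=5,
        )
        genome, truth = syn.generate_genome(spec)
        (seq,) = genome.values()
        consensus = truth.repeat_consensus["fam1"]
        assert len(truth.repeats) == 100
        # every truth placement carries the exact consensus
        for _, row in truth.repeats.iterrows():
            assert seq[row["start"] : row["end"]] == consensus
        # and string search over the genome finds at least those copies
        found, pos = 0, 0
        while (pos := seq.find(consensus, pos)) != -1:
            found += 1
            pos += 1
        assert found >= 100

    def test_same_seed_is_byte_identical(self):
        spec = syn.SyntheticGenomeSpec(
            genome_length=20_000,
            repeat_families=(syn.RepeatFamilySpec("f", 200, 10, 0.05),),
            tandem_specs=(syn.TandemSpec("AG", 12, 5),),
            numt_spec=syn.NumtSpec(mito_length=2_000, n_insertions=3),
            gene_spec=syn.GeneSpec(n_genes=5),
            seed=11,
        )
        g1, t1 = syn.generate_genome(spec)
        g2, t2 = syn.generate_genome(spec)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1.repeats, t2.repeats)
        pd.testing.assert_frame_equal(t1.numts, t2.numts)

    def test_divergent_copies_match_stated_rate(self):
        spec = syn.SyntheticGenomeSpec(
            genome_length=400_000,
            repeat_families=(syn.RepeatFamilySpec("f", 1_000, 100, 0.10),),
            seed=7,
        )
        genome, truth = syn.generate_genome(spec)
        (seq,) = genome.values()
        cons = truth.repeat_consensus["f"]
        mism = sum(
            sum(a != b for a, b in zip(seq[r["start"] : r["end"]], cons))
            for _, r in truth.repeats.iterrows()
        )
        rate = mism / (1_000 * 100)
        # binomial(1e5, 0.1): 3 sigma ~ 0.003
        assert abs(rate - 0.10) < 0.005

    def test_truth_features_lie_within_scaffold(self):
        spec = syn.SyntheticGenomeSpec(
            genome_length=30_000,
            tandem_specs=(syn.TandemSpec("ACG", 10, 8),),
            numt_spec=syn.NumtSpec(mito_length=3_000, n_insertions=4),
            seed=13,
        )
        genome, truth = syn.generate_genome(spec)
        (seq,) = genome.values()
        for df in (truth.tandems, truth.numts):
            assert (df["start"] >= 0).all() and (df["end"] <= len(seq)).all()

    def test_infeasible_packing_rejected(self):
        spec = syn.SyntheticGenomeSpec(
            genome_length=1_000,
            repeat_families=(syn.RepeatFamilySpec("f", 600, 3, 0.0),),
            seed=0,
        )
        with pytest.raises(ValueError, match="genome"):
            syn.generate_genome(spec)


class TestSimulateReads:
    def test_read_count_matches_coverage(self):
        genome, _ = syn.generate_genome(syn.SyntheticGenomeSpec(10_000, seed=1))
        reads = syn.simulate_reads(
            genome, syn.ReadSimSpec(coverage=10, read_length=100, seed=2)
        )
        assert len(reads) == 1_000

    def test_error_free_reads_are_genome_substrings(self, rng):
        from genomesurvey.sequtils import revcomp

        genome, _ = syn.generate_genome(syn.SyntheticGenomeSpec(5_000, seed=4))
        (seq,) = genome.values()
        reads = syn.simulate_reads(
            genome, syn.ReadSimSpec(coverage=5, read_length=80, seed=5)
        )
        for _, r in reads:
            assert r in seq or revcomp(r) in seq

    def test_error_rate_matches_binomial_expectation(self):
        genome, _ = syn.generate_genome(syn.SyntheticGenomeSpec(20_000, seed=6))
        rate = 0.01
        reads = syn.simulate_reads(
            genome,
            syn.ReadSimSpec(coverage=50, read_length=100, error_rate=rate, seed=8),
        )
        assert sum(len(r) for _, r in reads) >= 1_000_000
        # the error-free run at the same seed shares starts and orientations,
        # so position-wise differences count exactly the injected substitutions
        clean = syn.simulate_reads(
            genome, syn.ReadSimSpec(coverage=50, read_length=100, error_rate=0.0, seed=8)
        )
        diffs = sum(
            sum(a != b for a, b in zip(r1, r2))
            for (_, r1), (_, r2) in zip(reads, clean)
        )
        n = sum(len(r) for _, r in reads)
        sd = (rate * (1 - rate) / n) ** 0.5
        assert abs(diffs / n - rate) < 3 * sd

    def test_read_length_longer_than_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="short"):
            syn.simulate_reads(
                {"short": "ACGT" * 10},
                syn.ReadSimSpec(coverage=1, read_length=100, seed=0),
            )


class TestHomologPair:
    def test_zero_rearrangements_gives_one_block_per_scaffold(self):
        pair = syn.generate_homolog_pair(
            syn.HomologPairSpec(n_scaffolds=4), syn.Rearrangements(), seed=3
        )
        assert len(pair.truth_blocks) == 4
        assert (pair.truth_blocks["n_genes"] == 8).all()

    def test_one_mid_scaffold_translocation_splits_into_two_blocks(self):
        pair = syn.generate_homolog_pair(
            syn.HomologPairSpec(n_scaffolds=2, genes_per_scaffold=5),
            syn.Rearrangements(n_translocations=1),
            seed=4,
        )
        # the affected 5-gene scaffold splits into two blocks, the other stays whole
        assert len(pair.truth_blocks) == 3

    def test_unknown_lg_count_bookkeeping(self):
        pair = syn.generate_homolog_pair(
            syn.HomologPairSpec(n_scaffolds=5),
            syn.Rearrangements(n_unknown_lg=3),
            seed=5,
        )
        assert (pair.orthologs["target_lg"] == "unknown").sum() == 3

    def test_too_many_rearrangements_rejected(self):
        with pytest.raises(ValueError, match="rearrangements"):
            syn.generate_homolog_pair(
                syn.HomologPairSpec(n_scaffolds=2, genes_per_scaffold=2),
                syn.Rearrangements(n_translocations=3, n_unknown_lg=3),
                seed=0,
            )


class TestEmitHitTables:
    def _truth_with_numts(self, n, seed=21):
        spec = syn.SyntheticGenomeSpec(
            genome_length=60_000,
            numt_spec=syn.NumtSpec(mito_length=4_000, n_insertions=n),
            seed=seed,
        )
        return syn.generate_genome(spec)

    def test_one_hit_per_true_numt_with_identity_in_range(self):
        _, truth = self._truth_with_numts(5)
        tables = syn.emit_hit_tables(truth, syn.HitNoise(n_decoys=0), seed=1)
        numt = tables["numt"]
        assert len(numt) == 5
        assert ((numt["pident"] >= 85.0) & (numt["pident"] <= 99.0)).all()

    def test_decoys_all_above_evalue_cutoff(self):
        _, truth = self._truth_with_numts(5)
        tables = syn.emit_hit_tables(
            truth, syn.HitNoise(n_decoys=7), seed=2, scaffold_length=60_000
        )
        numt = tables["numt"]
        assert len(numt) == 12
        decoys = numt[numt["evalue"] > 1e-4]
        assert len(decoys) == 7

    def test_empty_truth_gives_empty_tables(self):
        genome, truth = syn.generate_genome(syn.SyntheticGenomeSpec(1_000, seed=0))
        tables = syn.emit_hit_tables(truth, syn.HitNoise(n_decoys=0), seed=0)
        assert tables["numt"].empty and tables["protein"].empty
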