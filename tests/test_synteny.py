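"""Synteny filters, block building, scaffold scoring and summaries."""

import itertools

import pandas as pd
import pytest

from genomesurvey import synthetic as syn
from genomesurvey.synteny import (
    build_blocks,
    filter_synteny_inputs,
    score_scaffold_synteny,
    summarize_synteny,
)


def placements(rows):
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])


def orthologs(rows):
    return pd.DataFrame(rows, columns=["query_gene", "target_gene", "target_scaffold", "target_lg"])


class TestFilters:
    def setup_method(self):
        self.lengths = {"big": 200_000, "small": 50_000}

    def test_multi_mapped_gene_removed(self):
        pl = placements([("g1", "big", 0, 100, "+")])
        orth = orthologs([("g1", "t1", "s", "LG1"), ("g1", "t2", "s", "LG2")])
        _, o = filter_synteny_inputs(pl, orth, self.lengths)
        assert o.empty

    def test_unknown_lg_removed(self):
        pl = placements([("g1", "big", 0, 100, "+")])
        orth = orthologs([("g1", "t1", "s", "unknown")])
        _, o = filter_synteny_inputs(pl, orth, self.lengths)
        assert o.empty

    def test_short_scaffold_removed(self):
        pl = placements([("g1", "small", 0, 100, "+")])
        orth = orthologs([("g1", "t1", "s", "LG1")])
        p, o = filter_synteny_inputs(pl, orth, self.lengths)
        assert p.empty and o.empty

    def test_bookkeeping_twenty_genes(self):
        rows, orth_rows = [], []
        for i in range(20):
            scaf = "small" if i < 5 else "big"
            rows.append((f"g{i}", scaf, i * 1_000, i * 1_000 + 500, "+"))
            lg = "unknown" if i in (5, 6) else "LG1"
            orth_rows.append((f"g{i}", f"t{i}", "s", lg))
        for i in (7, 8, 9):  # multi-mapped
            orth_rows.append((f"g{i}", f"t{i}_dup", "s2", "LG2"))
        p, o = filter_synteny_inputs(placements(rows), orthologs(orth_rows), self.lengths)
        assert len(p) == len(o) == 10

    def test_filters_order_independent(self):
        # applying the three filters in any order yields the same retained set;
        # the combined function must agree with every sequential composition
        rows = [(f"g{i}", "big" if i % 2 else "small", i * 10, i * 10 + 5, "+") for i in range(8)]
        orth_rows = [(f"g{i}", f"t{i}", "s", ["LG1", "unknown"][i % 3 == 0]) for i in range(8)]
        orth_rows.append(("g1", "t1b", "s", "LG2"))
        pl, orth = placements(rows), orthologs(orth_rows)
        lengths = {"big": 200_000, "small": 10}
        base_p, base_o = filter_synteny_inputs(pl, orth, lengths)

        def f_len(p, o):
            keep = {s for s, l in lengths.items() if l >= 100_000}
            return p[p["scaffold"].isin(keep)], o

        def f_multi(p, o):
            vq = o["query_gene"].value_counts()
            vt = o["target_gene"].value_counts()
            o = o[~o["query_gene"].isin(vq[vq > 1].index)]
            return p, o[~o["target_gene"].isin(vt[vt > 1].index)]

        def f_lg(p, o):
            return p, o[o["target_lg"] != "unknown"]

        for perm in itertools.permutations([f_len, f_multi, f_lg]):
            p, o = pl, orth
            for f in perm:
                p, o = f(p, o)
            final_q = set(o["query_gene"]) & set(p["gene_id"])
            assert final_q == set(base_o["query_gene"])

    def test_unknown_scaffold_errors(self):
        with pytest.raises(ValueError, match="unknown scaffold"):
            filter_synteny_inputs(
                placements([("g1", "ghost", 0, 10, "+")]), orthologs([]), self.lengths
            )


class TestBuildBlocks:
    def test_five_genes_one_lg_single_block(self):
        pl = placements([(f"g{i}", "s", i * 10_000, i * 10_000 + 2_000, "+") for i in range(5)])
        orth = orthologs([(f"g{i}", f"t{i}", "x", "LG1") for i in range(5)])
        blocks = build_blocks(pl, orth)
        assert len(blocks) == 1
        b = blocks.iloc[0]
        assert (b["n_genes"], b["start"], b["end"]) == (5, 0, 42_000)

    def test_interrupting_lg_splits_runs(self):
        lgs = ["LG1", "LG1", "LG5", "LG1", "LG1"]
        pl = placements([(f"g{i}", "s", i * 10_000, i * 10_000 + 2_000, "+") for i in range(5)])
        orth = orthologs([(f"g{i}", f"t{i}", "x", lgs[i]) for i in range(5)])
        blocks = build_blocks(pl, orth)
        # the LG5 singleton forms no block; two 2-gene LG1 blocks remain
        assert list(blocks["target_lg"]) == ["LG1", "LG1"]
        assert list(blocks["n_genes"]) == [2, 2]

    def test_short_span_suppressed(self):
        pl = placements([("g1", "s", 0, 150, "+"), ("g2", "s", 750, 900, "+")])
        orth = orthologs([("g1", "t1", "x", "LG1"), ("g2", "t2", "x", "LG1")])
        assert build_blocks(pl, orth, min_block_len=1_000).empty

    def test_filtered_genes_are_transparent_to_adjacency(self):
        pl = placements([(f"g{i}", "s", i * 10_000, i * 10_000 + 2_000, "+") for i in range(3)])
        # g1 filtered out entirely (absent from the ortholog map)
        orth = orthologs([("g0", "t0", "x", "LG1"), ("g2", "t2", "x", "LG1")])
        blocks = build_blocks(pl, orth)
        assert len(blocks) == 1 and blocks.iloc[0]["n_genes"] == 2


class TestScoring:
    def blocks_df(self, rows):
        return pd.DataFrame(rows, columns=["scaffold", "start", "end", "target_lg", "n_genes", "length"])

    def test_single_lg_fully_syntenic(self):
        rep = score_scaffold_synteny(self.blocks_df([("s", 0, 10, "LG3", 2, 10)]))
        assert rep.iloc[0]["fraction_to_modal"] == 1.0 and rep.iloc[0]["syntenic"]

    def test_boundary_fraction_inclusive(self):
        rep = score_scaffold_synteny(self.blocks_df([
            ("s", 0, 9_500, "LG1", 4, 9_500),
            ("s", 10_000, 10_500, "LG2", 2, 500),
        ]))
        assert rep.iloc[0]["fraction_to_modal"] == pytest.approx(0.95)
        assert bool(rep.iloc[0]["syntenic"])

    def test_translocated_run_pushes_scaffold_below_threshold(self):
        pair = syn.generate_homolog_pair(
            syn.HomologPairSpec(n_scaffolds=10), syn.Rearrangements(), seed=8
        )
        orth = pair.orthologs.copy()
        # move two adjacent genes of Ascaf_1 (a >1 kb run, >5% of block bp)
        moved = ["A1g4", "A1g5"]
        orth.loc[orth["query_gene"].isin(moved), ["target_scaffold", "target_lg"]] = "LG9"
        pl, o = filter_synteny_inputs(pair.genes_a, orth, pair.scaffold_lengths)
        reports = score_scaffold_synteny(build_blocks(pl, o))
        assert len(reports) == 10
        flags = dict(zip(reports["scaffold"], reports["syntenic"]))
        assert not flags["Ascaf_1"]
        assert sum(flags.values()) == 9


class TestSummaryAndProperties:
    def test_published_scale_ratio(self):
        reports = pd.DataFrame({
            "scaffold": [f"s{i}" for i in range(329)],
            "total_block_bp": [1_000] * 329,
            "modal_lg": ["LG1"] * 329,
            "fraction_to_modal": [1.0] * 272 + [0.5] * 57,
            "syntenic": [True] * 272 + [False] * 57,
        })
        s = summarize_synteny(reports, {f"s{i}": 2_000 for i in range(329)})
        assert s.pct_syntenic == 83

    def test_empty_reports_all_zero(self):
        s = summarize_synteny(pd.DataFrame(), {})
        assert s.n_scaffolds == 0 and s.pct_syntenic == 0

    def test_zero_rearrangements_every_scaffold_fully_modal(self):
        pair = syn.generate_homolog_pair(
            syn.HomologPairSpec(n_scaffolds=6), syn.Rearrangements(), seed=12
        )
        pl, o = filter_synteny_inputs(pair.genes_a, pair.orthologs, pair.scaffold_lengths)
        reports = score_scaffold_synteny(build_blocks(pl, o))
        assert (reports["fraction_to_modal"] == 1.0).all()

    def test_truth_block_recovery_with_decoys(self):
        pair = syn.generate_homolog_pair(
            syn.HomologPairSpec(), syn.Rearrangements(1, 1, 2, 2), seed=5
        )
        pl, o = filter_synteny_inputs(pair.genes_a, pair.orthologs, pair.scaffold_lengths)
        blocks = build_blocks(pl, o)
        pd.testing.assert_frame_equal(blocks, pair.truth_blocks)

    def test_summary_recomputable_from_truth(self):
        pair = syn.generate_homolog_pair(
            syn.HomologPairSpec(n_scaffolds=10), syn.Rearrangements(2, 0, 1, 1), seed=9
        )
        pl, o = filter_synteny_inputs(pair.genes_a, pair.orthologs, pair.scaffold_lengths)
        reports = score_scaffold_synteny(build_blocks(pl, o))
        lengths = {s: pair.scaffold_lengths[s] for s in reports["scaffold"]}
        s = summarize_synteny(reports, lengths)
        # recompute directly from the generator's truth block list
        t = pair.truth_blocks
        assert s.total_block_bp == int(t["length"].sum())
        per_scaf = t.groupby("scaffold").apply(
            lambda g: g.groupby("target_lg")["length"].sum().max() / g["length"].sum(),
            include_groups=False,
        )
        assert s.n_syntenic == int((per_scaf >= 0.95).sum())
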