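"""Gene-set construction rules: hit filtering, rounds, overlap and similarity filters."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genomesurvey import synthetic as syn
from genomesurvey.annotation import (
    DenovoPrediction,
    GeneModel,
    cds_identity,
    filter_protein_hits,
    merge_denovo,
    ogs_stats,
    resolve_overlaps,
    select_homology_models,
)


def hit(q, e, cov):
    return {
        "qseqid": q, "sseqid": "s1", "pident": 80.0, "length": 100,
        "mismatch": 5, "gapopen": 0, "qstart": 1, "qend": 100,
        "sstart": 1, "send": 300, "evalue": e, "bitscore": 200.0, "qcovs": cov,
    }


def model(mid, scaffold="s1", strand="+", exons=((0, 100),), score=50.0, sim=0.5):
    return GeneModel(
        id=mid, scaffold=scaffold, strand=strand, exons=list(exons),
        score=score, similarity=sim,
    )


class TestFilterProteinHits:
    def test_good_hit_retained(self):
        assert filter_protein_hits(pd.DataFrame([hit("q1", 1e-5, 0.6)])) == {"q1"}

    def test_large_evalue_dropped(self):
        assert filter_protein_hits(pd.DataFrame([hit("q1", 1e-3, 0.9)])) == set()

    def test_boundary_coverage_inclusive(self):
        assert filter_protein_hits(pd.DataFrame([hit("q1", 1e-4, 0.5)])) == {"q1"}

    def test_synthetic_bookkeeping_with_subthreshold_queries(self):
        rows = [hit(f"q{i}", 1e-8, 0.8) for i in range(60)]
        rows += [hit(f"bad{i}", 1e-2, 0.9) for i in range(20)]
        rows += [hit(f"low{i}", 1e-8, 0.2) for i in range(20)]
        assert len(filter_protein_hits(pd.DataFrame(rows))) == 60

    def test_coverage_derived_from_coordinates_needs_length(self):
        df = pd.DataFrame([{k: v for k, v in hit("q1", 1e-6, 0.9).items() if k != "qcovs"}])
        with pytest.raises(ValueError, match="q1"):
            filter_protein_hits(df)
        got = filter_protein_hits(df, query_lengths={"q1": 120})
        assert got == {"q1"}  # (100-1+1)/120 = 0.83


class TestSelectHomologyModels:
    def test_round1_takes_best_scoring_model(self):
        cands = {"q": [model("m1", sim=0.50, score=90), model("m2", sim=0.40, score=80)]}
        accepted, un = select_homology_models(cands)
        assert [m.id for m in accepted] == ["m1"]
        assert accepted[0].annotation_round == 1 and not un

    def test_round2_rescues_weak_query(self):
        accepted, un = select_homology_models({"q": [model("m", sim=0.20)]})
        assert accepted[0].annotation_round == 2 and not un

    def test_query_below_round2_unannotated(self):
        accepted, un = select_homology_models({"q": [model("m", sim=0.10)]})
        assert accepted == [] and un == {"q"}

    def test_every_query_classified_exactly_once(self, rng):
        cands = {
            f"q{i}": [model(f"m{i}", sim=float(rng.uniform(0, 0.9)))]
            for i in range(50)
        }
        accepted, un = select_homology_models(cands)
        r1 = sum(1 for m in accepted if m.annotation_round == 1)
        r2 = sum(1 for m in accepted if m.annotation_round == 2)
        assert r1 + r2 + len(un) == 50


class TestResolveOverlaps:
    def test_same_strand_overlap_keeps_best_score(self):
        a = model("a", exons=[(0, 100)], score=80)
        b = model("b", exons=[(50, 150)], score=95)
        assert [m.id for m in resolve_overlaps([a, b])] == ["b"]

    def test_opposite_strand_overlaps_untouched(self):
        a = model("a", strand="+", exons=[(0, 100)])
        b = model("b", strand="-", exons=[(50, 150)])
        assert len(resolve_overlaps([a, b])) == 2

    def test_transitive_chain_single_survivor(self):
        # A overlaps B, B overlaps C, A does not overlap C -> one survivor
        a = model("a", exons=[(0, 100)], score=70)
        b = model("b", exons=[(80, 220)], score=60)
        c = model("c", exons=[(200, 300)], score=90)
        out = resolve_overlaps([a, b, c])
        assert [m.id for m in out] == ["c"]

    def test_brute_force_component_enumeration_on_ten_models(self, rng):
        models = []
        for i in range(10):
            s = int(rng.integers(0, 500))
            models.append(model(f"m{i}", exons=[(s, s + int(rng.integers(40, 120)))],
                                score=float(rng.integers(0, 100))))
        out = resolve_overlaps(models)
        # brute force: transitive closure of the overlap relation
        def overlaps(x, y):
            return x.start < y.end and y.start < x.end
        comp = {m.id: {m.id} for m in models}
        changed = True
        while changed:
            changed = False
            for x, y in itertools.combinations(models, 2):
                if overlaps(x, y) and comp[x.id] != comp[y.id]:
                    merged = comp[x.id] | comp[y.id]
                    for mid in merged:
                        comp[mid] = merged
                    changed = True
        expected = set()
        for group in {frozenset(v) for v in comp.values()}:
            members = [m for m in models if m.id in group]
            expected.add(min(members, key=lambda m: (-m.score, -m.span, m.id)).id)
        assert {m.id for m in out} == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 100), st.integers(0, 50),
                      st.sampled_from("+-")),
            min_size=1, max_size=12,
        )
    )
    def test_no_same_strand_overlaps_survive(self, raw):
        models = [
            model(f"m{i}", strand=strand, exons=[(s, s + l)], score=float(sc))
            for i, (s, l, sc, strand) in enumerate(raw)
        ]
        out = resolve_overlaps(models)
        for x, y in itertools.combinations(out, 2):
            if x.scaffold == y.scaffold and x.strand == y.strand:
                assert not (x.start < y.end and y.start < x.end)


def pred(pid, s, e, cds, scaffold="s1", strand="+"):
    return DenovoPrediction(id=pid, scaffold=scaffold, strand=strand,
                            exons=[(s, e)], cds=cds)


class TestMergeDenovo:
    def test_prediction_without_counterpart_excluded(self):
        out = merge_denovo([pred("a", 0, 100, "ATG" * 30)], [], [])
        assert out == []

    def test_ninety_percent_identical_pair_both_dropped(self):
        cds1 = "ATGAAACCCGGGTTT" * 6
        cds2 = cds1[:-6] + "CATCAT"  # ~93% identical
        assert cds_identity(cds1, cds2) >= 0.85
        a1, a2 = pred("a1", 0, 100, cds1), pred("a2", 300, 400, cds2)
        b1, b2 = pred("b1", 0, 100, cds1), pred("b2", 300, 400, cds2)
        assert merge_denovo([a1, a2], [b1, b2], []) == []

    def test_keep_one_flag_retains_first(self):
        cds = "ATGAAACCCGGGTTT" * 6
        a1, a2 = pred("a1", 0, 100, cds), pred("a2", 300, 400, cds)
        out = merge_denovo([a1, a2], [pred("b1", 0, 100, cds), pred("b2", 300, 400, cds)],
                           [], keep_one=True)
        assert [m.id for m in out] == ["a1"]

    def test_survivor_overlapping_homology_not_appended(self):
        hom = [model("h", exons=[(0, 200)])]
        a = pred("a", 50, 150, "ATGCCC" * 20)
        free = pred("f", 1_000, 1_100, "TTTAGG" * 20)
        out = merge_denovo([a, free], [pred("b", 50, 150, "X" * 10), pred("g", 1_000, 1_100, "Y" * 10)],
                           hom)
        assert {m.id for m in out} == {"h", "f"}
        assert next(m for m in out if m.id == "f").source == "denovo"

    def test_idempotent_on_own_output(self):
        a = pred("a", 0, 100, "ATGAAACCC" * 10)
        b = pred("b", 500, 600, "TTTGGGCCC" * 10)
        out1 = merge_denovo([a, b], [pred("a2", 0, 100, "Q"), pred("b2", 500, 600, "Q")], [])
        assert {m.id for m in out1} == {"a", "b"}
        out2 = merge_denovo([a, b], [a, b], out1)
        assert {m.id for m in out2} == {"a", "b"}

    def test_zero_exon_prediction_rejected(self):
        with pytest.raises(ValueError, match="zero exons"):
            DenovoPrediction(id="x", scaffold="s", strand="+", exons=[], cds="A")


class TestOgsStats:
    def test_published_scale_ratio(self):
        ogs = [model(f"h{i}") for i in range(11_139)]
        ogs += [GeneModel(id=f"d{i}", scaffold="s", strand="+", exons=[(0, 10)],
                          source="denovo") for i in range(4_765)]
        stats = ogs_stats(ogs, donor_set_size=15_314)
        assert stats.n_total == 15_904
        assert stats.homology_percentage == 73

    def test_zero_and_full_homology(self):
        assert ogs_stats([], 100).homology_percentage == 0
        ogs = [model(f"h{i}") for i in range(100)]
        assert ogs_stats(ogs, 100).homology_percentage == 100

    def test_invalid_donor_size(self):
        with pytest.raises(ValueError):
            ogs_stats([], 0)
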