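"""Homology-based and de novo gene-set construction rules.

The gene set is built from precomputed alignment evidence, not by running an
alignment engine: protein-to-genome hits (BLAST-style tables) are filtered
by E-value and query coverage; spliced candidate models carrying a
similarity score are accepted in two rounds of decreasing stringency (35%
then 15% of the optimal similarity); same-strand overlapping models are
reduced to the best-scoring one; and de novo predictions supported by two
independent predictors are appended where the homology set left gaps, after
discarding near-identical (>=85%) prediction pairs that likely stem from
unmasked transposable elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd


@dataclass
class GeneModel:
    id: str
    scaffold: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # sorted, non-overlapping, half-open
    source: str = "homology"  # 'homology' | 'denovo'
    donor: str | None = None  # donor protein/gene id for homology models
    score: float = 0.0
    similarity: float | None = None  # fraction of optimal alignment similarity
    annotation_round: int | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene model {self.id} has zero exons")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"gene model {self.id} has overlapping exons")
        self.exons = ex

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class DenovoPrediction:
    id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str  # coding sequence used by the pairwise-similarity filter

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"prediction {self.id} has zero exons")
        self.exons = sorted(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class OGSStats:
    n_total: int
    n_homology: int
    n_denovo_added: int
    donor_set_size: int
    homology_percentage: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------


def filter_protein_hits(
    hits: pd.DataFrame,
    e_max: float = 1e-4,
    min_query_cov: float = 0.5,
    query_lengths: dict[str, int] | None = None,
) -> set[str]:
    """Donor proteins retained for homology annotation.

    A query is retained iff it has at least one hit with e-value <= `e_max`
    and query coverage >= `min_query_cov` (boundaries inclusive).  Coverage
    is taken from the ``qcovs`` column when present, otherwise derived from
    qstart/qend and the query length.
    """
    if hits.empty:
        return set()
    df = hits.copy()
    if "qcovs" not in df.columns or df["qcovs"].isna().any():
        if query_lengths is None:
            missing = df["qseqid"].iloc[0]
            raise ValueError(
                f"query coverage absent and no query length available for {missing!r}"
            )
        covs = []
        for _, row in df.iterrows():
            q = row["qseqid"]
            if q not in query_lengths:
                raise ValueError(f"no query length for {q!r}")
            covs.append((abs(row["qend"] - row["qstart"]) + 1) / query_lengths[q])
        df["qcovs"] = covs
    good = df[(df["evalue"] <= e_max) & (df["qcovs"] >= min_query_cov)]
    return set(good["qseqid"])


def select_homology_models(
    candidates: dict[str, list[GeneModel]],
    round1: float = 0.35,
    round2: float = 0.15,
) -> tuple[list[GeneModel], set[str]]:
    """Two-round similarity gating of candidate homology models.

    Per query: accept the best-scoring model with similarity >= `round1`;
    queries with none are retried at `round2`; queries failing both remain
    unannotated.  Returns (accepted models, unannotated query ids); each
    accepted model records the round that admitted it.
    """
    accepted: list[GeneModel] = []
    unannotated: set[str] = set()
    for query, models in candidates.items():
        chosen = None
        for rnd, thr in ((1, round1), (2, round2)):
            viable = [m for m in models if (m.similarity or 0.0) >= thr]
            if viable:
                chosen = max(viable, key=lambda m: (m.score, m.span, m.id))
                chosen.annotation_round = rnd
                break
        if chosen is None:
            unannotated.add(query)
        else:
            accepted.append(chosen)
    return accepted, unannotated


def _overlap_components(models: list) -> list[list]:
    """Connected components of span-overlapping models (single sweep)."""
    comps: list[list] = []
    cur: list = []
    cur_end = -1
    for m in sorted(models, key=lambda m: (m.start, m.end)):
        if cur and m.start < cur_end:
            cur.append(m)
            cur_end = max(cur_end, m.end)
        else:
            if cur:
                comps.append(cur)
            cur = [m]
            cur_end = m.end
    if cur:
        comps.append(cur)
    return comps


def resolve_overlaps(models: list[GeneModel]) -> list[GeneModel]:
    """Reduce same-strand overlapping models to the single best one.

    Within each connected component of same-strand span-overlapping models
    exactly one survives: maximum score, ties to the longer span, then the
    lexicographically smaller id.  Opposite-strand overlaps are untouched.
    """
    out: list[GeneModel] = []
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        groups.setdefault((m.scaffold, m.strand), []).append(m)
    for group in groups.values():
        for comp in _overlap_components(group):
            out.append(min(comp, key=lambda m: (-m.score, -m.span, m.id)))
    return sorted(out, key=lambda m: (m.scaffold, m.start, m.id))


def _reciprocal_overlap(a, b) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.span, ov / b.span)


def cds_identity(a: str, b: str) -> float:
    """Global (end-to-end, unit-cost) identity of two coding sequences."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a.upper(), b.upper(), mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def merge_denovo(
    predictions_a: list[DenovoPrediction],
    predictions_b: list[DenovoPrediction],
    homology_set: list[GeneModel],
    min_reciprocal_overlap: float = 0.5,
    max_pairwise_similarity: float = 0.85,
    keep_one: bool = False,
) -> list[GeneModel]:
    """Final OGS: homology models plus consensus de novo additions.

    1. consensus = predictions from set A with a same-strand counterpart in
       set B at reciprocal span overlap >= `min_reciprocal_overlap`;
    2. any consensus pair with coding-sequence identity >=
       `max_pairwise_similarity` is removed entirely (both members; with
       ``keep_one`` the lexicographically first member survives);
    3. survivors overlapping no homology model on either strand of the same
       scaffold are appended as source='denovo'.
    """
    consensus = []
    for a in predictions_a:
        for b in predictions_b:
            if (
                a.scaffold == b.scaffold
                and a.strand == b.strand
                and _reciprocal_overlap(a, b) >= min_reciprocal_overlap
            ):
                consensus.append(a)
                break

    consensus = sorted(consensus, key=lambda p: p.id)
    dropped: set[str] = set()
    for i, a in enumerate(consensus):
        for b in consensus[i + 1 :]:
            if cds_identity(a.cds, b.cds) >= max_pairwise_similarity:
                if keep_one:
                    dropped.add(b.id)
                else:
                    dropped.add(a.id)
                    dropped.add(b.id)
    survivors = [p for p in consensus if p.id not in dropped]

    by_scaffold: dict[str, list[GeneModel]] = {}
    for h in homology_set:
        by_scaffold.setdefault(h.scaffold, []).append(h)
    added = []
    for p in survivors:
        clash = any(
            p.start < h.end and h.start < p.end
            for h in by_scaffold.get(p.scaffold, [])
        )
        if not clash:
            added.append(
                GeneModel(
                    id=p.id,
                    scaffold=p.scaffold,
                    strand=p.strand,
                    exons=p.exons,
                    source="denovo",
                )
            )
    return list(homology_set) + added


def ogs_stats(ogs: list[GeneModel], donor_set_size: int) -> OGSStats:
    """Headline gene-set statistics, including the homology share of the donor set."""
    if donor_set_size <= 0:
        raise ValueError("donor_set_size must be positive")
    n_hom = sum(1 for m in ogs if m.source == "homology")
    n_dn = sum(1 for m in ogs if m.source == "denovo")
    return OGSStats(
        n_total=len(ogs),
        n_homology=n_hom,
        n_denovo_added=n_dn,
        donor_set_size=donor_set_size,
        homology_percentage=int(round(100.0 * n_hom / donor_set_size)),
    )
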