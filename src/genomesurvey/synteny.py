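"""Haplotype-block construction from ortholog gene order and synteny scoring.

Scaffolds of the query genome are compared against a chromosome-scale
reference through the genomic locations of orthologous genes.  Three filters
precede block building: scaffolds shorter than 100 kb are ignored, genes
homologous to multiple genomic locations in either species are discarded,
and genes whose reference target belongs to an unknown linkage group (LG)
are excluded.  Blocks are maximal runs of >=2 consecutive retained genes on
a scaffold whose targets share one LG; a block spans from the first gene
start to the last gene end (intergenic DNA included) and must be at least
1 kb long.  A scaffold counts as syntenic when >=95% of its block base pairs
point at a single LG.

Filtered-out genes are transparent to adjacency (they do not break runs); a
retained gene targeting a different LG does.  Target gene order within a
block is not enforced — blocks check shared location, not collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

UNKNOWN_LG = "unknown"


@dataclass
class SyntenySummary:
    n_scaffolds: int
    n_syntenic: int
    pct_syntenic: int  # rounded to integer
    total_block_bp: int
    block_bp_pct_of_filtered: float  # % of total filtered scaffold length

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def filter_synteny_inputs(
    placements: pd.DataFrame,  # gene_id, scaffold, start, end, strand
    orthologs: pd.DataFrame,  # query_gene, target_gene, target_scaffold, target_lg
    scaffold_lengths: dict[str, int],
    min_scaffold_len: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three synteny input filters; afterwards the map is one-to-one.

    Filters (order-independent): scaffold length >= `min_scaffold_len`;
    genes with multiple target locations or targets hit by multiple genes
    removed; unknown-LG targets removed.
    """
    unknown_scafs = set(placements["scaffold"]) - set(scaffold_lengths)
    if unknown_scafs:
        raise ValueError(f"placements on unknown scaffolds: {sorted(unknown_scafs)[:5]}")

    keep_scaf = {s for s, l in scaffold_lengths.items() if l >= min_scaffold_len}
    pl = placements[placements["scaffold"].isin(keep_scaf)]

    orth = orthologs.copy()
    multi_q = orth["query_gene"].value_counts()
    multi_t = orth["target_gene"].value_counts()
    bad_q = set(multi_q[multi_q > 1].index)
    bad_t_genes = set(multi_t[multi_t > 1].index)
    orth = orth[~orth["query_gene"].isin(bad_q)]
    orth = orth[~orth["target_gene"].isin(bad_t_genes)]
    orth = orth[orth["target_lg"] != UNKNOWN_LG]

    orth = orth[orth["query_gene"].isin(set(pl["gene_id"]))]
    pl = pl[pl["gene_id"].isin(set(orth["query_gene"]))]
    return pl.reset_index(drop=True), orth.reset_index(drop=True)


def build_blocks(
    placements: pd.DataFrame,
    orthologs: pd.DataFrame,
    min_block_len: int = 1_000,
) -> pd.DataFrame:
    """Haplotype blocks from runs of same-LG consecutive retained genes.

    Returns columns: scaffold, start, end, target_lg, n_genes, length.
    Runs with fewer than 2 genes or spans below `min_block_len` are dropped.
    """
    lg_of = dict(zip(orthologs["query_gene"], orthologs["target_lg"]))
    rows = []
    for scaf, grp in placements.groupby("scaffold", sort=False):
        grp = grp.sort_values(["start", "end"])
        run: list[tuple[int, int]] = []
        run_lg = None

        def flush():
            if run_lg is not None and len(run) >= 2:
                start = run[0][0]
                end = max(e for _, e in run)
                if end - start >= min_block_len:
                    rows.append((scaf, start, end, run_lg, len(run), end - start))

        for _, g in grp.iterrows():
            lg = lg_of.get(g["gene_id"])
            if lg is None:
                continue
            if lg == run_lg:
                run.append((int(g["start"]), int(g["end"])))
            else:
                flush()
                run = [(int(g["start"]), int(g["end"]))]
                run_lg = lg
        flush()
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "target_lg", "n_genes", "length"]
    ).sort_values(["scaffold", "start"], ignore_index=True)


def score_scaffold_synteny(blocks: pd.DataFrame, threshold: float = 0.95) -> pd.DataFrame:
    """Per-scaffold synteny: block bp pointing at the modal target LG.

    Returns columns: scaffold, total_block_bp, modal_lg, fraction_to_modal,
    syntenic (fraction >= threshold, inclusive).  Modal ties break to the LG
    with more genes, then lexicographically.  Scaffolds without blocks do not
    appear.
    """
    rows = []
    for scaf, grp in blocks.groupby("scaffold", sort=False):
        total = int(grp["length"].sum())
        per_lg = grp.groupby("target_lg").agg(
            bp=("length", "sum"), genes=("n_genes", "sum")
        )
        per_lg = per_lg.sort_values(
            ["bp", "genes"], ascending=[False, False], kind="stable"
        )
        top_bp = per_lg["bp"].iloc[0]
        tied = per_lg[per_lg["bp"] == top_bp]
        top_genes = tied["genes"].max()
        modal = sorted(tied[tied["genes"] == top_genes].index)[0]
        frac = per_lg.loc[modal, "bp"] / total if total else 0.0
        rows.append((scaf, total, modal, float(frac), bool(frac >= threshold)))
    return pd.DataFrame(
        rows,
        columns=["scaffold", "total_block_bp", "modal_lg", "fraction_to_modal", "syntenic"],
    ).sort_values("scaffold", ignore_index=True)


def summarize_synteny(
    reports: pd.DataFrame, filtered_scaffold_lengths: dict[str, int]
) -> SyntenySummary:
    """Genome-level synteny summary over the per-scaffold reports."""
    if reports.empty:
        return SyntenySummary(0, 0, 0, 0, 0.0)
    n = len(reports)
    n_syn = int(reports["syntenic"].sum())
    total_bp = int(reports["total_block_bp"].sum())
    denom = sum(filtered_scaffold_lengths.values())
    return SyntenySummary(
        n_scaffolds=n,
        n_syntenic=n_syn,
        pct_syntenic=int(round(100.0 * n_syn / n)),
        total_block_bp=total_bp,
        block_bp_pct_of_filtered=round(100.0 * total_bp / denom, 1) if denom else 0.0,
    )
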