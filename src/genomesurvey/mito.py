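"""Mitogenome completeness and gene-order checks on transcript scaffolds.

Mitochondrial genes are expressed almost everywhere, so a fragmented
mitogenome can be reconstructed from transcriptome scaffolds: scaffolds are
first screened by blastx-style hits against a reference mitogenome at a
stringent E-value cutoff (1e-12), their gene annotations are then compared
against the reference gene order — the mitochondrial molecule is circular
and a scaffold may derive from either strand, so a scaffold is
order-consistent when its genes form a contiguous run of the circular
reference order in either direction with strands consistent under that
direction — and completeness is the annotated base-pair total over the
reference mitogenome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MITO_CLASSES = ("protein_coding", "tRNA", "rRNA")


@dataclass
class ReferenceGeneOrder:
    """Circular ordered gene inventory of a reference mitogenome."""

    genes: list[tuple[str, str, str, int]]  # (name, class, strand, length)
    total_length: int  # reference mitogenome length, bases

    def __post_init__(self):
        names = [g[0] for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError("reference gene names must be unique")
        for name, cls, strand, length in self.genes:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
            if cls not in MITO_CLASSES:
                raise ValueError(f"unknown gene class {cls!r} for {name}")

    @property
    def names(self) -> list[str]:
        return [g[0] for g in self.genes]

    @property
    def strand_of(self) -> dict[str, str]:
        return {g[0]: g[2] for g in self.genes}

    @property
    def class_of(self) -> dict[str, str]:
        return {g[0]: g[1] for g in self.genes}

    @property
    def length_of(self) -> dict[str, int]:
        return {g[0]: g[3] for g in self.genes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genes, columns=["gene", "class", "strand", "length"])


@dataclass
class MitoReport:
    n_protein_coding_complete: int
    n_protein_coding_partial: int
    n_trna: int
    n_rrna: int
    total_annotated_bp: int
    completeness: float
    order_consistent: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def synthetic_reference_order() -> ReferenceGeneOrder:
    """Stylized hymenopteran-like mitogenome inventory (synthetic defaults).

    13 protein-coding genes, 22 tRNAs and 2 rRNAs in a typical insect
    arrangement with approximate gene lengths; the total length (~16.3 kb)
    is a honey-bee-like constant.  Intended as a testing default — real
    analyses should supply the reference of their focal taxon.
    """
    pcg = [
        ("ND2", 1002), ("COX1", 1566), ("COX2", 678), ("ATP8", 159),
        ("ATP6", 678), ("COX3", 780), ("ND3", 354), ("ND5", 1665),
        ("ND4", 1341), ("ND4L", 264), ("ND6", 516), ("CYTB", 1149),
        ("ND1", 918),
    ]
    trna_names = [
        "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK",
        "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
        "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
    ]
    # interleave: stylized order loosely following the ancestral insect plan
    order: list[tuple[str, str, str, int]] = []
    minus = {"trnQ", "trnC", "trnY", "trnF", "trnH", "trnP", "trnL1", "trnV",
             "ND5", "ND4", "ND4L", "ND1", "16S", "12S"}

    def add(name, cls, length):
        order.append((name, cls, "-" if name in minus else "+", length))

    add("trnI", "tRNA", 70); add("trnQ", "tRNA", 70); add("trnM", "tRNA", 70)
    add("ND2", "protein_coding", 1002)
    add("trnW", "tRNA", 70); add("trnC", "tRNA", 70); add("trnY", "tRNA", 70)
    add("COX1", "protein_coding", 1566)
    add("trnL2", "tRNA", 70)
    add("COX2", "protein_coding", 678)
    add("trnK", "tRNA", 70); add("trnD", "tRNA", 70)
    add("ATP8", "protein_coding", 159)
    add("ATP6", "protein_coding", 678)
    add("COX3", "protein_coding", 780)
    add("trnG", "tRNA", 70)
    add("ND3", "protein_coding", 354)
    add("trnA", "tRNA", 70); add("trnR", "tRNA", 70); add("trnN", "tRNA", 70)
    add("trnS1", "tRNA", 70); add("trnE", "tRNA", 70); add("trnF", "tRNA", 70)
    add("ND5", "protein_coding", 1665)
    add("trnH", "tRNA", 70)
    add("ND4", "protein_coding", 1341)
    add("ND4L", "protein_coding", 264)
    add("trnT", "tRNA", 70); add("trnP", "tRNA", 70)
    add("ND6", "protein_coding", 516)
    add("CYTB", "protein_coding", 1149)
    add("trnS2", "tRNA", 70)
    add("ND1", "protein_coding", 918)
    add("trnL1", "tRNA", 70)
    add("16S", "rRNA", 1300)
    add("trnV", "tRNA", 70)
    add("12S", "rRNA", 800)
    assert len([g for g in order if g[1] == "tRNA"]) == 22
    # genes treated as abutting: the default reference length is the gene
    # total, so annotating every reference gene yields completeness 1.0; the
    # A+T-rich control region is excluded (supply a custom total_length to
    # include it)
    return ReferenceGeneOrder(genes=order, total_length=sum(g[3] for g in order))


# ---------------------------------------------------------------------------


def identify_mito_scaffolds(hits: pd.DataFrame, e_max: float = 1e-12) -> set[str]:
    """Scaffolds with at least one reference-mitogenome hit at e <= e_max."""
    if hits.empty:
        return set()
    return set(hits.loc[hits["evalue"] <= e_max, "sseqid"])


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def check_gene_order(
    scaffold_genes: list[tuple[str, str]],  # (gene name, strand) in scaffold order
    reference: ReferenceGeneOrder,
) -> bool:
    """True iff the genes form a contiguous run of the circular reference order.

    Both directions are tried: forward (gene names match a circular slice of
    the reference and strands equal the reference strands) and reverse (the
    reversed gene list matches a slice with all strands flipped) — a scaffold
    may be assembled from either strand of the circular molecule.
    """
    names = reference.names
    ref_strand = reference.strand_of
    for g, _ in scaffold_genes:
        if g not in ref_strand:
            raise ValueError(f"annotation names unknown gene {g!r}")
    k = len(scaffold_genes)
    if k == 0:
        return True
    m = len(names)
    if k > m:
        return False
    for offset in range(m):
        window = [names[(offset + i) % m] for i in range(k)]
        if [g for g, _ in scaffold_genes] == window and all(
            s == ref_strand[g] for g, s in scaffold_genes
        ):
            return True
        rev = [(g, _flip(s)) for g, s in reversed(scaffold_genes)]
        if [g for g, _ in rev] == window and all(
            s == ref_strand[g] for g, s in rev
        ):
            return True
    return False


def mito_completeness(
    annotations: pd.DataFrame,  # scaffold, gene, start, end, strand
    reference: ReferenceGeneOrder,
) -> MitoReport:
    """Inventory counts, annotated length and completeness vs the reference.

    A protein-coding gene is partial when its annotated length is below the
    reference gene length; an annotation exceeding the reference length by
    more than 10% is rejected as suspect.
    """
    length_of = reference.length_of
    class_of = reference.class_of
    n_pc_complete = n_pc_partial = n_trna = n_rrna = 0
    total_bp = 0
    if not annotations.empty:
        for _, row in annotations.iterrows():
            g = row["gene"]
            if g not in length_of:
                raise ValueError(f"annotation names unknown gene {g!r}")
            alen = int(row["end"] - row["start"])
            if alen > 1.1 * length_of[g]:
                raise ValueError(
                    f"annotated length {alen} of {g} exceeds reference "
                    f"length {length_of[g]} by more than 10%"
                )
            total_bp += alen
        for g, grp in annotations.groupby("gene"):
            alen = int((grp["end"] - grp["start"]).sum())
            cls = class_of[g]
            if cls == "protein_coding":
                if alen < length_of[g]:
                    n_pc_partial += 1
                else:
                    n_pc_complete += 1
            elif cls == "tRNA":
                n_trna += 1
            else:
                n_rrna += 1

    order_flags = {}
    if not annotations.empty:
        for scaf, grp in annotations.groupby("scaffold"):
            grp = grp.sort_values("start")
            order_flags[scaf] = check_gene_order(
                list(zip(grp["gene"], grp["strand"])), reference
            )
    return MitoReport(
        n_protein_coding_complete=n_pc_complete,
        n_protein_coding_partial=n_pc_partial,
        n_trna=n_trna,
        n_rrna=n_rrna,
        total_annotated_bp=int(total_bp),
        completeness=total_bp / reference.total_length,
        order_consistent=order_flags,
    )
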