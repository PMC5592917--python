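"""NUMT scan summaries, repeat-element content tables, read-based repeat fraction.

Three independent views of repetitive content:

* NUMTs — nuclear insertions of mitochondrial DNA, recognized as blastn hits
  of the mitogenome against the assembly at E <= 1e-4 and summarized after
  merging overlapping hits;
* assembly repeat content — per-class (retrotransposon / DNA transposon /
  unclassified) family, element and cumulative-length accounting over
  RepeatMasker-style annotations, with percentages over the assembly length
  excluding ambiguous (N) stretches;
* read-based repeat fraction — high-copy contigs discovered from raw reads
  carry mean depth proportional to their genomic copy number, so
  length_i * (depth_i / C) estimates the genomic base pairs each contig
  represents; summing over contigs whose depth clears a minimum-frequency
  threshold and dividing by the estimated genome size G gives the fraction
  of the genome in highly abundant sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from genomesurvey.sequtils import merge_intervals, non_ambiguous_length

REPEAT_CLASSES = ("retrotransposon", "dna_transposon", "unclassified")


@dataclass
class NumtSummary:
    n_scaffolds_with_hits: int
    n_fragments: int
    total_bp: int
    mean_fragment_length: float
    mean_identity: float  # proportion in [0, 1]
    assembly_fraction: float  # of non-ambiguous assembly length
    per_scaffold_bp: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("per_scaffold_bp")
        d["max_concatenated_bp"] = max(self.per_scaffold_bp.values(), default=0)
        return d


@dataclass
class RepeatClassRow:
    n_families: int
    n_elements: int
    cumulative_length: int
    percent_of_assembly: float  # excluding N stretches, 1 decimal


@dataclass
class RepeatContentTable:
    rows: dict[str, RepeatClassRow]  # per class + 'classified' + 'total'
    classified_family_pct: float  # share of families with a known TE class
    classified_element_pct: float

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "repeat_class": name,
                "n_families": r.n_families,
                "n_elements": r.n_elements,
                "cumulative_length": r.cumulative_length,
                "percent_of_assembly": r.percent_of_assembly,
            }
            for name, r in self.rows.items()
        ]
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------


def _normalize_interval(s, e):
    s, e = int(s), int(e)
    return (s, e) if s <= e else (e, s)


def summarize_numts(
    hits: pd.DataFrame,
    assembly: dict[str, str],
    e_max: float = 1e-4,
    length_weighted: bool = True,
) -> NumtSummary:
    """Summary of mitogenome blastn hits against the nuclear assembly.

    Hits with e-value <= `e_max` are retained; overlapping hits on a scaffold
    are merged into fragments with length-weighted identity.  The assembly
    fraction uses the non-ambiguous assembly length as denominator.
    """
    denom = non_ambiguous_length(assembly)
    if hits.empty:
        return NumtSummary(0, 0, 0, 0.0, 0.0, 0.0, {})
    good = hits[hits["evalue"] <= e_max]
    frags: list[tuple[str, int, int, float]] = []
    for scaf, grp in good.groupby("sseqid"):
        if scaf not in assembly:
            raise ValueError(f"hit on unknown scaffold {scaf!r}")
        ivs = []
        for _, row in grp.iterrows():
            s, e = _normalize_interval(row["sstart"] - 1, row["send"])
            if e > len(assembly[scaf]) or s < 0:
                raise ValueError(f"hit beyond scaffold bounds on {scaf!r}: {s}-{e}")
            ivs.append((s, e, float(row["pident"]) / 100.0))
        for ms, me in merge_intervals([(s, e) for s, e, _ in ivs]):
            members = [(s, e, p) for s, e, p in ivs if s < me and ms < e]
            w = sum(e - s for s, e, _ in members)
            ident = sum((e - s) * p for s, e, p in members) / w if w else 0.0
            frags.append((scaf, ms, me, ident))
    if not frags:
        return NumtSummary(0, 0, 0, 0.0, 0.0, 0.0, {})
    total_bp = sum(e - s for _, s, e, _ in frags)
    if length_weighted:
        mean_ident = sum((e - s) * p for _, s, e, p in frags) / total_bp
    else:
        mean_ident = sum(p for *_, p in frags) / len(frags)
    per_scaf: dict[str, int] = {}
    for scaf, s, e, _ in frags:
        per_scaf[scaf] = per_scaf.get(scaf, 0) + (e - s)
    return NumtSummary(
        n_scaffolds_with_hits=len(per_scaf),
        n_fragments=len(frags),
        total_bp=int(total_bp),
        mean_fragment_length=total_bp / len(frags),
        mean_identity=mean_ident,
        assembly_fraction=(total_bp / denom) if denom else 0.0,
        per_scaffold_bp=per_scaf,
    )


def aggregate_repeat_annotations(
    annotations: pd.DataFrame,  # family, scaffold, start, end (half-open)
    catalog: dict[str, str],  # family -> class label
    assembly: dict[str, str],
) -> RepeatContentTable:
    """Table-style repeat-content report over per-copy annotations.

    Family counts come from the catalog; element counts and overlap-merged
    cumulative lengths per class from the annotations; percentages use the
    assembly length excluding ambiguous stretches, rounded to one decimal.
    """
    for cls in set(catalog.values()):
        if cls not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {cls!r}")
    unknown = set(annotations["family"]) - set(catalog) if not annotations.empty else set()
    if unknown:
        raise ValueError(f"annotations cite unknown families: {sorted(unknown)[:5]}")

    denom = non_ambiguous_length(assembly)
    rows: dict[str, RepeatClassRow] = {}
    fam_by_class = {cls: [f for f, c in catalog.items() if c == cls] for cls in REPEAT_CLASSES}

    def class_stats(families):
        fams = set(families)
        if annotations.empty:
            return 0, 0
        sub = annotations[annotations["family"].isin(fams)]
        n_el = len(sub)
        length = 0
        for _, grp in sub.groupby("scaffold"):
            length += sum(
                e - s for s, e in merge_intervals(zip(grp["start"], grp["end"]))
            )
        return n_el, length

    for cls in REPEAT_CLASSES:
        n_el, length = class_stats(fam_by_class[cls])
        rows[cls] = RepeatClassRow(
            n_families=len(fam_by_class[cls]),
            n_elements=n_el,
            cumulative_length=length,
            percent_of_assembly=round(100.0 * length / denom, 1) if denom else 0.0,
        )
    classified = [rows["retrotransposon"], rows["dna_transposon"]]
    for name, members in (("classified", classified), ("total", list(rows.values())[:3])):
        rows[name] = RepeatClassRow(
            n_families=sum(r.n_families for r in members),
            n_elements=sum(r.n_elements for r in members),
            cumulative_length=sum(r.cumulative_length for r in members),
            percent_of_assembly=round(
                100.0 * sum(r.cumulative_length for r in members) / denom, 1
            )
            if denom
            else 0.0,
        )
    total_fams = rows["total"].n_families
    total_els = rows["total"].n_elements
    return RepeatContentTable(
        rows=rows,
        classified_family_pct=round(100.0 * rows["classified"].n_families / total_fams, 1)
        if total_fams
        else 0.0,
        classified_element_pct=round(100.0 * rows["classified"].n_elements / total_els, 1)
        if total_els
        else 0.0,
    )


def estimate_read_repeat_fraction(
    profiles: pd.DataFrame,  # contig, length, mean_depth
    mean_coverage: float,
    genome_size: float,
    min_freq_multiplier: float | None = None,
    literal_formula: bool = False,
) -> float:
    """Fraction of the genome in highly abundant sequence, from contig depths.

    Each contig contributes ``length * (mean_depth / C)`` normalized base
    pairs (its length at estimated genomic copy number); contigs are included
    when ``mean_depth >= min_freq_multiplier * C`` (default multiplier: C
    itself, i.e. a minimum repeat frequency of C^2 — 400x at 20x genome-wide
    coverage).  The sum over included contigs divided by the genome size G is
    the repeat fraction.  ``literal_formula`` switches to the alternative
    normalization depth / (length * C).
    """
    if mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if profiles.empty:
        return 0.0
    if (profiles["length"] <= 0).any():
        raise ValueError("contig lengths must be positive")
    mult = mean_coverage if min_freq_multiplier is None else min_freq_multiplier
    min_depth = mult * mean_coverage
    kept = profiles[profiles["mean_depth"] >= min_depth]
    if kept.empty:
        return 0.0
    if literal_formula:
        normalized = kept["mean_depth"] / (kept["length"] * mean_coverage)
    else:
        normalized = kept["length"] * (kept["mean_depth"] / mean_coverage)
    return float(normalized.sum() / genome_size)
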