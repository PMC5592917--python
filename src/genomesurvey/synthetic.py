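"""Synthetic genomes, reads, homolog pairs and hit tables with known truth.

Every generator is deterministic for a fixed seed and returns, next to the
sequences, exact truth tables (0-based half-open coordinates) that downstream
recovery tests compare against.  The generators emulate the salient features
of a repeat-rich bee genome survey: interspersed repeat families at
configurable copy number and divergence, micro-/minisatellite loci, NUMT
insertions derived from a mitogenome at 85-99% identity, non-overlapping gene
models, uniform-coverage single-end reads with i.i.d. substitution errors,
and a homologous second genome with known orthology and rearrangements.

Not emulated (by design): realistic Illumina error/quality profiles, read
pairing and insert sizes, indel errors, assembly fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from genomesurvey.sequtils import (
    decode,
    encode,
    merge_intervals,
    mutate_codes,
    random_codes,
    revcomp_codes,
)

# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class RepeatFamilySpec:
    family_id: str
    unit_length: int  # bp per copy
    copy_number: int
    divergence: float  # expected per-base substitution rate from consensus


@dataclass(frozen=True)
class TandemSpec:
    motif: str
    n_units: int
    n_loci: int


@dataclass(frozen=True)
class NumtSpec:
    mito_length: int
    n_insertions: int
    identity_range: tuple[float, float] = (0.85, 0.99)
    fragment_length_range: tuple[int, int] = (300, 1500)


@dataclass(frozen=True)
class GeneSpec:
    n_genes: int
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (50, 200)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    genome_length: int
    gc_fraction: float = 0.4
    repeat_families: tuple[RepeatFamilySpec, ...] = ()
    tandem_specs: tuple[TandemSpec, ...] = ()
    numt_spec: NumtSpec | None = None
    gene_spec: GeneSpec | None = None
    scaffold_name: str = "scaffold_1"
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        for fam in self.repeat_families:
            if not 0.0 <= fam.divergence <= 1.0:
                raise ValueError(f"divergence of {fam.family_id} outside [0, 1]")
        if self.numt_spec is not None:
            lo, hi = self.numt_spec.identity_range
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("NUMT identity range must lie in [0, 1]")


@dataclass(frozen=True)
class ReadSimSpec:
    coverage: float
    read_length: int
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")


@dataclass
class SyntheticTruth:
    """Exact placements of every generated feature.

    DataFrames (all coordinates 0-based half-open):
      repeats   : family_id, scaffold, start, end
      tandems   : motif, scaffold, start, end
      numts     : scaffold, start, end, identity
      genes     : gene_id, scaffold, strand, start, end, exons (list of (s, e))
      orthologs : query_gene, target_gene, target_scaffold, target_lg
    """

    repeats: pd.DataFrame = field(default_factory=pd.DataFrame)
    tandems: pd.DataFrame = field(default_factory=pd.DataFrame)
    numts: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    orthologs: pd.DataFrame = field(default_factory=pd.DataFrame)
    mito_sequence: str | None = None
    repeat_consensus: dict[str, str] = field(default_factory=dict)

    def repeat_fraction(self, genome_length: int) -> float:
        """Ground-truth repeat content: merged repeat span / genome length."""
        if self.repeats.empty:
            return 0.0
        total = 0
        for _, grp in self.repeats.groupby("scaffold"):
            ivs = merge_intervals(zip(grp["start"], grp["end"]))
            total += sum(e - s for s, e in ivs)
        return total / genome_length


_EMPTY = {
    "repeats": ["family_id", "scaffold", "start", "end"],
    "tandems": ["motif", "scaffold", "start", "end"],
    "numts": ["scaffold", "start", "end", "identity"],
    "genes": ["gene_id", "scaffold", "strand", "start", "end", "exons"],
    "orthologs": ["query_gene", "target_gene", "target_scaffold", "target_lg"],
}


def _empty_truth() -> SyntheticTruth:
    return SyntheticTruth(**{k: pd.DataFrame(columns=v) for k, v in _EMPTY.items()})


# ---------------------------------------------------------------------------
# genome generation


def _place_features(rng, genome_length, lengths, max_tries_per_feature=400):
    """Sample non-overlapping start positions for features of given lengths.

    Longest-first greedy rejection sampling; raises when the features cannot
    be packed (total length too close to the genome length).
    """
    if sum(lengths) > genome_length:
        raise ValueError(
            f"features total {sum(lengths)} bp but genome is only "
            f"{genome_length} bp; enlarge the genome or reduce feature content"
        )
    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    placed: list[tuple[int, int]] = []
    starts = [0] * len(lengths)
    for idx in order:
        length = lengths[idx]
        for _ in range(max_tries_per_feature):
            s = int(rng.integers(0, genome_length - length + 1))
            e = s + length
            if all(e <= ps or s >= pe for ps, pe in placed):
                placed.append((s, e))
                starts[idx] = s
                break
        else:
            raise ValueError(
                "could not place all features without overlap; the genome is "
                "too densely packed — enlarge the genome or reduce feature content"
            )
    return starts


def generate_genome(spec: SyntheticGenomeSpec):
    """Generate one scaffold plus exact truth tables.

    Features (repeat copies, tandem arrays, NUMTs, gene intervals) are placed
    at mutually non-overlapping positions on an i.i.d. background, so the
    truth tables exactly describe the emitted sequence.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome = random_codes(rng, spec.genome_length, spec.gc_fraction)
    truth = _empty_truth()

    # draw all feature payloads first, then pack them
    payloads: list[tuple[str, dict]] = []

    for fam in spec.repeat_families:
        consensus = random_codes(rng, fam.unit_length, spec.gc_fraction)
        truth.repeat_consensus[fam.family_id] = decode(consensus)
        for i in range(fam.copy_number):
            copy = mutate_codes(rng, consensus, fam.divergence)
            payloads.append(("repeat", {"family_id": fam.family_id, "codes": copy}))

    for tspec in spec.tandem_specs:
        unit = encode(tspec.motif.upper())
        if (unit == 255).any():
            raise ValueError(f"ambiguous residue in tandem motif {tspec.motif!r}")
        array = np.tile(unit, tspec.n_units)
        for _ in range(tspec.n_loci):
            payloads.append(("tandem", {"motif": tspec.motif.upper(), "codes": array}))

    mito = None
    if spec.numt_spec is not None:
        ns = spec.numt_spec
        mito = random_codes(rng, ns.mito_length, spec.gc_fraction)
        truth.mito_sequence = decode(mito)
        lo_f, hi_f = ns.fragment_length_range
        hi_f = min(hi_f, ns.mito_length)
        lo_f = min(lo_f, hi_f)
        for _ in range(ns.n_insertions):
            flen = int(rng.integers(lo_f, hi_f + 1))
            fstart = int(rng.integers(0, ns.mito_length - flen + 1))
            identity = float(rng.uniform(*ns.identity_range))
            frag = mutate_codes(rng, mito[fstart : fstart + flen], 1.0 - identity)
            payloads.append(("numt", {"codes": frag, "identity": identity}))

    gene_structs = []
    if spec.gene_spec is not None:
        gs = spec.gene_spec
        for i in range(gs.n_genes):
            n_ex = int(rng.integers(gs.exons_per_gene[0], gs.exons_per_gene[1] + 1))
            ex_lens = rng.integers(*gs.exon_length_range, size=n_ex, endpoint=True)
            in_lens = rng.integers(*gs.intron_length_range, size=max(n_ex - 1, 0), endpoint=True)
            total = int(ex_lens.sum() + in_lens.sum())
            gene_structs.append((f"gene_{i + 1:04d}", ex_lens, in_lens))
            payloads.append(("gene", {"length": total, "index": i}))

    lengths = [
        p[1]["codes"].size if "codes" in p[1] else p[1]["length"] for p in payloads
    ]
    starts = _place_features(rng, spec.genome_length, lengths)

    rep_rows, tan_rows, numt_rows, gene_rows = [], [], [], []
    scaf = spec.scaffold_name
    for (kind, payload), start in zip(payloads, starts):
        if "codes" in payload:
            codes = payload["codes"]
            genome[start : start + codes.size] = codes
            end = start + codes.size
        else:
            end = start + payload["length"]
        if kind == "repeat":
            rep_rows.append((payload["family_id"], scaf, start, end))
        elif kind == "tandem":
            tan_rows.append((payload["motif"], scaf, start, end))
        elif kind == "numt":
            numt_rows.append((scaf, start, end, payload["identity"]))
        elif kind == "gene":
            gene_id, ex_lens, in_lens = gene_structs[payload["index"]]
            exons, pos = [], start
            for j, el in enumerate(ex_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if j < len(in_lens):
                    pos += int(in_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((gene_id, scaf, strand, start, end, exons))

    if rep_rows:
        truth.repeats = pd.DataFrame(rep_rows, columns=_EMPTY["repeats"])
    if tan_rows:
        truth.tandems = pd.DataFrame(tan_rows, columns=_EMPTY["tandems"])
    if numt_rows:
        truth.numts = pd.DataFrame(numt_rows, columns=_EMPTY["numts"])
    if gene_rows:
        truth.genes = pd.DataFrame(gene_rows, columns=_EMPTY["genes"]).sort_values(
            "start", ignore_index=True
        )

    return {scaf: decode(genome)}, truth


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(sequences: dict[str, str], rs: ReadSimSpec) -> list[tuple[str, str]]:
    """Uniform-coverage single-end reads with i.i.d. substitution errors.

    The number of reads is ``round(coverage * total_length / read_length)``,
    so total read bases match the requested coverage to within one read.
    Reads are drawn from both strands with equal probability.
    """
    rs.validate()
    if not sequences:
        raise ValueError("at least one sequence is required")
    for name, seq in sequences.items():
        if rs.read_length > len(seq):
            raise ValueError(
                f"read_length {rs.read_length} exceeds length of sequence {name!r}"
            )
    rng = np.random.default_rng(rs.seed)
    names = list(sequences)
    encoded = {n: encode(sequences[n]) for n in names}
    lengths = np.array([len(sequences[n]) for n in names], dtype=float)
    total = lengths.sum()
    n_reads = int(round(rs.coverage * total / rs.read_length))

    scaffold_idx = rng.choice(len(names), size=n_reads, p=lengths / total)
    reads: list[tuple[str, str]] = []
    window = np.arange(rs.read_length)
    for si in range(len(names)):
        idx = np.flatnonzero(scaffold_idx == si)
        if idx.size == 0:
            continue
        codes = encoded[names[si]]
        starts = rng.integers(0, codes.size - rs.read_length + 1, size=idx.size)
        mat = codes[starts[:, None] + window]
        flip = rng.random(idx.size) < 0.5
        if rs.error_rate > 0:
            mask = rng.random(mat.shape) < rs.error_rate
            shifts = rng.integers(1, 4, size=mat.shape)
            mat = np.where(mask, (mat + shifts) % 4, mat).astype(np.uint8)
        for row, read_i, rc in zip(mat, idx, flip):
            seq = decode(revcomp_codes(row) if rc else row)
            reads.append((f"read_{read_i + 1:07d}", seq))
    reads.sort(key=lambda r: r[0])
    return reads


# ---------------------------------------------------------------------------
# homologous genome pair


@dataclass(frozen=True)
class Rearrangements:
    n_translocations: int = 0
    n_inversions: int = 0
    n_multi_homologs: int = 0
    n_unknown_lg: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_translocations
            + self.n_inversions
            + self.n_multi_homologs
            + self.n_unknown_lg
        )


@dataclass(frozen=True)
class HomologPairSpec:
    n_scaffolds: int = 10
    genes_per_scaffold: int = 8
    scaffold_length: int = 150_000
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    gc_fraction: float = 0.4


@dataclass
class HomologPair:
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    genes_a: pd.DataFrame  # gene_id, scaffold, start, end, strand
    genes_b: pd.DataFrame
    orthologs: pd.DataFrame  # query_gene, target_gene, target_scaffold, target_lg
    truth_blocks: pd.DataFrame  # scaffold, start, end, target_lg, n_genes, length
    scaffold_lengths: dict[str, int]


def generate_homolog_pair(
    spec: HomologPairSpec, rearrangements: Rearrangements, seed: int = 0
) -> HomologPair:
    """Two homologous genomes with a known ortholog map and block truth.

    Genome A scaffolds each correspond to one linkage group (LG) of genome B.
    Injected perturbations:
      * translocations — a mid-scaffold gene is reassigned to a different LG,
        splitting the scaffold's truth blocks;
      * inversions — a gene's target strand flips (block truth unaffected:
        blocks check shared location, not collinearity);
      * multi-homologs — a gene receives a second target location (removed by
        the multiplicity filter);
      * unknown-LG — a gene's target is labelled LG "unknown" (removed by the
        LG filter).
    The truth block list reflects the survey's block definition: per scaffold,
    runs of >=2 consecutive retained genes sharing one target LG, spanning
    first gene start to last gene end, kept when the span is >= 1 kb.
    """
    if spec.genes_per_scaffold < 2:
        raise ValueError("need at least 2 genes per scaffold")
    n_genes = spec.n_scaffolds * spec.genes_per_scaffold
    if rearrangements.total > n_genes:
        raise ValueError("more rearrangements requested than genes available")
    if spec.n_scaffolds < 2 and (
        rearrangements.n_translocations or rearrangements.n_multi_homologs
    ):
        raise ValueError(
            "translocations/multi-homologs need at least two scaffolds (target LGs)"
        )

    rng = np.random.default_rng(seed)
    genome_a, genome_b = {}, {}
    scaffold_lengths = {}
    gene_rows_a, gene_rows_b, orth_rows = [], [], []

    lg_names = [f"LG{i + 1}" for i in range(spec.n_scaffolds)]
    for si in range(spec.n_scaffolds):
        a_name = f"Ascaf_{si + 1}"
        genome_a[a_name] = decode(
            random_codes(rng, spec.scaffold_length, spec.gc_fraction)
        )
        genome_b[lg_names[si]] = decode(
            random_codes(rng, spec.scaffold_length, spec.gc_fraction)
        )
        scaffold_lengths[a_name] = spec.scaffold_length

        # lay genes left to right with random gaps
        slot = spec.scaffold_length // spec.genes_per_scaffold
        for gi in range(spec.genes_per_scaffold):
            glen = int(rng.integers(*spec.gene_length_range, endpoint=True))
            lo = si_start = gi * slot
            hi = si_start + slot - glen
            start = int(rng.integers(lo, max(hi, lo + 1)))
            gid = f"A{si + 1}g{gi + 1}"
            tid = f"B{si + 1}g{gi + 1}"
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows_a.append((gid, a_name, start, start + glen, strand))
            gene_rows_b.append((tid, lg_names[si], start, start + glen, strand))
            orth_rows.append((gid, tid, lg_names[si], lg_names[si]))

    orth = pd.DataFrame(orth_rows, columns=_EMPTY["orthologs"])
    genes_a = pd.DataFrame(
        gene_rows_a, columns=["gene_id", "scaffold", "start", "end", "strand"]
    )
    genes_b = pd.DataFrame(
        gene_rows_b, columns=["gene_id", "scaffold", "start", "end", "strand"]
    )

    # choose disjoint genes to perturb; avoid first/last gene of a scaffold for
    # translocations so they provably split a block
    all_ids = list(genes_a["gene_id"])
    mid_ids = [
        g
        for si in range(spec.n_scaffolds)
        for g in all_ids[
            si * spec.genes_per_scaffold + 1 : (si + 1) * spec.genes_per_scaffold - 1
        ]
    ]
    rng.shuffle(mid_ids)
    if rearrangements.n_translocations > len(mid_ids):
        raise ValueError("not enough interior genes for the requested translocations")
    trans = set(mid_ids[: rearrangements.n_translocations])
    remaining = [g for g in all_ids if g not in trans]
    rng.shuffle(remaining)
    k1 = rearrangements.n_inversions
    k2 = rearrangements.n_multi_homologs
    k3 = rearrangements.n_unknown_lg
    inv = set(remaining[:k1])
    multi = set(remaining[k1 : k1 + k2])
    unknown = set(remaining[k1 + k2 : k1 + k2 + k3])

    for g in trans:
        own_lg = orth.loc[orth["query_gene"] == g, "target_lg"].iloc[0]
        other = [lg for lg in lg_names if lg != own_lg]
        new_lg = other[int(rng.integers(0, len(other)))]
        orth.loc[orth["query_gene"] == g, ["target_scaffold", "target_lg"]] = new_lg
    for g in inv:
        tid = orth.loc[orth["query_gene"] == g, "target_gene"].iloc[0]
        sel = genes_b["gene_id"] == tid
        genes_b.loc[sel, "strand"] = genes_b.loc[sel, "strand"].map(
            {"+": "-", "-": "+"}
        )
    extra_rows = []
    for g in multi:
        own_lg = orth.loc[orth["query_gene"] == g, "target_lg"].iloc[0]
        other = [lg for lg in lg_names if lg != own_lg]
        dup_lg = other[int(rng.integers(0, len(other)))]
        extra_rows.append((g, f"{g}_dup", dup_lg, dup_lg))
    if extra_rows:
        orth = pd.concat(
            [orth, pd.DataFrame(extra_rows, columns=orth.columns)], ignore_index=True
        )
    for g in unknown:
        orth.loc[orth["query_gene"] == g, "target_lg"] = "unknown"

    truth_blocks = _expected_blocks(
        genes_a, orth, removed=multi | unknown, min_block_len=1_000
    )
    return HomologPair(
        genome_a, genome_b, genes_a, genes_b, orth, truth_blocks, scaffold_lengths
    )


def _expected_blocks(genes_a, orth, removed, min_block_len):
    lg_of = {}
    for _, row in orth.iterrows():
        q = row["query_gene"]
        if q in removed:
            continue
        lg_of[q] = row["target_lg"]
    rows = []
    for scaf, grp in genes_a.groupby("scaffold", sort=False):
        grp = grp.sort_values("start")
        run: list[tuple[int, int]] = []
        run_lg = None

        def flush():
            if run_lg is not None and len(run) >= 2:
                start, end = run[0][0], max(e for _, e in run)
                if end - start >= min_block_len:
                    rows.append((scaf, start, end, run_lg, len(run), end - start))

        for _, g in grp.iterrows():
            lg = lg_of.get(g["gene_id"])
            if lg is None:
                continue  # filtered genes are transparent
            if lg == run_lg:
                run.append((g["start"], g["end"]))
            else:
                flush()
                run = [(g["start"], g["end"])]
                run_lg = lg
        flush()
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "target_lg", "n_genes", "length"]
    ).sort_values(["scaffold", "start"], ignore_index=True)


# ---------------------------------------------------------------------------
# hit tables and depth profiles


@dataclass(frozen=True)
class HitNoise:
    evalue_range: tuple[float, float] = (1e-40, 1e-10)  # true hits
    identity_jitter: float = 0.0  # +/- percentage points on pident
    n_decoys: int = 0
    decoy_evalue_range: tuple[float, float] = (1e-3, 1.0)  # above the 1e-4 cutoff


def emit_hit_tables(
    truth: SyntheticTruth,
    noise: HitNoise = HitNoise(),
    seed: int = 0,
    scaffold_length: int | None = None,
) -> dict[str, pd.DataFrame]:
    """BLAST-outfmt6-style hit tables (plus qcovs) derived from truth.

    Returns ``{"numt": ..., "protein": ...}``: one record per true placement,
    with e-values drawn below the cutoffs, plus ``n_decoys`` decoy records per
    table whose e-values lie in ``decoy_evalue_range`` (above the cutoffs).
    """
    rng = np.random.default_rng(seed)

    def loguniform(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    cols = [
        "qseqid",
        "sseqid",
        "pident",
        "length",
        "mismatch",
        "gapopen",
        "qstart",
        "qend",
        "sstart",
        "send",
        "evalue",
        "bitscore",
        "qcovs",
    ]

    def build(rows):
        return pd.DataFrame(rows, columns=cols)

    numt_rows = []
    for _, row in truth.numts.iterrows():
        length = int(row["end"] - row["start"])
        ident = 100.0 * float(row["identity"])
        if noise.identity_jitter:
            ident = float(
                np.clip(ident + rng.uniform(-1, 1) * noise.identity_jitter, 0, 100)
            )
        ev = float(loguniform(*noise.evalue_range, 1)[0])
        mism = int(round(length * (1 - ident / 100.0)))
        numt_rows.append(
            (
                "mito",
                row["scaffold"],
                round(ident, 2),
                length,
                mism,
                0,
                1,
                length,
                int(row["start"]) + 1,
                int(row["end"]),
                ev,
                round(2.0 * length * ident / 100.0, 1),
                1.0,
            )
        )
    mito_len = len(truth.mito_sequence) if truth.mito_sequence else 16_000
    for d in range(noise.n_decoys):
        length = int(rng.integers(80, 400))
        start = int(rng.integers(0, max((scaffold_length or 100_000) - length, 1)))
        numt_rows.append(
            (
                "mito",
                "decoy_scaffold" if truth.numts.empty else truth.numts["scaffold"].iloc[0],
                round(float(rng.uniform(70, 85)), 2),
                length,
                int(length * 0.2),
                0,
                1,
                min(length, mito_len),
                start + 1,
                start + length,
                float(loguniform(*noise.decoy_evalue_range, 1)[0]),
                round(1.2 * length, 1),
                0.3,
            )
        )

    prot_rows = []
    for _, g in truth.genes.iterrows():
        length = int(g["end"] - g["start"])
        ev = float(loguniform(*noise.evalue_range, 1)[0])
        prot_rows.append(
            (
                f"donor_{g['gene_id']}",
                g["scaffold"],
                round(float(rng.uniform(60, 95)), 2),
                length,
                0,
                0,
                1,
                length // 3,
                int(g["start"]) + 1,
                int(g["end"]),
                ev,
                round(1.5 * length, 1),
                round(float(rng.uniform(0.6, 1.0)), 3),
            )
        )
    for d in range(noise.n_decoys):
        length = int(rng.integers(60, 200))
        prot_rows.append(
            (
                f"decoy_query_{d + 1}",
                "decoy_scaffold",
                round(float(rng.uniform(30, 60)), 2),
                length,
                int(length * 0.4),
                1,
                1,
                length // 3,
                1,
                length,
                float(loguniform(*noise.decoy_evalue_range, 1)[0]),
                round(0.8 * length, 1),
                round(float(rng.uniform(0.05, 0.4)), 3),
            )
        )

    return {"numt": build(numt_rows), "protein": build(prot_rows)}


def emit_depth_profiles(
    spec: SyntheticGenomeSpec, coverage: float, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Per-family contig depth profiles (contig, length, mean_depth).

    Emulates mapping all reads against assembled repeat-family consensus
    contigs: a family with ``c`` genomic copies accumulates ``c`` times the
    genome-wide per-base coverage.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fam in spec.repeat_families:
        depth = coverage * fam.copy_number
        if noise_sd:
            depth = max(0.0, float(rng.normal(depth, noise_sd)))
        rows.append((fam.family_id, fam.unit_length, depth))
    return pd.DataFrame(rows, columns=["contig", "length", "mean_depth"])
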