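"""File-format plumbing: FASTA/FASTQ via Biopython, tabular hits and GFF3 via pandas.

Hit tables follow BLAST ``outfmt 6`` column order with one appended
``qcovs``-style column (query coverage as a proportion in [0, 1]).
GFF3 is emitted 1-based inclusive; all in-memory coordinates in this package
are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HIT_COLUMNS = [
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

GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, description: str = "") -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=description)
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[tuple[str, str]], path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == len(HIT_COLUMNS) - 1:  # plain outfmt 6, no qcovs
        df.columns = HIT_COLUMNS[:-1]
    else:
        df.columns = HIT_COLUMNS[: df.shape[1]]
    return df


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    """Flat GFF3 reader; coordinates converted to 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=GFF_COLUMNS, dtype={"seqid": str}
    )
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write features (0-based half-open start/end) as 1-based inclusive GFF3."""
    out = features.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    cols = [c for c in GFF_COLUMNS if c in out.columns]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        out[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
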