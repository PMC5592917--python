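"""K-mer frequency spectrum and survey estimates (genome size, depth, coverage).

The estimator follows the classic short-read survey arithmetic: with N reads
of single-read length L, the read set contains N*(L-K+1) k-mer observations.
Low-frequency k-mers (frequency <= an error cutoff, default 3) are treated as
sequencing errors and their observations (B) subtracted; dividing the
remaining observations by the k-mer depth D (the primary non-error peak of
the spectrum) yields the genome size

    G = (N * (L - K + 1) - B) / D

Mean per-base coverage is C = sum_i(R_i * L_i) / G over the sequencing
libraries, and the repetitive fraction of the genome is read off the spectrum
as the observation mass above a multiple of the depth peak.

K-mers are counted in canonical (strand-collapsed) form, since reads sample
both strands; k-mers containing ambiguous residues are skipped.  The counter
is an in-memory 2-bit-packed implementation (k <= 31) intended for desk-scale
inputs (up to ~1e8 k-mer observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from genomesurvey.sequtils import encode


@dataclass
class KmerSpectrum:
    """Counts of distinct k-mers per occurrence frequency."""

    k: int
    counts: dict[int, int]  # frequency f -> number of distinct k-mers seen f times

    @property
    def total_observations(self) -> int:
        """Sum of f * counts[f]; equals the windowed k-mer count of the input."""
        return int(sum(f * n for f, n in self.counts.items()))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        return pd.DataFrame(rows, columns=["frequency", "n_distinct_kmers"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, k: int) -> "KmerSpectrum":
        return cls(k=k, counts=dict(zip(df.iloc[:, 0].astype(int), df.iloc[:, 1].astype(int))))


@dataclass
class LibraryStats:
    """Read-set bookkeeping: per-library (R_i, L_i) plus single-read length L."""

    libraries: list[tuple[int, float]]  # (n_reads R_i, mean read length L_i)
    read_length: int  # single-read length L used in the size formula

    @property
    def n_reads(self) -> int:
        return int(sum(r for r, _ in self.libraries))

    @property
    def total_bases(self) -> float:
        return float(sum(r * l for r, l in self.libraries))

    @classmethod
    def from_reads(cls, reads: list[tuple[str, str]]) -> "LibraryStats":
        lengths = [len(seq) for _, seq in reads]
        if not lengths:
            raise ValueError("empty read set")
        return cls(
            libraries=[(len(lengths), float(np.mean(lengths)))],
            read_length=int(round(np.mean(lengths))),
        )


@dataclass
class SurveyEstimates:
    B: int  # low-frequency (error) k-mer observations
    D: float  # k-mer depth (centroid-refined spectrum peak)
    G: int  # estimated genome size, bases
    C: float | None = None  # mean per-base coverage
    spectrum_repeat_fraction: float | None = None

    def to_dict(self) -> dict:
        return {
            "error_kmer_observations_B": self.B,
            "kmer_depth_D": self.D,
            "genome_size_G": self.G,
            "coverage_C": self.C,
            "spectrum_repeat_fraction": self.spectrum_repeat_fraction,
        }


# ---------------------------------------------------------------------------


def count_kmer_spectrum(reads, k: int = 25) -> KmerSpectrum:
    """Canonical k-mer frequency spectrum of a read set.

    Parameters
    ----------
    reads : iterable of (name, sequence) tuples or plain sequences
    k : k-mer length (1..31; packed into 64-bit integers)
    """
    if not 1 <= k <= 31:
        raise ValueError("k must lie in 1..31 for the packed counter")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    chunks: list[np.ndarray] = []
    any_window = False
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        if len(seq) < k:
            continue
        any_window = True
        codes = encode(seq)
        valid = codes != 255
        safe = np.where(valid, codes, 0).astype(np.int64)
        n_win = len(seq) - k + 1
        win = np.lib.stride_tricks.sliding_window_view(safe, k)
        fwd = win @ powers
        comp = 3 - safe
        rwin = np.lib.stride_tricks.sliding_window_view(comp, k)
        rev = rwin @ powers[::-1]
        canon = np.minimum(fwd, rev)
        ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
        chunks.append(canon[ok])
    if not any_window:
        raise ValueError(f"k={k} is larger than every read")
    if not chunks or all(c.size == 0 for c in chunks):
        return KmerSpectrum(k=k, counts={})
    codes = np.concatenate(chunks)
    _, per_kmer = np.unique(codes, return_counts=True)
    freqs, n_distinct = np.unique(per_kmer, return_counts=True)
    return KmerSpectrum(k=k, counts={int(f): int(n) for f, n in zip(freqs, n_distinct)})


def estimate_depth(spectrum: KmerSpectrum, error_cutoff: int = 3) -> int:
    """K-mer depth D: the frequency of the primary non-error spectrum peak.

    D is the argmax of counts[f] over f > error_cutoff; ties break toward the
    smaller frequency.
    """
    candidates = {f: n for f, n in spectrum.counts.items() if f > error_cutoff}
    if not candidates:
        raise ValueError(
            "all k-mers look like errors: no spectrum mass above the error cutoff"
        )
    best_n = max(candidates.values())
    return min(f for f, n in candidates.items() if n == best_n)


def refine_depth(spectrum: KmerSpectrum, error_cutoff: int = 3) -> float:
    """Sub-integer k-mer depth: count-weighted centroid around the peak.

    The discrete argmax peak is quantized to whole frequencies, which alone
    perturbs the genome-size estimate by up to ~1/D.  The refined depth is
    the count-weighted mean frequency over the single-copy peak's
    neighbourhood [peak/2, 1.5*peak] (still above the error cutoff) — wide
    enough to be insensitive to +/-1 wobble of the argmax, narrow enough to
    exclude multi-copy (repeat) peaks at 2D and beyond.  No distributional
    model is fitted.
    """
    peak = estimate_depth(spectrum, error_cutoff)
    lo = max(error_cutoff + 1, int(np.ceil(peak / 2)))
    hi = int(np.floor(1.5 * peak)) + 1
    mass = {f: n for f, n in spectrum.counts.items() if lo <= f <= hi}
    total = sum(mass.values())
    if total == 0:
        return float(peak)
    return sum(f * n for f, n in mass.items()) / total


def estimate_genome_size(
    spectrum: KmerSpectrum,
    libstats: LibraryStats,
    error_cutoff: int = 3,
    depth: float | None = None,
    refine: bool = True,
) -> SurveyEstimates:
    """Genome size G = (N*(L-K+1) - B) / D, rounded to the nearest base.

    B is the total count of low-frequency k-mer *observations* (frequency
    times multiplicity for every frequency <= error_cutoff), which keeps the
    numerator in observation units.  By default D is the centroid-refined
    spectrum peak (see `refine_depth`); pass ``refine=False`` for the raw
    integer argmax peak, or `depth` to override D entirely.
    """
    if depth is not None:
        D = depth
    elif refine:
        D = refine_depth(spectrum, error_cutoff)
    else:
        D = estimate_depth(spectrum, error_cutoff)
    B = int(sum(f * n for f, n in spectrum.counts.items() if f <= error_cutoff))
    N = libstats.n_reads
    L = libstats.read_length
    numerator = N * (L - spectrum.k + 1) - B
    if numerator <= 0:
        raise ValueError(
            f"non-positive numerator in size formula: N*(L-K+1)={N * (L - spectrum.k + 1)}"
            f" while B={B}"
        )
    G = int(round(numerator / D))
    return SurveyEstimates(B=B, D=D, G=G)


def estimate_repeat_fraction(
    spectrum: KmerSpectrum,
    D: int,
    error_cutoff: int = 3,
    repeat_multiplier: float = 1.5,
) -> float:
    """Spectrum-based repetitive fraction of the genome.

    Observation mass at frequencies above ``repeat_multiplier * D`` (k-mers
    present in more than ~one genomic copy) over all non-error observation
    mass (frequencies above the error cutoff).  Non-increasing in the
    multiplier; lies in [0, 1].
    """
    if D <= 0:
        raise ValueError("D must be positive")
    denom = sum(f * n for f, n in spectrum.counts.items() if f > error_cutoff)
    if denom == 0:
        raise ValueError("no non-error spectrum mass; cannot estimate repeat fraction")
    cut = repeat_multiplier * D
    num = sum(f * n for f, n in spectrum.counts.items() if f > cut)
    return num / denom


def estimate_coverage(libstats: LibraryStats, G: int | float) -> float:
    """Mean per-base coverage C = sum_i(R_i * L_i) / G."""
    if G <= 0:
        raise ValueError("estimated genome size must be positive")
    return libstats.total_bases / G


def run_kmer_survey(
    reads,
    k: int = 25,
    error_cutoff: int = 3,
    repeat_multiplier: float = 1.5,
    libstats: LibraryStats | None = None,
) -> tuple[KmerSpectrum, SurveyEstimates]:
    """Full survey: spectrum, depth, genome size, coverage, repeat fraction."""
    reads = list(reads)
    if libstats is None:
        libstats = LibraryStats.from_reads(
            [r if isinstance(r, tuple) else ("read", r) for r in reads]
        )
    spectrum = count_kmer_spectrum(reads, k=k)
    est = estimate_genome_size(spectrum, libstats, error_cutoff=error_cutoff)
    est.C = estimate_coverage(libstats, est.G)
    est.spectrum_repeat_fraction = estimate_repeat_fraction(
        spectrum, est.D, error_cutoff=error_cutoff, repeat_multiplier=repeat_multiplier
    )
    return spectrum, est
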