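"""Micro- and minisatellite detection by lag-u self-comparison scoring.

A tandem array with unit length u makes the sequence locally self-similar at
lag u: position i tends to match position i-u.  For each candidate unit
length the scanner scores every position against the residue one unit
earlier (+1 match, -4 mismatch by default, the parameterization of
satellite scans in insect genome surveys) and reports maximal-scoring
disjoint segments with score >= 12.  A perfect repeat of total length l and
unit u therefore scores l - u.

Locus semantics (shared exactly with the exhaustive oracle in
``genomesurvey.tandem_oracle``):

* per unit length, loci are the disjoint segments obtained by repeatedly
  taking the maximum-scoring segment of the lag-u score array (ties broken
  to the smaller end, then the smaller start) until the best score drops
  below ``min_score``;
* a segment of lag-array span m maps to the sequence interval
  [start, start + m + u) — the matched region plus its leading unit — and is
  only a locus when m >= u (interval at least two units long);
* candidate loci from different unit lengths that overlap are resolved to
  the highest score (ties: shorter unit, then leftmost).

Gapped (indel) extension is not modelled: scoring is the ungapped lag
comparison and ``n_gaps`` is always 0.  Reported motifs are normalized to
the lexicographically minimal rotation of the leading unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from genomesurvey.sequtils import (
    encode,
    merged_length,
    minimal_rotation,
    non_ambiguous_length,
)


@dataclass(frozen=True)
class TandemScoring:
    match: int = 1
    mismatch: int = -4
    gap: int = -4  # retained for interface completeness; ungapped scan
    min_score: int = 12


@dataclass
class TandemRepeatLocus:
    scaffold: str
    start: int
    end: int  # half-open
    motif: str
    unit_length: int
    score: int
    n_mismatches: int
    n_gaps: int = 0


@dataclass
class TandemRepeatSummary:
    micro_count: int
    micro_bp: int
    mini_count: int
    mini_bp: int
    combined_fraction: float  # of assembly, excluding ambiguous stretches

    def to_dict(self) -> dict:
        return {
            "micro_count": self.micro_count,
            "micro_bp": self.micro_bp,
            "mini_count": self.mini_count,
            "mini_bp": self.mini_bp,
            "combined_fraction": self.combined_fraction,
        }


# ---------------------------------------------------------------------------
# segment extraction


def _max_segment(prefix: np.ndarray):
    """Maximum-sum segment of the score array underlying `prefix`.

    Returns (score, s, e) with ties broken to the smallest e, then the
    smallest s.  `prefix` has length m+1 with prefix[0] = 0.
    """
    runmin = np.minimum.accumulate(prefix[:-1])
    scores = prefix[1:] - runmin
    e_idx = int(np.argmax(scores))  # first occurrence -> smallest e
    best = int(scores[e_idx])
    e = e_idx + 1
    s = int(np.argmax(prefix[:e] == runmin[e_idx]))  # first min -> smallest s
    return best, s, e


def _disjoint_segments(x: np.ndarray, min_score: int):
    """Repeated max-segment extraction (recursing left/right of each pick)."""
    out: list[tuple[int, int, int]] = []  # (score, s, e)
    stack = [(0, x.size)]
    prefix_full = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    while stack:
        lo, hi = stack.pop()
        if hi - lo <= 0:
            continue
        prefix = prefix_full[lo : hi + 1] - prefix_full[lo]
        best, s, e = _max_segment(prefix)
        if best < min_score:
            continue
        out.append((best, lo + s, lo + e))
        stack.append((lo, lo + s))
        stack.append((lo + e, hi))
    return sorted(out, key=lambda t: t[1])


def _lag_scores(codes: np.ndarray, u: int, scoring: TandemScoring) -> np.ndarray:
    a, b = codes[u:], codes[:-u]
    match = (a == b) & (a != 255) & (b != 255)
    return np.where(match, scoring.match, scoring.mismatch).astype(np.int64)


def resolve_overlapping_loci(loci: list[TandemRepeatLocus]) -> list[TandemRepeatLocus]:
    """Keep the best locus among overlapping candidates.

    Priority: higher score, then shorter unit, then leftmost, then smaller
    end; surviving loci never overlap on a scaffold.
    """
    ranked = sorted(
        loci, key=lambda l: (-l.score, l.unit_length, l.start, l.end, l.scaffold)
    )
    kept: list[TandemRepeatLocus] = []
    for cand in ranked:
        if all(
            cand.scaffold != k.scaffold or cand.end <= k.start or cand.start >= k.end
            for k in kept
        ):
            kept.append(cand)
    return sorted(kept, key=lambda l: (l.scaffold, l.start))


def find_tandem_repeats(
    sequence: str,
    unit_range: tuple[int, int] = (1, 6),
    scoring: TandemScoring = TandemScoring(),
    scaffold: str = "seq",
) -> list[TandemRepeatLocus]:
    """Scan one sequence for tandem repeats with units in `unit_range`."""
    u_min, u_max = unit_range
    if not 1 <= u_min <= u_max <= 1000:
        raise ValueError("unit range must satisfy 1 <= min <= max <= 1000")
    if not sequence:
        raise ValueError("empty sequence")
    codes = encode(sequence)
    candidates: list[TandemRepeatLocus] = []
    for u in range(u_min, min(u_max, len(sequence) - 1) + 1):
        if codes.size <= u:
            break
        x = _lag_scores(codes, u, scoring)
        for score, s, e in _disjoint_segments(x, scoring.min_score):
            if e - s < u:  # interval shorter than two units
                continue
            n_mm = int(np.sum(x[s:e] == scoring.mismatch))
            unit_seq = sequence[s : s + u].upper()
            candidates.append(
                TandemRepeatLocus(
                    scaffold=scaffold,
                    start=s,
                    end=e + u,
                    motif=minimal_rotation(unit_seq),
                    unit_length=u,
                    score=score,
                    n_mismatches=n_mm,
                )
            )
    return resolve_overlapping_loci(candidates)


def scan_assembly(
    sequences: dict[str, str],
    micro_range: tuple[int, int] = (1, 6),
    mini_range: tuple[int, int] = (7, 100),
    scoring: TandemScoring = TandemScoring(),
) -> list[TandemRepeatLocus]:
    """Two-pass scan (micro then mini classes) over every scaffold."""
    loci: list[TandemRepeatLocus] = []
    for name, seq in sequences.items():
        loci.extend(find_tandem_repeats(seq, micro_range, scoring, scaffold=name))
        if mini_range is not None:
            loci.extend(find_tandem_repeats(seq, mini_range, scoring, scaffold=name))
    return loci


def summarize_tandem_repeats(
    loci: list[TandemRepeatLocus],
    assembly: dict[str, str],
    micro_max_unit: int = 6,
) -> TandemRepeatSummary:
    """Per-class counts and overlap-merged cumulative lengths.

    The combined fraction uses the assembly length excluding ambiguous
    (N) stretches as denominator.
    """
    micro, mini, all_iv = [], [], []
    for loc in loci:
        if loc.scaffold not in assembly:
            raise ValueError(f"locus on unknown scaffold {loc.scaffold!r}")
        if loc.end > len(assembly[loc.scaffold]) or loc.start < 0:
            raise ValueError(
                f"locus {loc.scaffold}:{loc.start}-{loc.end} beyond scaffold end"
            )
        (micro if loc.unit_length <= micro_max_unit else mini).append(loc)
        all_iv.append((loc.scaffold, loc.start, loc.end))

    def class_bp(class_loci):
        total = 0
        by_scaf: dict[str, list] = {}
        for l in class_loci:
            by_scaf.setdefault(l.scaffold, []).append((l.start, l.end))
        for ivs in by_scaf.values():
            total += merged_length(ivs)
        return total

    denom = non_ambiguous_length(assembly)
    by_scaf_all: dict[str, list] = {}
    for scaf, s, e in all_iv:
        by_scaf_all.setdefault(scaf, []).append((s, e))
    covered = sum(merged_length(ivs) for ivs in by_scaf_all.values())
    return TandemRepeatSummary(
        micro_count=len(micro),
        micro_bp=class_bp(micro),
        mini_count=len(mini),
        mini_bp=class_bp(mini),
        combined_fraction=(covered / denom) if denom else 0.0,
    )
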