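"""Exhaustive reference scorer for tandem-repeat detection.

Implements the same locus semantics as ``genomesurvey.tandem`` by brute
force: every (start, end) segment of the lag-u score array is scored via an
explicit O(m^2) difference matrix, the maximum is chosen with the identical
tie-break (smaller end, then smaller start), and the selection recurses into
the untouched flanks.  Cross-unit overlap resolution is likewise re-derived
with a naive quadratic sweep.  Intended for validation on short sequences
(a few kb); quadratic in sequence length.
"""

from __future__ import annotations

import numpy as np

from genomesurvey.sequtils import minimal_rotation
from genomesurvey.tandem import TandemRepeatLocus, TandemScoring


def _brute_segments(x: np.ndarray, min_score: int):
    """All disjoint max-scoring segments by exhaustive enumeration."""
    out = []

    def recurse(lo, hi):
        m = hi - lo
        if m <= 0:
            return
        prefix = np.concatenate(([0], np.cumsum(x[lo:hi], dtype=np.int64)))
        # score of segment (s, e] = prefix[e] - prefix[s]; full (m+1)x(m+1) table
        table = prefix[None, 1:] - prefix[: -1, None]  # [s, e-1]
        mask = np.triu(np.ones_like(table, dtype=bool))  # e > s
        table = np.where(mask, table, np.iinfo(np.int64).min)
        best = int(table.max())
        if best < min_score:
            return
        ss, ee = np.nonzero(table == best)
        order = np.lexsort((ss, ee))  # smallest e, then smallest s
        s, e = int(ss[order[0]]), int(ee[order[0]]) + 1
        out.append((best, lo + s, lo + e))
        recurse(lo, lo + s)
        recurse(lo + e, hi)

    recurse(0, x.size)
    return sorted(out, key=lambda t: t[1])


def exhaustive_find_tandem_repeats(
    sequence: str,
    unit_range: tuple[int, int] = (1, 6),
    scoring: TandemScoring = TandemScoring(),
    scaffold: str = "seq",
) -> list[TandemRepeatLocus]:
    seq = sequence.upper()
    n = len(seq)
    candidates = []
    for u in range(unit_range[0], min(unit_range[1], n - 1) + 1):
        x = np.array(
            [
                scoring.match
                if seq[i] == seq[i - u] and seq[i] in "ACGT" and seq[i - u] in "ACGT"
                else scoring.mismatch
                for i in range(u, n)
            ],
            dtype=np.int64,
        )
        for score, s, e in _brute_segments(x, scoring.min_score):
            if e - s < u:
                continue
            n_mm = sum(1 for i in range(s, e) if x[i] == scoring.mismatch)
            candidates.append(
                TandemRepeatLocus(
                    scaffold=scaffold,
                    start=s,
                    end=e + u,
                    motif=minimal_rotation(seq[s : s + u]),
                    unit_length=u,
                    score=score,
                    n_mismatches=int(n_mm),
                )
            )
    # naive overlap resolution: best score, shorter unit, leftmost
    kept: list[TandemRepeatLocus] = []
    for cand in sorted(
        candidates, key=lambda l: (-l.score, l.unit_length, l.start, l.end, l.scaffold)
    ):
        overlaps = False
        for k in kept:
            if cand.scaffold == k.scaffold and cand.start < k.end and k.start < cand.end:
                overlaps = True
                break
        if not overlaps:
            kept.append(cand)
    return sorted(kept, key=lambda l: (l.scaffold, l.start))
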