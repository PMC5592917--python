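"""Assembly-style summary statistics (N50/N25, GC, scaffold counts)."""

from __future__ import annotations

import numpy as np

from genomesurvey.sequtils import non_ambiguous_length


def nx_length(lengths, x: float) -> int:
    """Nx: length of the shortest scaffold among the longest scaffolds that
    jointly contain x% of the assembly bases."""
    if not 0 < x <= 100:
        raise ValueError("x must lie in (0, 100]")
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("no scaffolds")
    target = arr.sum() * x / 100.0
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, target))
    return int(arr[min(idx, arr.size - 1)])


def assembly_stats(sequences: dict[str, str]) -> dict:
    """Scaffold count, total/longest length, N50, N25 and GC fraction.

    GC is computed over unambiguous residues only.
    """
    if not sequences:
        raise ValueError("empty assembly")
    lengths = [len(s) for s in sequences.values()]
    n_gc = sum(s.count("G") + s.count("C") + s.count("g") + s.count("c")
               for s in sequences.values())
    n_acgt = non_ambiguous_length(sequences)
    return {
        "n_scaffolds": len(lengths),
        "total_length": int(sum(lengths)),
        "longest_scaffold": int(max(lengths)),
        "N50": nx_length(lengths, 50),
        "N25": nx_length(lengths, 25),
        "gc_fraction": (n_gc / n_acgt) if n_acgt else 0.0,
    }
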