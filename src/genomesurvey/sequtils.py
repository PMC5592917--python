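"""Small sequence/interval helpers shared across the survey stages.

Sequences are handled either as plain Python strings (A/C/G/T/N upper case)
or, inside the generators and the k-mer counter, as numpy ``uint8`` arrays of
2-bit base codes (A=0, C=1, G=2, T=3).
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# uint8 ASCII -> 2-bit code; 255 marks ambiguous residues
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[ord(chr(_b).lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """String -> 2-bit code array (ambiguous residues become 255)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_codes(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> np.ndarray:
    """I.i.d. random base codes with the requested GC fraction."""
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)


def mutate_codes(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Binomial substitutions at `rate`; every hit changes the base."""
    out = codes.copy()
    hits = np.flatnonzero(rng.random(codes.size) < rate)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous residues."""
    n_gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    n_acgt = sum(seq.count(b) for b in "ACGTacgt")
    if n_acgt == 0:
        raise ValueError("sequence has no unambiguous residues")
    return n_gc / n_acgt


def non_ambiguous_length(sequences) -> int:
    """Total assembly length excluding stretches of N (and any ambiguity code)."""
    total = 0
    for seq in sequences.values():
        total += sum(seq.count(b) for b in "ACGTacgt")
    return total


def minimal_rotation(s: str) -> str:
    """Lexicographically smallest rotation (Booth-style, small strings)."""
    doubled = s + s
    return min(doubled[i : i + len(s)] for i in range(len(s)))


def merge_intervals(intervals):
    """Merge overlapping/touching half-open intervals; returns sorted list."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
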