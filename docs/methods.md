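# Methods

## Scope and shape

The package implements the survey layer of a short-read genome project —
the estimators and decision rules that run *around* heavyweight external
tools (assemblers, aligners, repeat finders, gene predictors), never those
tools themselves. Alignment hits, candidate gene models with similarity
scores, repeat annotations and per-contig depth profiles are *inputs*;
the contribution is the arithmetic and the filtering logic applied to them.
All stages are exercised end to end on synthetic genomes with exact ground
truth (the `synthetic` module is first-class, tested code).

## K-mer survey

Reads are decomposed into canonical (strand-collapsed) k-mers, `k = 25` by
default, packed 2 bits/base into 64-bit integers (`k ≤ 31`); windows
containing ambiguous residues are skipped. The spectrum maps each frequency
`f` to the number of distinct k-mers observed exactly `f` times, and
conserves observations exactly: `Σ f·counts[f] = Σ max(L−k+1, 0)` over reads.
The counter is in-memory and intended for desk-scale inputs (≲ 10⁸ k-mer
observations, a few GB).

**Depth.** The integer peak is the argmax of `counts[f]` over `f >` the
error cutoff (default 3), ties toward the smaller frequency. Because the
argmax is quantized to whole frequencies, it alone perturbs the genome-size
estimate by up to `~1/D` (≈ 7% at depth 15), so the size formula uses a
refined depth: the count-weighted mean frequency over `[peak/2, 1.5·peak]`.
The window is wide enough to be insensitive to ±1 wobble of the argmax and
narrow enough to exclude the two-copy peak at `2D`; no distributional model
is fitted. Note the k-mer depth is `C·(L−K+1)/L`, not the base coverage `C`.

**Error mass `B`.** The formula's `B` counts low-frequency k-mer
*observations* (frequency × multiplicity for `f ≤` cutoff), not distinct
k-mers — observation units keep the numerator `N·(L−K+1) − B` dimensionally
consistent. The alternative (distinct k-mers) is a documented ambiguity of
the survey literature; observation units are the implemented choice.

**Repeat fraction.** Observation mass above `repeat_multiplier·D` (default
1.5, exposed as a flag) over all non-error mass. The rule is a documented
choice: the multiplier 1.5 separates single-copy mass (centred at `D`) from
two-copy-and-above mass (centred at `2D` and beyond). The estimate is
non-increasing in the multiplier and inherits a small upward bias from the
Poisson tail of single-copy k-mers (~2–5 points at depth 15) — visible in
the worked example (0.211 measured vs 0.24 planted after the high-copy
families push some mass *below* threshold, and 0.30→~0.32 on the two-copy
fixture from tail leakage).

## Tandem repeats

For each unit length `u`, position `i` is scored against position `i−u`
(+1 match, −4 mismatch; ambiguous residues never match). Loci are the
disjoint maximal-scoring segments of this lag array, found by repeatedly
extracting the maximum-sum segment (ties: smaller end, then smaller start)
and recursing into the flanks until the best score drops below 12. A
segment of lag-array span `m` maps to the sequence interval
`[start, start+m+u)` and is a locus only when `m ≥ u` (≥ 2 units). Candidates
from different units that overlap resolve to the highest score (ties:
shorter unit, then leftmost). A perfect repeat of total length `ℓ` scores
`ℓ−u`, so the shortest reportable perfect microsatellite is 14 bp
(e.g. (AG)₇ → score 12).

Gapped (indel) extension is not modelled: the scan is strictly ungapped and
`n_gaps` is always 0. The −4 gap parameter is retained in the interface for
report completeness. This is the one simplification relative to
full dynamic-programming satellite scanners; in exchange, the scanner's
output is *provably* checkable — `tandem_oracle.exhaustive_find_tandem_repeats`
re-derives the same semantics by brute force (all O(n²) segments scored via
an explicit difference matrix) and the two are asserted equal on random and
planted sequences.

The minisatellite unit ceiling defaults to 100 (configurable to 1000):
the scan is O(n) per unit, so the ceiling bounds runtime linearly; the
validation fixtures only need units ≤ 10. Motifs are normalized to the
lexicographically minimal rotation of the locus's leading unit; where a
planted array abuts background that happens to continue a lag pattern, the
locus legitimately extends and the leading unit (hence the reported motif)
may differ from the planted motif. Micro (1–6) and mini (7–100) classes are
scanned in two independent passes, mirroring the two-run protocol of
satellite scans; summary lengths merge overlaps within class, and the
combined genome fraction merges across classes and divides by the assembly
length excluding ambiguous stretches.

## Gene-set construction

Donor proteins survive the hit filter when at least one alignment has
E ≤ 1e−4 and query coverage ≥ 50% (boundaries inclusive). Candidate spliced
models per retained query are accepted in two rounds: best-scoring model
with similarity ≥ 35%, else best with ≥ 15%, else unannotated; every query
is classified exactly once. Same-strand overlapping models reduce to exactly
one survivor per connected component of the overlap relation (max score,
ties to longer span then lexicographic id); opposite strands never compete.

De novo predictions require consensus between two predictors,
operationalized as same-strand reciprocal span overlap ≥ 50% (the source
protocol gives no criterion; this is the package's choice). Consensus
predictions with pairwise coding-sequence identity ≥ 85% are removed —
*both* members, since such pairs are suspected unmasked transposable
elements and neither copy is trustworthy; `keep_one=True` offers the
representative-keeping alternative. Identity is global end-to-end edit
distance (edlib NW) over the CDS, `1 − d/max(|a|,|b|)`. Survivors overlapping
no homology model on either strand are appended as `source="denovo"`.

## NUMT and repeat content

NUMT hits at E ≤ 1e−4 are merged per scaffold before counting (overlapping
hits become one fragment; identity length-weighted). Mean identity is
length-weighted by default (unweighted available). The assembly fraction —
like every "% of assembly" in the package — uses the assembly length
excluding ambiguous stretches as denominator.

The repeat-content table counts families from the catalog and elements from
the per-copy annotations, with per-class cumulative lengths overlap-merged;
classified (retro + DNA transposon) plus unclassified always equal the
totals row, and percentages are rounded to one decimal.

The read-based repeat fraction treats per-contig depth as copy number:
`l·(d/C)` genomic bp per contig, summed over contigs with
`d ≥ min_freq_multiplier·C` (default multiplier `C`, i.e. a minimum repeat
frequency of `C²` — 400× at 20× coverage) and divided by `G`. The source
description reads literally as `d/(l·C)`, which has inconsistent units;
the implemented form is the dimensionally coherent reading, and the literal
variant is available behind `literal_formula=True` for comparison.

## Synteny

Three order-independent input filters: scaffolds ≥ 100 kb; genes homologous
to multiple locations in either species removed; unknown-linkage-group
targets removed. Afterwards the ortholog map is one-to-one. Blocks are
maximal runs of ≥ 2 consecutive retained genes sharing one target LG,
spanning first gene start to last gene end, kept at ≥ 1 kb. Filtered genes
are transparent to adjacency (they do not break runs); a retained gene
targeting a different LG does. Within-block target order/orientation is not
enforced — blocks check shared location, not collinearity, so inversions do
not break blocks. The synteny fraction denominator is block base pairs on
the scaffold (not gene counts, not scaffold length); a scaffold is syntenic
at modal-LG fraction ≥ 0.95 inclusive, modal ties to more genes then
lexicographic. A single translocated gene forms no block and thus never
de-syntenizes a scaffold; only a translocated *run* of ≥ 2 genes (≥ 1 kb)
can, which the validation fixtures exploit.

## Mitogenome checks

The molecule is circular and a scaffold may derive from either strand, so a
scaffold is order-consistent when its genes form a contiguous run of the
circular reference order forward with matching strands, or reversed with
all strands flipped. Completeness is annotated bp over the reference total
length and is additive over disjoint scaffolds; protein-coding genes shorter
than their reference length are partial, and annotations exceeding it by
> 10% are rejected as suspect. The bundled reference
(`synthetic_reference_order`) is a stylized, synthetic hymenopteran-like
inventory (13 protein-coding + 22 tRNA + 2 rRNA, ~14.7 kb of genes treated
as abutting, control region excluded so self-annotation is exactly 1.0);
real analyses should supply their taxon's reference and total length.

## Synthetic data: what it does and does not emulate

The generators emulate uniform-coverage single-end reads with i.i.d.
substitution errors (no indels, no quality profiles, no pairing), repeat
families as point-substitution divergence from a consensus, NUMTs as
mitogenome fragments at 85–99% identity, genes as reserved intervals, and a
homolog pair whose rearrangements (translocations, strand inversions,
multi-homolog decoys, unknown-LG decoys) map one-to-one onto the synteny
filters. Features are placed without overlap, so truth tables describe the
emitted sequence exactly and truth repeat content is computable exactly.
Consequently, passing tests demonstrate the *estimators'* correctness under
their own model assumptions — they do not certify behaviour under real-read
artefacts (GC bias, duplicated reads, indel errors, heterozygosity) or
repeat structures more tangled than the planted ones.

## Problem sizes and numerical choices

Validation fixtures are 100–200 kb genomes at 15–20× (spectra of ~10⁵
distinct k-mers), 2 kb sequences for the quadratic tandem oracle, and
8–10-scaffold homolog pairs — sizes at which every oracle comparison is
exact and the whole suite runs in well under a minute per stage, chosen as
the smallest scales at which the statistical recovery criteria (5% genome
size, 10-point repeat fractions) are comfortably non-trivial. Determinism:
every generator takes an explicit seed; the pipeline derives per-stage seeds
by fixed offsets from the config seed; reruns are byte-identical. Rounding:
genome size to the nearest base, report percentages via Python's round
(banker's) at the stated precision. Degenerate inputs raise informative
errors rather than returning sentinel values (all-error spectra,
non-positive size-formula numerators, infeasible feature packing, zero-exon
models, annotations beyond scaffold or reference bounds).

## Known limitations

* The tandem scanner's ungapped scoring under-scores arrays whose copies
  drift by indels; such arrays fragment into multiple loci.
* The spectrum repeat fraction inherits Poisson-tail bias at low depth
  (few points upward for unique sequence, partially cancelled by below-
  threshold leakage of true repeat mass).
* Homology candidates carry externally computed similarity/score fields;
  the package does not verify them against the sequences.
* The depth-profile repeat estimate assumes mapping depth scales linearly
  with copy number (no mapping saturation or multi-mapping ambiguity).
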