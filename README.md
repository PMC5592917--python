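# genomesurvey

Survey computations for fragmented, repeat-rich draft genomes — the
quantitative layer of a short-read genome project for a bee genome whose
repetitive content defeats straightforward assembly. The package implements,
as one tested pipeline over synthetic genomes with known ground truth:

* **k-mer spectrum estimation** of genome size, sequencing depth, coverage
  and repetitive fraction;
* **tandem-repeat scanning** for micro- (unit 1–6 bp) and minisatellites
  (unit 7–1000 bp) with affine-style penalties;
* **homology/de novo gene-set construction rules** as filters over
  alignment-hit and prediction tables;
* **NUMT and repeat-element content summaries** (assembly-based and
  coverage-normalized read-based);
* **synteny haplotype blocks** from ortholog gene order against a
  chromosome-scale reference;
* **mitogenome completeness** and circular gene-order checks on transcript
  scaffolds.

## The core estimators

With `N` reads of single-read length `L`, the read set contains
`N·(L−K+1)` k-mer observations at k-mer length `K` (here `K = 25`).
Low-frequency k-mers (frequency ≤ 3) are treated as sequencing errors; their
observation total `B` is subtracted and the remainder divided by the k-mer
depth `D` (the non-error peak of the spectrum):

```
G = (N·(L−K+1) − B) / D          genome size
C = Σᵢ (Rᵢ·Lᵢ) / G               mean per-base coverage over libraries i
```

The repetitive fraction of the genome is the spectrum observation mass above
`1.5·D` over all non-error mass. A second, read-based repeat estimate
normalizes per-contig mean depth by `C`: a contig of length `l` and depth `d`
represents `l·(d/C)` genomic base pairs; summing over contigs whose depth
clears a minimum repeat frequency of `C²` and dividing by `G` gives the
fraction of the genome in highly abundant sequence.

Tandem repeats are scored by lag-`u` self-comparison (+1 match, −4 mismatch,
minimum score 12), so a perfect array of total length `ℓ` and unit `u`
scores `ℓ−u`. Synteny blocks are maximal runs of ≥ 2 consecutive orthologous
genes (spans plus intergenic DNA, ≥ 1 kb) on ≥ 100 kb scaffolds whose
reference targets share one linkage group; a scaffold is syntenic when ≥ 95%
of its block base pairs point at a single linkage group.

## Worked example

The numbered scripts under `analysis/` run each stage on a 200 kb synthetic
genome (three planted repeat families totalling 24% of the genome, 30 tandem
arrays, 6 NUMT insertions at 85–99% identity, 40 gene models, 15× error-free
reads) and on a 10-scaffold homolog pair with injected rearrangements:

```
$ python analysis/02_kmer_survey.py
k-mer survey (k=25):
  depth D = 11.27, error observations B = 2037
  genome size G = 202068 bp (truth 200000, 1.03% off)
  coverage C = 14.85x
  spectrum repeat fraction = 0.211 (truth 0.240)

$ python analysis/06_synteny.py
synteny: 9 blocks on 8 scaffolds (truth match: True)
  8/8 scaffolds >=95% syntenic (100%)
  block bp: 858423 (89.4% of filtered scaffold length)
```

The genome size lands within ~1% of truth (the k-mer depth 11.27 is the
expected `C·(L−K+1)/L = 14.85·76/100 ≈ 11.3`, not the base coverage); the
spectrum repeat fraction tracks the planted 24% repeat content; and the
block builder reproduces the generator's truth decomposition exactly. The
same stages are available as a CLI (`survey run`, `survey kmer`,
`survey tandem`, `survey synteny`, …) writing JSON/TSV reports.

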