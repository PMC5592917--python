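#!/usr/bin/env python
"""Generate the synthetic study genome, read set and homolog pair.

Writes the sequence artifacts under scratch/ (FASTA/FASTQ, regenerable) and a
small truth summary under results/.  Every downstream analysis script
regenerates its inputs deterministically from the same seed, so this script
is for inspection, not a required first step.
"""

import json
from pathlib import Path

from genomesurvey import io as gio
from genomesurvey import synthetic as syn
from genomesurvey.pipeline import SurveyConfig, _genome_spec

SEED = 1

cfg = SurveyConfig(seed=SEED)
scratch = Path("scratch/simulated")
scratch.mkdir(parents=True, exist_ok=True)
results = Path("results")
results.mkdir(exist_ok=True)

spec = _genome_spec(cfg)
genome, truth = syn.generate_genome(spec)
reads = syn.simulate_reads(
    genome,
    syn.ReadSimSpec(coverage=cfg.coverage, read_length=cfg.read_length,
                    error_rate=cfg.error_rate, seed=SEED + 2),
)
gio.write_fasta(genome, scratch / "genome.fasta", description=f"seed={SEED}")
gio.write_fastq(reads, scratch / "reads.fastq")
truth.repeats.to_csv(scratch / "truth_repeats.tsv", sep="\t", index=False)
truth.numts.to_csv(scratch / "truth_numts.tsv", sep="\t", index=False)
truth.tandems.to_csv(scratch / "truth_tandems.tsv", sep="\t", index=False)

pair = syn.generate_homolog_pair(
    syn.HomologPairSpec(n_scaffolds=cfg.pair_n_scaffolds,
                        genes_per_scaffold=cfg.pair_genes_per_scaffold,
                        scaffold_length=cfg.pair_scaffold_length),
    syn.Rearrangements(*cfg.rearrangements),
    seed=SEED + 6,
)
gio.write_fasta(pair.genome_a, scratch / "genome_a.fasta")
gio.write_fasta(pair.genome_b, scratch / "genome_b.fasta")
pair.orthologs.to_csv(scratch / "orthologs.tsv", sep="\t", index=False)

summary = {
    "seed": SEED,
    "genome_length": cfg.genome_length,
    "n_reads": len(reads),
    "true_repeat_fraction": truth.repeat_fraction(cfg.genome_length),
    "n_true_tandem_loci": len(truth.tandems),
    "n_true_numts": len(truth.numts),
    "n_true_genes": len(truth.genes),
    "homolog_pair_truth_blocks": len(pair.truth_blocks),
}
(results / "simulation_truth.json").write_text(json.dumps(summary, indent=2) + "\n")
print("simulated genome + reads + homolog pair")
for k, v in summary.items():
    print(f"  {k}: {v}")
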