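#!/usr/bin/env python
"""Simulate one female-like and one male-like sequencing sample.

Two diploid genomes (500 kb here, standing in for the ~600 Mb genome of a
survey-scale fish) are drawn with the survey's design parameters: GC 41.8%,
SNP heterozygosity 0.37% (female) / 0.38% (male), 27% two-copy repeats,
paired 150-bp reads from 350-bp inserts at 70x with 0.03% base error, plus
small injected fractions of N-rich and low-quality pairs for the QC stage.

Reads (FASTQ) and haplotypes (FASTA) go to scratch/data/; the ground-truth
summaries go to results/.
"""
import sys
from pathlib import Path

import genomesurvey as gs
from genomesurvey.readqc import write_fastq_pairs
from genomesurvey.simulate import (
    inject_artifacts,
    simulate_diploid_genome,
    simulate_reads,
    write_truth_fasta,
    write_truth_json,
)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

SAMPLES = {
    "female": gs.SimulationSpec(
        genome_length=500_000, het_rate=0.0037, seed=101,
        n_fraction_contaminated=0.001, lowq_fraction_contaminated=0.001,
    ),
    "male": gs.SimulationSpec(
        genome_length=500_000, het_rate=0.0038, seed=202,
        n_fraction_contaminated=0.001, lowq_fraction_contaminated=0.001,
    ),
}


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    for name, spec in SAMPLES.items():
        truth = simulate_diploid_genome(spec)
        pairs = simulate_reads(truth, spec)
        pairs, tags = inject_artifacts(pairs, spec)
        prefix = DATA / name
        write_truth_fasta(truth, prefix)
        write_fastq_pairs(pairs, DATA / f"{name}_1.fastq", DATA / f"{name}_2.fastq")
        write_truth_json(truth, spec, RESULTS / f"{name}_truth.json")
        print(
            f"{name}: {spec.genome_length:,} bp genome, {len(truth.snp_positions):,} SNPs "
            f"(rate {len(truth.snp_positions)/spec.genome_length:.4%}), "
            f"GC {truth.realized_gc:.2%}, {len(pairs):,} read pairs "
            f"({len(tags.all_ids)} corrupted for QC)"
        )


if __name__ == "__main__":
    sys.exit(main())
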