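# genomesurvey

A k-mer genome survey toolkit for paired-end short-read data, built for the
situation every new genome project starts in: reads exist, an assembly does
not, and you want the genome's size, heterozygosity, repeat content and
marker landscape before committing to one. It implements the classic
17-mer survey used for fish and other non-model vertebrates — the analysis
behind statements like *"the female genome is 613.16 Mbp with 0.37%
heterozygosity and 27% repeats"* — as a tested, seedable pipeline:

* **readqc** — paired-read filtering (adapter, ≥10% N, >50% bases under
  Q5) and run statistics (raw/clean bases, effective rate, error rate,
  Q20/Q30, GC);
* **kmerspec** — canonical 17-mer spectrum; peak depth; genome size
  `= k-mer number / peak depth`; revised size; heterozygosity from the
  half-depth component via `a½ / (k·(2 − a½))`; repeat ratio beyond
  1.8× the peak;
* **gcdepth** — GC and alignment-free depth in 10-kb windows;
* **ssr** — MISA-dialect microsatellite mining (thresholds 10/6/5/5/5/5,
  compound merging, flank filter, AC/GT-style canonical classes);
* **marker** — presence/absence screening of candidate sex-linked markers
  by k-mer containment, with alignment identity against assemblies;
* **simulate** — a diploid genome + read generator with known SNP rate,
  repeat fraction, GC, coverage and error rate, so every estimator is
  validated against ground truth;
* **report** — one-command orchestration producing consolidated
  JSON/TSV tables.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Simulate a megabase diploid genome with 0.37% heterozygosity, sequence it
error-free at 74×, and run the 17-mer survey:

```python
import genomesurvey as gs

spec = gs.SimulationSpec(genome_length=1_000_000, het_rate=0.0037,
                         repeat_fraction=0.0, coverage=74.0,
                         base_error_rate=0.0, seed=1)
truth = gs.simulate_diploid_genome(spec)
pairs = gs.simulate_reads(truth, spec)
est = gs.run_survey(sequences=[s for p in pairs for s in (p.seq1, p.seq2)])
print(len(truth.snp_positions), est.peak_depth,
      round(est.genome_size / 1e6, 2), round(est.heterozygosity_rate * 100, 4))
```

prints

```
3787 65 1.02 0.3666
```

— the genome carries 3,787 SNPs (realized rate 0.379%); the spectrum peaks
at 65× (per-k-mer depth is coverage scaled by (150−17+1)/150 ≈ 0.89); the
estimated size is 1.02 Mbp (the ±1 integer peak bin bounds the size error
at ~1.5%); and the recovered heterozygosity is 0.3666%, within 0.01 points
of the realized truth.

The same stages run from the shell (`survey simulate|qc|kmer|gcdepth|ssr|
marker|run`), and the numbered drivers under `analysis/` walk a full
two-sample (female/male) survey at 500-kb scale, writing the familiar
survey-style tables under `results/`: run `python analysis/01_*.py`
through `07_*.py` in order (intermediate FASTQ lands in `scratch/`).

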