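#!/usr/bin/env python
"""GC content vs sequencing depth in 10-kb windows over each genome.

Uses the simulated haplotype A as the assembly stand-in and the clean read
sets for the alignment-free depth track (mean canonical 17-mer multiplicity,
edge-corrected for 150-bp reads). Writes results/gcdepth_<sample>.tsv and a
GC-depth scatter figure.
"""
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from genomesurvey.gcdepth import load_fasta, window_depth, window_gc, windows_to_tsv
from genomesurvey.kmerspec import KmerIndex
from genomesurvey.readqc import iter_fastq_sequences

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, name in zip(axes, ("female", "male")):
        seqs = load_fasta(DATA / f"{name}.hapA.fasta")
        fastqs = [DATA / f"{name}_clean_1.fastq", DATA / f"{name}_clean_2.fastq"]
        index = KmerIndex.from_sequences(iter_fastq_sequences(fastqs), k=17)
        windows = window_depth(window_gc(seqs), seqs, index, 17, read_length=150)
        windows_to_tsv(windows, RESULTS / f"gcdepth_{name}.tsv")
        gc = [w.gc_percent for w in windows]
        depth = [w.mean_depth for w in windows]
        ax.scatter(gc, depth, s=12, alpha=0.6)
        ax.set_xlabel("GC content (%)")
        ax.set_title(name)
        print(
            f"{name}: {len(windows)} windows, GC {min(gc):.1f}-{max(gc):.1f}%, "
            f"depth {min(depth):.1f}-{max(depth):.1f}x"
        )
    axes[0].set_ylabel("mean depth (x)")
    fig.tight_layout()
    (RESULTS / "figures").mkdir(parents=True, exist_ok=True)
    fig.savefig(RESULTS / "figures" / "gc_depth.png", dpi=150)
    print("wrote results/gcdepth_*.tsv")


if __name__ == "__main__":
    sys.exit(main())
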