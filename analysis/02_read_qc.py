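#!/usr/bin/env python
"""Filter both samples' read pairs and tabulate run statistics.

Applies the three pair-drop rules (adapter, >=10% N, >50% bases under Q5)
and writes one row per sample — raw/clean bases, effective rate, error rate,
Q20/Q30, GC — to results/table1.tsv, with clean FASTQ under scratch/data/.
"""
import sys
from pathlib import Path

import pandas as pd

from genomesurvey.readqc import filter_read_pairs, read_fastq_pairs, write_fastq_pairs

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    rows = []
    for name in ("female", "male"):
        pairs = read_fastq_pairs(DATA / f"{name}_1.fastq", DATA / f"{name}_2.fastq")
        clean, report = filter_read_pairs(pairs)
        write_fastq_pairs(clean, DATA / f"{name}_clean_1.fastq", DATA / f"{name}_clean_2.fastq")
        row = {"library": name, **report.to_table_row(insert_size=350)}
        rows.append(row)
        print(
            f"{name}: {report.pairs_in:,} pairs in, {report.pairs_out:,} kept "
            f"({report.effective_rate:.2f}% effective), dropped "
            f"{report.pairs_dropped_n} N-rich / {report.pairs_dropped_lowq} low-quality; "
            f"error {report.error_rate:.3f}%, Q20 {report.q20:.2f}%, Q30 {report.q30:.2f}%, "
            f"GC {report.gc_content:.2f}%"
        )
    out = RESULTS / "table1.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
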