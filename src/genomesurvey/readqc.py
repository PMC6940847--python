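"""Paired-read quality filtering and sequencing-run statistics.

A read pair is dropped when (in this order, first failure counts):

1. either mate contains the library adapter (exact substring, if one is given);
2. uncertain bases (N) make up at least 10% of either mate;
3. low-quality bases (Phred < 5) make up more than 50% of either mate.

Survivors pass through unchanged. The accompanying statistics are the usual
run-level accounting: raw/clean base totals, effective rate, mean base error
(``10^(-Q/10)`` averaged over bases), Q20/Q30 and GC content.
"""
from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import EstimationError, FormatError

N_FRACTION_LIMIT = 0.10  # "at least 10%" -> >= is a drop
LOWQ_PHRED = 5  # quality < 5 counts as low-quality
LOWQ_FRACTION_LIMIT = 0.50  # "> 50%" -> strictly greater is a drop
PHRED_OFFSET = 33


@dataclass
class ReadPair:
    """One read pair; qualities are Phred+33 strings, same length as seqs."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def validate(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FormatError(f"read '{self.id}': sequence/quality length mismatch")

    def phred(self, mate: int) -> np.ndarray:
        q = self.qual1 if mate == 1 else self.qual2
        return np.frombuffer(q.encode("ascii"), dtype=np.uint8).astype(np.int16) - PHRED_OFFSET


@dataclass
class QcReport:
    """One row of sequencing-run accounting (raw/clean bases, rates, drops)."""

    raw_bases: int = 0
    clean_bases: int = 0
    pairs_in: int = 0
    pairs_out: int = 0
    pairs_dropped_adapter: int = 0
    pairs_dropped_n: int = 0
    pairs_dropped_lowq: int = 0
    error_rate: float = 0.0  # percent
    q20: float = 0.0  # percent
    q30: float = 0.0  # percent
    gc_content: float = 0.0  # percent

    @property
    def effective_rate(self) -> float:
        """Clean bases as a percent of raw bases."""
        if self.raw_bases == 0:
            return 0.0
        return 100.0 * self.clean_bases / self.raw_bases

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["effective_rate"] = self.effective_rate
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_table_row(self, insert_size: Optional[int] = None) -> dict:
        """Display row (percents to 2 decimals) in run-table column order."""
        row = {
            "insert_size_bp": insert_size,
            "raw_base_bp": self.raw_bases,
            "effective_rate_pct": round(self.effective_rate, 2),
            "clean_base_bp": self.clean_bases,
            "error_rate_pct": round(self.error_rate, 2),
            "q20_pct": round(self.q20, 2),
            "q30_pct": round(self.q30, 2),
            "gc_content_pct": round(self.gc_content, 2),
        }
        if insert_size is None:
            row.pop("insert_size_bp")
        return row


def _open_maybe_gz(path: str | Path, mode: str = "rt") -> IO[str]:
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode)
    return open(p, mode)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    with _open_maybe_gz(path1) as fh1, _open_maybe_gz(path2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2):
            pair = ReadPair(id=id1.split()[0], seq1=s1.upper(), qual1=q1, seq2=s2.upper(), qual2=q2)
            pair.validate()
            yield pair


def iter_fastq_sequences(paths: Sequence[str | Path]) -> Iterator[str]:
    """Stream bare sequences from FASTQ files (both mates, any number of files)."""
    for path in paths:
        with _open_maybe_gz(path) as fh:
            for _, seq, _ in FastqGeneralIterator(fh):
                yield seq.upper()


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with _open_maybe_gz(path1, "wt") as fh1, _open_maybe_gz(path2, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 0.0


def _lowq_fraction(qual: str) -> float:
    if not qual:
        return 0.0
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    return float((arr < LOWQ_PHRED + PHRED_OFFSET).sum()) / len(qual)


def _accumulate_stats(pairs: Sequence[ReadPair]) -> Tuple[int, float, float, float, float]:
    """(bases, error%, q20%, q30%, gc%) over all bases of the given pairs."""
    seqs = []
    quals = []
    for p in pairs:
        seqs.append(p.seq1)
        seqs.append(p.seq2)
        quals.append(p.qual1)
        quals.append(p.qual2)
    seq = "".join(seqs).encode("ascii")
    qual = "".join(quals).encode("ascii")
    n_bases = len(seq)
    if n_bases == 0:
        return 0, 0.0, 0.0, 0.0, 0.0
    q = np.frombuffer(qual, dtype=np.uint8).astype(np.int32) - PHRED_OFFSET
    err = float(np.mean(np.power(10.0, -q / 10.0))) * 100.0
    q20 = 100.0 * float((q >= 20).sum()) / n_bases
    q30 = 100.0 * float((q >= 30).sum()) / n_bases
    s = np.frombuffer(seq, dtype=np.uint8)
    gc = int(((s == ord("G")) | (s == ord("C"))).sum())
    at = int(((s == ord("A")) | (s == ord("T"))).sum())
    gc_pct = 100.0 * gc / (gc + at) if (gc + at) else 0.0
    return n_bases, err, q20, q30, gc_pct


def qc_stats(pairs: Sequence[ReadPair]) -> QcReport:
    """Run statistics of a read-pair collection without filtering."""
    pairs = list(pairs)
    if not pairs:
        raise EstimationError("qc_stats: empty read stream")
    for p in pairs:
        p.validate()
    n_bases, err, q20, q30, gc = _accumulate_stats(pairs)
    return QcReport(
        raw_bases=n_bases,
        clean_bases=n_bases,
        pairs_in=len(pairs),
        pairs_out=len(pairs),
        error_rate=err,
        q20=q20,
        q30=q30,
        gc_content=gc,
    )


def filter_read_pairs(
    pairs: Iterable[ReadPair], adapter: Optional[str] = None
) -> Tuple[List[ReadPair], QcReport]:
    """Apply the three pair-drop rules; report accounts for the clean set.

    Quality statistics (error rate, Q20/Q30, GC) are computed over the clean
    bases; raw/clean totals and per-rule drop counts cover the whole input.
    """
    kept: List[ReadPair] = []
    report = QcReport()
    for pair in pairs:
        pair.validate()
        report.pairs_in += 1
        pair_bases = len(pair.seq1) + len(pair.seq2)
        report.raw_bases += pair_bases
        if adapter and (adapter in pair.seq1 or adapter in pair.seq2):
            report.pairs_dropped_adapter += 1
            continue
        if _n_fraction(pair.seq1) >= N_FRACTION_LIMIT or _n_fraction(pair.seq2) >= N_FRACTION_LIMIT:
            report.pairs_dropped_n += 1
            continue
        if _lowq_fraction(pair.qual1) > LOWQ_FRACTION_LIMIT or _lowq_fraction(pair.qual2) > LOWQ_FRACTION_LIMIT:
            report.pairs_dropped_lowq += 1
            continue
        kept.append(pair)
        report.pairs_out += 1
        report.clean_bases += pair_bases
    if kept:
        _, report.error_rate, report.q20, report.q30, report.gc_content = _accumulate_stats(kept)
    return kept, report
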