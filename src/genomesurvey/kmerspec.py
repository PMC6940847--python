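"""Canonical k-mer spectrum profiling of a short-read set.

The depth histogram of canonical 17-mers carries three signals that a genome
survey reads off before any assembly exists:

* the modal k-mer depth estimates the per-base sequencing depth, and
  ``genome size = k-mer number / peak depth`` (k-mer individuals above the
  low-frequency error cutoff divided by the peak);
* heterozygous k-mers — those overlapping a SNP between the two haplotypes —
  sit at half the homozygous depth, so the weight of a half-depth mixture
  component (``a_half``) converts to a per-base heterozygosity rate via
  ``a_half / (k * (2 - a_half))``;
* k-mers from repeated sequence stack up beyond the main peak, so the
  individual mass past ``1.8 x peak`` estimates the repetitive fraction.

K-mers are counted in canonical (strand-collapsed) form: a window and its
reverse complement are the same species. Windows containing N are skipped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from ._dna import encode
from .errors import EstimationError, ValidationError

MAX_K = 31  # a k-mer must pack into a 64-bit code (2 bits/base)
DEFAULT_K = 17
DEFAULT_MIN_DEPTH = 6  # "low-frequency" means depth <= 5
DEFAULT_REPEAT_MULTIPLIER = 1.8

_CHUNK_BASES = 1 << 24


def _check_k(k: int) -> None:
    if not (1 <= k <= MAX_K):
        raise ValidationError(f"k must be in [1, {MAX_K}], got {k}")


def _canonical_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit codes of the canonical k-mers of an encoded sequence.

    ``arr`` may contain code 4 (N / separator); windows touching such a
    position are dropped.
    """
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = arr > 3
    invalid = None
    if bad.any():
        c = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
        invalid = (c[k:] - c[:-k]) > 0
        arr = np.where(bad, np.uint8(0), arr)
    a = arr.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | a[j : j + n]
        rc |= (np.uint64(3) - a[j : j + n]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rc)
    if invalid is not None:
        canon = canon[~invalid]
    return canon


def _iter_code_chunks(sequences: Iterable[str], k: int) -> Iterator[np.ndarray]:
    """Concatenate encoded sequences (separator-padded) and emit code chunks."""
    sep = np.array([4], dtype=np.uint8)  # acts like N: breaks windows
    buf: list[np.ndarray] = []
    size = 0
    for seq in sequences:
        buf.append(encode(seq))
        buf.append(sep)
        size += len(seq) + 1
        if size >= _CHUNK_BASES:
            yield _canonical_codes(np.concatenate(buf), k)
            buf, size = [], 0
    if buf:
        yield _canonical_codes(np.concatenate(buf), k)


@dataclass
class KmerHistogram:
    """Depth -> species-count table for a fixed k.

    ``species`` are distinct canonical k-mers; ``individuals`` at depth d are
    ``d * species(d)`` — total window occurrences.
    """

    k: int
    counts: Dict[int, int] = field(default_factory=dict)

    def species(self, min_depth: int = 1) -> int:
        return sum(s for d, s in self.counts.items() if d >= min_depth)

    def individuals(self, min_depth: int = 1, max_depth: float = math.inf) -> int:
        return sum(d * s for d, s in self.counts.items() if min_depth <= d <= max_depth)

    @property
    def total_individuals(self) -> int:
        return self.individuals()

    def to_tsv(self, path: str | Path) -> None:
        """Two-column (depth, species) table — the common k-mer ``.histo`` dialect."""
        with open(path, "w") as fh:
            for d in sorted(self.counts):
                fh.write(f"{d}\t{self.counts[d]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = DEFAULT_K) -> "KmerHistogram":
        counts: Dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                d, s = line.split("\t")[:2]
                counts[int(d)] = int(s)
        return cls(k=k, counts=counts)


@dataclass
class KmerIndex:
    """Sorted unique canonical k-mer codes with their read-set counts."""

    k: int
    codes: np.ndarray  # uint64, sorted ascending
    code_counts: np.ndarray  # int64, same length

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], k: int = DEFAULT_K) -> "KmerIndex":
        _check_k(k)
        chunks = [c for c in _iter_code_chunks(sequences, k) if c.size]
        if not chunks:
            return cls(k=k, codes=np.empty(0, np.uint64), code_counts=np.empty(0, np.int64))
        codes = np.concatenate(chunks)
        del chunks
        uniq, cnt = np.unique(codes, return_counts=True)
        return cls(k=k, codes=uniq, code_counts=cnt.astype(np.int64))

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 where absent)."""
        pos = np.searchsorted(self.codes, codes)
        pos = np.minimum(pos, max(self.codes.size - 1, 0))
        out = np.zeros(codes.shape, dtype=np.int64)
        if self.codes.size:
            hit = self.codes[pos] == codes
            out[hit] = self.code_counts[pos[hit]]
        return out

    def histogram(self) -> KmerHistogram:
        if self.code_counts.size == 0:
            return KmerHistogram(k=self.k, counts={})
        depth = np.bincount(self.code_counts)
        return KmerHistogram(
            k=self.k,
            counts={int(d): int(s) for d, s in enumerate(depth) if d >= 1 and s > 0},
        )


def count_kmers(sequences: Iterable[str], k: int = DEFAULT_K) -> KmerHistogram:
    """Canonical k-mer depth histogram of a sequence stream.

    Conservation: total individuals equals the number of N-free length-k
    windows across all input sequences.
    """
    return KmerIndex.from_sequences(sequences, k).histogram()


def detect_peak(
    hist: KmerHistogram, min_depth: int = DEFAULT_MIN_DEPTH, smooth: bool = False
) -> int:
    """Modal depth of the spectrum above the low-frequency cutoff.

    Ties break toward the smaller depth. ``smooth`` applies a centred width-3
    moving average to the species counts before the argmax (off by default).
    """
    depths = np.array(sorted(d for d in hist.counts if d >= min_depth))
    if depths.size == 0:
        raise EstimationError(f"no k-mer mass at depth >= {min_depth}")
    full = np.zeros(int(depths.max()) + 2, dtype=float)
    for d in depths:
        full[d] = hist.counts[d]
    if smooth:
        kernel = np.array([1.0, 1.0, 1.0]) / 3.0
        full = np.convolve(full, kernel, mode="same")
    sl = full[min_depth:]
    return int(np.argmax(sl)) + min_depth


def genome_size_from_counts(kmer_number: int, peak_depth: int) -> float:
    """Genome size in bp: k-mer individuals divided by the peak depth."""
    if peak_depth < 1:
        raise ValidationError(f"peak_depth must be >= 1, got {peak_depth}")
    if kmer_number <= 0:
        raise EstimationError("k-mer number is zero; cannot estimate genome size")
    return kmer_number / peak_depth


@dataclass(frozen=True)
class GenomeSizeResult:
    genome_size: float  # bp
    kmer_number: int
    error_rate_kmer: float  # fraction of individuals discarded below the cutoff
    revised_genome_size: float  # bp


def estimate_genome_size(
    hist: KmerHistogram, peak_depth: int, min_depth: int = DEFAULT_MIN_DEPTH
) -> GenomeSizeResult:
    """Genome size and its error-revised value from the spectrum.

    ``kmer_number`` sums individuals at depth >= ``min_depth``; the error rate
    entering the revision is the fraction of individuals discarded below the
    cutoff (putative sequencing-error k-mers), so
    ``revised = size * (1 - error_rate)``.
    """
    kmer_number = hist.individuals(min_depth=min_depth)
    size = genome_size_from_counts(kmer_number, peak_depth)
    total = hist.total_individuals
    err = (total - kmer_number) / total if total else 0.0
    return GenomeSizeResult(size, kmer_number, err, size * (1.0 - err))


def _mixture_kernel(
    depths: np.ndarray, mean: float, model: str, nb_size: float
) -> np.ndarray:
    if model == "poisson":
        return stats.poisson.pmf(depths, mean)
    if model == "nbinom":
        # variance = mean * (1 + mean / nb_size)
        p = nb_size / (nb_size + mean)
        return stats.nbinom.pmf(depths, nb_size, p)
    raise ValidationError(f"unknown mixture model '{model}'")


def estimate_het_fraction(
    hist: KmerHistogram,
    peak_depth: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    multiplier: float = DEFAULT_REPEAT_MULTIPLIER,
    model: str = "poisson",
    nb_size: float = 200.0,
) -> float:
    """Weight ``a_half`` of the half-depth (heterozygous) spectrum component.

    Fits species counts over depths ``[min_depth, multiplier * peak]`` with a
    nonnegative least-squares mixture of two depth kernels centred at
    ``peak/2`` and ``peak``; returns heterozygous species / total species of
    the two components.
    """
    if peak_depth < 4:
        raise ValidationError(f"peak_depth must be >= 4 for the half-depth fit, got {peak_depth}")
    lo, hi = min_depth, int(math.floor(multiplier * peak_depth))
    depths = np.arange(lo, hi + 1)
    y = np.array([hist.counts.get(int(d), 0) for d in depths], dtype=float)
    if y.sum() <= 0:
        raise EstimationError(
            f"degenerate histogram: no species in depth range [{lo}, {hi}]"
        )
    design = np.column_stack(
        [
            _mixture_kernel(depths, peak_depth / 2.0, model, nb_size),
            _mixture_kernel(depths, float(peak_depth), model, nb_size),
        ]
    )
    if not np.isfinite(design).all() or design.sum() == 0:
        raise EstimationError("mixture kernels are degenerate at this peak depth")
    (w_het, w_hom), _ = optimize.nnls(design, y)
    if w_het + w_hom <= 0:
        raise EstimationError("mixture fit collapsed to zero mass")
    return float(w_het / (w_het + w_hom))


def heterozygosity_rate(a_half: float, k: int) -> float:
    """Per-base SNP rate from the heterozygous k-mer species fraction.

    Each SNP disrupts ~2k k-mer species at half depth, giving
    ``rate = a_half / (k * (2 - a_half))``; monotone increasing in ``a_half``.
    """
    if not (0.0 <= a_half <= 1.0):
        raise ValidationError(f"a_half must be in [0, 1], got {a_half}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return a_half / (k * (2.0 - a_half))


def repeat_ratio(
    hist: KmerHistogram,
    peak_depth: int,
    multiplier: float = DEFAULT_REPEAT_MULTIPLIER,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> float:
    """Fraction of k-mer individuals at depth beyond ``multiplier * peak``."""
    if peak_depth < 1:
        raise ValidationError(f"peak_depth must be >= 1, got {peak_depth}")
    denom = hist.individuals(min_depth=min_depth)
    if denom == 0:
        raise EstimationError("no k-mer individuals above the low-frequency cutoff")
    cutoff = multiplier * peak_depth
    num = sum(d * s for d, s in hist.counts.items() if d > cutoff)
    return num / denom


@dataclass
class SurveyEstimates:
    """One survey row: spectrum-derived genome statistics for one read set."""

    k: int
    peak_depth: int
    kmer_number: int
    n_kspecies: int
    a_half: float
    genome_size: float  # bp
    error_rate_kmer: float
    revised_genome_size: float  # bp
    heterozygosity_rate: float
    repeat_ratio: float

    def to_row(self) -> Dict[str, float]:
        """Display row: Mbp and percents rounded to 2 decimals."""
        return {
            "k": self.k,
            "kmer_depth": self.peak_depth,
            "kmer_number": self.kmer_number,
            "genome_size_mbp": round(self.genome_size / 1e6, 2),
            "revised_genome_size_mbp": round(self.revised_genome_size / 1e6, 2),
            "heterozygous_ratio_pct": round(self.heterozygosity_rate * 100, 2),
            "repeat_pct": round(self.repeat_ratio * 100, 2),
        }


def estimate_from_histogram(
    hist: KmerHistogram,
    min_depth: int = DEFAULT_MIN_DEPTH,
    repeat_multiplier: float = DEFAULT_REPEAT_MULTIPLIER,
    model: str = "poisson",
) -> SurveyEstimates:
    """Compose peak -> size -> heterozygosity -> repeats on one histogram."""
    peak = detect_peak(hist, min_depth=min_depth)
    size = estimate_genome_size(hist, peak, min_depth=min_depth)
    a_half = estimate_het_fraction(
        hist, peak, min_depth=min_depth, multiplier=repeat_multiplier, model=model
    )
    het = heterozygosity_rate(a_half, hist.k)
    rep = repeat_ratio(hist, peak, multiplier=repeat_multiplier, min_depth=min_depth)
    return SurveyEstimates(
        k=hist.k,
        peak_depth=peak,
        kmer_number=size.kmer_number,
        n_kspecies=hist.species(min_depth=min_depth),
        a_half=a_half,
        genome_size=size.genome_size,
        error_rate_kmer=size.error_rate_kmer,
        revised_genome_size=size.revised_genome_size,
        heterozygosity_rate=het,
        repeat_ratio=rep,
    )


def run_survey(
    fastq: Sequence[str | Path] | None = None,
    sequences: Iterable[str] | None = None,
    k: int = DEFAULT_K,
    min_depth: int = DEFAULT_MIN_DEPTH,
    repeat_multiplier: float = DEFAULT_REPEAT_MULTIPLIER,
) -> SurveyEstimates:
    """Full k-mer survey of a read set given FASTQ paths or raw sequences."""
    _check_k(k)
    if sequences is None:
        if not fastq:
            raise ValidationError("run_survey needs FASTQ paths or a sequence stream")
        from .readqc import iter_fastq_sequences

        sequences = iter_fastq_sequences(fastq)
    try:
        hist = count_kmers(sequences, k=k)
    except Exception as exc:  # pragma: no cover - re-raise with stage name
        raise EstimationError(f"k-mer counting failed: {exc}") from exc
    if not hist.counts:
        raise EstimationError("empty read set: no k-mers counted")
    return estimate_from_histogram(
        hist, min_depth=min_depth, repeat_multiplier=repeat_multiplier
    )
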