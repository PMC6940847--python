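"""Diploid genome and paired-end read simulation with known ground truth.

The generator emulates a fish-scale whole-genome shotgun experiment at desk
scale: a diploid genome whose two haplotypes differ by i.i.d. biallelic SNPs
at a chosen rate, a chosen fraction of the genome occupied by exact two-copy
repeats, tunable GC, and paired 150-bp reads from 350-bp fragments at a
chosen fold coverage with i.i.d. substitution errors. Every quantity the
downstream estimators infer (heterozygosity, repeat fraction, GC, coverage)
is therefore known exactly.

Default parameters mirror the sequencing design the estimators are meant for:
paired-end 150 bp, insert 350 bp, ~70x coverage, per-base error 0.03%,
GC 41.8%, SNP heterozygosity 0.37%, repeat fraction 27%.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from ._dna import decode, encode
from .errors import ValidationError
from .readqc import ReadPair, PHRED_OFFSET

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationSpec:
    """Full parameterisation of the synthetic diploid genome + read generator."""

    genome_length: int
    gc_fraction: float = 0.418
    het_rate: float = 0.0037
    repeat_fraction: float = 0.27
    repeat_unit_length: int = 2000  # TE-scale interspersed repeat unit
    coverage: float = 70.0
    read_length: int = 150
    insert_size: int = 350
    base_error_rate: float = 0.0003
    n_fraction_contaminated: float = 0.0
    lowq_fraction_contaminated: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "gc_fraction",
            "het_rate",
            "repeat_fraction",
            "base_error_rate",
            "n_fraction_contaminated",
            "lowq_fraction_contaminated",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < 2 * self.insert_size:
            raise ValidationError(
                f"genome_length must be >= 2 x insert_size, got {self.genome_length}"
            )
        if self.coverage <= 0:
            raise ValidationError(f"coverage must be > 0, got {self.coverage}")
        if self.read_length > self.insert_size:
            raise ValidationError(
                f"read_length ({self.read_length}) must be <= insert_size ({self.insert_size})"
            )
        if self.repeat_unit_length < 1:
            raise ValidationError(
                f"repeat_unit_length must be >= 1, got {self.repeat_unit_length}"
            )

    def n_pairs(self) -> int:
        """Pair count: round(coverage x genome_length / (2 x read_length))."""
        return int(round(self.coverage * self.genome_length / (2 * self.read_length)))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class DiploidTruth:
    """The simulated diploid genome with full ground truth."""

    haplotype_a: str
    haplotype_b: str
    snp_positions: List[int]
    planted_repeats: List[Tuple[int, int, int]]  # (position, length, copy_count)
    realized_gc: float


@dataclass
class ReadOrigins:
    """Provenance of each simulated pair, for validation against the truth."""

    haplotype: np.ndarray  # 0/1 per pair
    fragment_start: np.ndarray  # 0-based start of the insert


@dataclass
class ArtifactTags:
    """Which pair ids were deliberately corrupted, and how."""

    n_ids: Set[str] = field(default_factory=set)
    lowq_ids: Set[str] = field(default_factory=set)

    @property
    def all_ids(self) -> Set[str]:
        return self.n_ids | self.lowq_ids


def _rng(spec: SimulationSpec, stage: int) -> np.random.Generator:
    # stage-separated streams: editing one stage never perturbs another
    return np.random.default_rng([spec.seed, stage])


def simulate_diploid_genome(spec: SimulationSpec) -> DiploidTruth:
    """Draw haplotype A, plant exact two-copy repeats, derive haplotype B.

    Haplotype A bases are i.i.d. with P(G or C) = ``gc_fraction``. Repeats are
    planted by copying one random unit-length slot onto another disjoint slot
    until ``repeat_fraction`` of the genome lies in two-copy families.
    Haplotype B carries i.i.d. biallelic substitutions at ``het_rate``.
    Deterministic given the seed.
    """
    spec.validate()
    G = spec.genome_length
    rng = _rng(spec, 0)
    # base composition: [A, C, G, T]
    probs = np.array(
        [
            (1 - spec.gc_fraction) / 2,
            spec.gc_fraction / 2,
            spec.gc_fraction / 2,
            (1 - spec.gc_fraction) / 2,
        ]
    )
    hap_a = rng.choice(4, size=G, p=probs).astype(np.uint8)

    planted: List[Tuple[int, int, int]] = []
    unit = spec.repeat_unit_length
    if spec.repeat_fraction > 0:
        n_slots = G // unit
        n_families = int(round(spec.repeat_fraction * G / (2 * unit)))
        if 2 * n_families > n_slots:
            raise ValidationError(
                "repeat_fraction/repeat_unit_length leave no room for disjoint repeat copies"
            )
        slots = rng.permutation(n_slots)[: 2 * n_families]
        for i in range(n_families):
            src, dst = int(slots[2 * i]), int(slots[2 * i + 1])
            hap_a[dst * unit : (dst + 1) * unit] = hap_a[src * unit : (src + 1) * unit]
            planted.append((src * unit, unit, 2))
            planted.append((dst * unit, unit, 2))

    hap_b = hap_a.copy()
    snp_positions: List[int] = []
    if spec.het_rate > 0:
        mask = rng.random(G) < spec.het_rate
        pos = np.flatnonzero(mask)
        shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
        hap_b[pos] = (hap_b[pos] + shift) % 4
        snp_positions = [int(p) for p in pos]

    gc = float(((hap_a == 1) | (hap_a == 2)).mean())
    return DiploidTruth(
        haplotype_a=decode(hap_a),
        haplotype_b=decode(hap_b),
        snp_positions=snp_positions,
        planted_repeats=sorted(planted),
        realized_gc=gc,
    )


def _quality_chars(n_reads: int, err: float, rng: np.random.Generator) -> np.ndarray:
    """Per-read constant Phred score whose mean error equals ``err``.

    Mixes the two adjacent integer scores bracketing ``-10 log10(err)`` so the
    expected per-base error is exactly the requested rate. Error-free reads
    get Q60.
    """
    if err <= 0:
        return np.full(n_reads, 60, dtype=np.int16)
    qf = -10.0 * math.log10(err)
    q0 = int(math.floor(qf))
    q1 = q0 + 1
    e0, e1 = 10 ** (-q0 / 10), 10 ** (-q1 / 10)
    p0 = (err - e1) / (e0 - e1) if e0 != e1 else 1.0
    return np.where(rng.random(n_reads) < p0, q0, q1).astype(np.int16)


def _rows_to_strings(mat: np.ndarray) -> List[str]:
    """Decode a (n, L) base-code matrix into n DNA strings."""
    n, L = mat.shape
    blob = _BASE_LOOKUP[mat].tobytes()
    return [blob[i * L : (i + 1) * L].decode("ascii") for i in range(n)]


def simulate_reads(
    truth: DiploidTruth,
    spec: SimulationSpec,
    with_origins: bool = False,
):
    """Paired-end reads from random fragments of a random haplotype each.

    Mate 1 is the fragment's leading ``read_length`` bases; mate 2 is the
    reverse complement of its trailing ``read_length`` bases. Substitution
    errors are i.i.d. at ``base_error_rate``; the quality string encodes the
    realised error model. Returns a list of :class:`~genomesurvey.readqc.ReadPair`
    (plus a :class:`ReadOrigins` when ``with_origins``).
    """
    spec.validate()
    G = spec.genome_length
    rl, ins = spec.read_length, spec.insert_size
    n = spec.n_pairs()
    rng = _rng(spec, 1)

    haps = np.vstack([encode(truth.haplotype_a), encode(truth.haplotype_b)])
    hap_choice = rng.integers(0, 2, size=n)
    starts = rng.integers(0, G - ins + 1, size=n)

    offsets1 = np.arange(rl, dtype=np.int64)
    idx1 = starts[:, None] + offsets1
    reads1 = haps[hap_choice[:, None], idx1]
    del idx1
    idx2 = (starts + ins - rl)[:, None] + offsets1
    frag2 = haps[hap_choice[:, None], idx2]
    del idx2
    reads2 = (3 - frag2[:, ::-1]).astype(np.uint8)  # reverse complement
    del frag2

    if spec.base_error_rate > 0:
        for mat in (reads1, reads2):
            err_mask = rng.random(mat.shape) < spec.base_error_rate
            shift = rng.integers(1, 4, size=int(err_mask.sum())).astype(np.uint8)
            mat[err_mask] = (mat[err_mask] + shift) % 4

    q1 = _quality_chars(n, spec.base_error_rate, rng)
    q2 = _quality_chars(n, spec.base_error_rate, rng)
    qs1 = [chr(q + PHRED_OFFSET) * rl for q in q1]
    qs2 = [chr(q + PHRED_OFFSET) * rl for q in q2]
    seqs1 = _rows_to_strings(reads1)
    seqs2 = _rows_to_strings(reads2)

    pairs = [
        ReadPair(id=f"sim_{i}", seq1=seqs1[i], qual1=qs1[i], seq2=seqs2[i], qual2=qs2[i])
        for i in range(n)
    ]
    if with_origins:
        return pairs, ReadOrigins(haplotype=hap_choice, fragment_start=starts)
    return pairs


def inject_artifacts(
    pairs: Sequence[ReadPair], spec: SimulationSpec
) -> Tuple[List[ReadPair], ArtifactTags]:
    """Corrupt exact fractions of pairs so they must fail the QC filters.

    N-corrupted pairs get ceil(10% of the read) N bases in mate 1 (at least
    10% uncertain); low-quality pairs get just over 50% of mate 1 at Phred 2.
    The two corrupted sets are disjoint; tags record which ids were hit.
    """
    spec.validate()
    pairs = list(pairs)
    n = len(pairs)
    tags = ArtifactTags()
    n_n = int(round(spec.n_fraction_contaminated * n))
    n_q = int(round(spec.lowq_fraction_contaminated * n))
    if n_n + n_q > n:
        raise ValidationError("contamination fractions sum to more than 1")
    if n_n == 0 and n_q == 0:
        return pairs, tags
    rng = _rng(spec, 2)
    chosen = rng.permutation(n)[: n_n + n_q]
    out = list(pairs)
    for j in chosen[:n_n]:
        p = out[j]
        L = len(p.seq1)
        k = math.ceil(N_RUN_FRACTION * L)
        out[j] = ReadPair(p.id, "N" * k + p.seq1[k:], p.qual1, p.seq2, p.qual2)
        tags.n_ids.add(p.id)
    for j in chosen[n_n:]:
        p = out[j]
        L = len(p.qual1)
        k = L // 2 + 1  # strictly more than half the bases
        lowq = chr(2 + PHRED_OFFSET) * k
        out[j] = ReadPair(p.id, p.seq1, lowq + p.qual1[k:], p.seq2, p.qual2)
        tags.lowq_ids.add(p.id)
    return out, tags


N_RUN_FRACTION = 0.10  # matches the QC drop threshold


def write_truth_fasta(truth: DiploidTruth, prefix: str | Path) -> Tuple[Path, Path]:
    """Write the two haplotypes as FASTA files ``<prefix>.hapA/B.fasta``."""
    prefix = Path(prefix)
    paths = []
    for tag, seq in (("hapA", truth.haplotype_a), ("hapB", truth.haplotype_b)):
        path = prefix.with_name(prefix.name + f".{tag}.fasta")
        with open(path, "w") as fh:
            fh.write(f">{tag}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        paths.append(path)
    return paths[0], paths[1]


def write_truth_json(truth: DiploidTruth, spec: SimulationSpec, path: str | Path) -> None:
    """Ground-truth summary (not the sequences) as JSON."""
    with open(path, "w") as fh:
        json.dump(
            {
                "spec": asdict(spec),
                "n_snps": len(truth.snp_positions),
                "realized_gc": truth.realized_gc,
                "n_repeat_copies": len(truth.planted_repeats),
                "repeat_bases": sum(l for _, l, _ in truth.planted_repeats),
            },
            fh,
            indent=2,
        )
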