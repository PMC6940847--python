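"""Microsatellite (SSR) mining in the MISA dialect.

Detects maximal perfect tandem repeats of 1-6-base units with per-unit-length
minimum repeat numbers (10, 6, 5, 5, 5, 5 by default), merges runs closer
than a gap threshold into compound loci, optionally removes loci too close to
contig ends (where flanking sequence is too short to design primers), groups
motifs into canonical classes under rotation + reverse complement (AC/GT,
AGG/CCT, ...), and summarises the results.

Coordinates are 1-based inclusive, as in MISA output.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._dna import encode, revcomp
from .errors import FormatError, ValidationError

DEFAULT_THRESHOLDS: Dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
DEFAULT_MAX_GAP = 100
DEFAULT_MIN_FLANK = 100


@dataclass
class SsrLocus:
    """One microsatellite locus (perfect ``p1..p6`` or compound ``c``)."""

    sequence_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    motif: str
    repeat_number: int
    unit_length: int
    ssr_type: str  # "p1".."p6" or "c"
    canonical_class: Optional[str] = None
    members: Optional[List["SsrLocus"]] = None  # for compound loci

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def annotation(self) -> str:
        """MISA-style SSR column, e.g. ``(AC)6`` or ``(AC)6...(AG)7``."""
        if self.ssr_type == "c" and self.members:
            return "...".join(f"({m.motif}){m.repeat_number}" for m in self.members)
        return f"({self.motif}){self.repeat_number}"


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter unit."""
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical class of a motif under rotation and reverse complement.

    The representative is the lexicographically smallest rotation of the
    motif or its reverse complement, rendered as ``"X/revcomp(X)"``.
    """
    if not (1 <= len(motif) <= 6):
        raise ValidationError(f"motif length must be 1-6, got '{motif}'")
    if not set(motif) <= set("ACGT"):
        raise FormatError(f"motif '{motif}' contains non-ACGT characters")
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    best = min(candidates)
    return f"{best}/{revcomp(best)}"


def find_ssrs(
    sequence: str,
    sequence_id: str = "seq",
    thresholds: Optional[Mapping[int, int]] = None,
) -> List[SsrLocus]:
    """All maximal perfect tandem runs meeting their unit-length threshold.

    N breaks every run; partial trailing units are not counted; a run whose
    unit is a power of a shorter unit is reported at the shorter unit only.
    Loci are sorted by start, then end.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    seq = sequence.upper()
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise FormatError(f"non-DNA characters in sequence '{sequence_id}': {bad}")
    arr = encode(seq)
    L = arr.size
    loci: List[SsrLocus] = []
    for u, min_reps in sorted(thresholds.items()):
        if L < u * min_reps:
            continue
        m = (arr[: L - u] == arr[u:]) & (arr[: L - u] != 4)
        if not m.any():
            continue
        padded = np.concatenate(([False], m, [False])).astype(np.int8)
        edges = np.diff(padded)
        run_starts = np.flatnonzero(edges == 1)
        run_ends = np.flatnonzero(edges == -1)  # exclusive in m-coordinates
        for i, j in zip(run_starts, run_ends):
            total = (j - i) + u  # bases spanned by the perfect run
            reps = total // u
            if reps < min_reps:
                continue
            motif = seq[i : i + u]
            if not _is_primitive(motif):
                continue  # reported at the shorter unit
            loci.append(
                SsrLocus(
                    sequence_id=sequence_id,
                    start=int(i) + 1,
                    end=int(i) + u * reps,
                    motif=motif,
                    repeat_number=int(reps),
                    unit_length=u,
                    ssr_type=f"p{u}",
                    canonical_class=canonical_motif(motif),
                )
            )
    loci.sort(key=lambda l: (l.start, l.end))
    return loci


def merge_compound(
    loci: Sequence[SsrLocus],
    max_gap: int = DEFAULT_MAX_GAP,
    mode: str = "merge",
) -> List[SsrLocus]:
    """Merge (or remove) runs of loci closer than ``max_gap`` on one sequence.

    The inter-locus distance is the number of bases between consecutive loci.
    ``mode="merge"`` joins a chain into one compound ("c") locus spanning it;
    ``mode="remove"`` drops every locus that belongs to such a chain.
    """
    if mode not in ("merge", "remove"):
        raise ValidationError(f"mode must be 'merge' or 'remove', got '{mode}'")
    loci = list(loci)
    for a, b in zip(loci, loci[1:]):
        if a.sequence_id == b.sequence_id and b.start < a.start:
            raise ValidationError("merge_compound requires loci sorted by start")
    out: List[SsrLocus] = []
    chain: List[SsrLocus] = []

    def flush() -> None:
        if not chain:
            return
        if len(chain) == 1:
            out.append(chain[0])
        elif mode == "merge":
            out.append(
                SsrLocus(
                    sequence_id=chain[0].sequence_id,
                    start=chain[0].start,
                    end=chain[-1].end,
                    motif="+".join(m.motif for m in chain),
                    repeat_number=0,
                    unit_length=0,
                    ssr_type="c",
                    members=list(chain),
                )
            )
        chain.clear()

    for locus in loci:
        if chain and (
            locus.sequence_id != chain[-1].sequence_id
            or locus.start - chain[-1].end - 1 > max_gap
        ):
            flush()
        chain.append(locus)
    flush()
    return out


def filter_flanks(
    loci: Iterable[SsrLocus],
    sequence_lengths: Mapping[str, int],
    min_flank: int = DEFAULT_MIN_FLANK,
) -> List[SsrLocus]:
    """Drop loci with less than ``min_flank`` bases of flank on either side."""
    out = []
    for locus in loci:
        L = sequence_lengths[locus.sequence_id]
        if locus.start < 1 or locus.end > L:
            raise ValidationError(
                f"locus {locus.sequence_id}:{locus.start}-{locus.end} outside sequence (len {L})"
            )
        if (locus.start - 1) < min_flank or (L - locus.end) < min_flank:
            continue
        out.append(locus)
    return out


@dataclass
class SsrSummary:
    """Mining summary: totals, per-unit-length and per-class breakdowns."""

    sequences_examined: int = 0
    total_ssrs: int = 0
    sequences_with_ssr: int = 0
    sequences_with_more_than_one: int = 0
    compound_ssrs: int = 0
    per_unit_counts: Dict[int, int] = field(default_factory=dict)
    per_class_counts: Dict[str, int] = field(default_factory=dict)

    def unit_percents(self, decimals: int = 2) -> Dict[int, float]:
        """Share of each unit length among all SSRs, in percent."""
        if self.total_ssrs == 0:
            return {u: 0.0 for u in self.per_unit_counts}
        return {
            u: round(100.0 * c / self.total_ssrs, decimals)
            for u, c in sorted(self.per_unit_counts.items())
        }

    def class_percents(self, unit_length: Optional[int] = None, decimals: int = 2) -> Dict[str, float]:
        """Share of each canonical class, optionally within one unit length."""
        items = self.per_class_counts.items()
        if unit_length is not None:
            items = [(c, n) for c, n in items if len(c.split("/")[0]) == unit_length]
        denom = sum(n for _, n in items)
        if denom == 0:
            return {}
        return {c: round(100.0 * n / denom, decimals) for c, n in sorted(items)}

    def to_dict(self) -> dict:
        return {
            "sequences_examined": self.sequences_examined,
            "total_ssrs": self.total_ssrs,
            "sequences_with_ssr": self.sequences_with_ssr,
            "sequences_with_more_than_one": self.sequences_with_more_than_one,
            "compound_ssrs": self.compound_ssrs,
            "per_unit_counts": dict(sorted(self.per_unit_counts.items())),
            "per_unit_percents": self.unit_percents(),
            "per_class_counts": dict(sorted(self.per_class_counts.items())),
        }


def summarize_ssrs(loci: Sequence[SsrLocus], sequences_examined: int) -> SsrSummary:
    """Tabulate the output of the mining pipeline.

    A compound locus counts once in ``total_ssrs`` and once in the compound
    row; its member motifs contribute to the per-class breakdown.
    """
    summary = SsrSummary(sequences_examined=sequences_examined, total_ssrs=len(loci))
    per_seq: Dict[str, int] = {}
    for locus in loci:
        per_seq[locus.sequence_id] = per_seq.get(locus.sequence_id, 0) + 1
        if locus.ssr_type == "c":
            summary.compound_ssrs += 1
            members = locus.members or []
        else:
            members = [locus]
            summary.per_unit_counts[locus.unit_length] = (
                summary.per_unit_counts.get(locus.unit_length, 0) + 1
            )
        for m in members:
            cls = m.canonical_class or canonical_motif(m.motif)
            summary.per_class_counts[cls] = summary.per_class_counts.get(cls, 0) + 1
    summary.sequences_with_ssr = len(per_seq)
    summary.sequences_with_more_than_one = sum(1 for v in per_seq.values() if v > 1)
    return summary


def scan_sequences(
    sequences: Mapping[str, str],
    thresholds: Optional[Mapping[int, int]] = None,
    max_gap: int = DEFAULT_MAX_GAP,
    min_flank: int = DEFAULT_MIN_FLANK,
    compound_mode: str = "merge",
) -> List[SsrLocus]:
    """Full pipeline per sequence: detect -> compound -> flank filter."""
    out: List[SsrLocus] = []
    lengths = {sid: len(s) for sid, s in sequences.items()}
    for sid, seq in sequences.items():
        loci = find_ssrs(seq, sequence_id=sid, thresholds=thresholds)
        loci = merge_compound(loci, max_gap=max_gap, mode=compound_mode)
        if min_flank > 0:
            loci = filter_flanks(loci, lengths, min_flank=min_flank)
        out.extend(loci)
    return out


def loci_to_misa_table(loci: Sequence[SsrLocus]) -> pd.DataFrame:
    """MISA-style table: ID, SSR nr., type, SSR, size, start, end."""
    rows = []
    per_seq: Dict[str, int] = {}
    for locus in loci:
        per_seq[locus.sequence_id] = per_seq.get(locus.sequence_id, 0) + 1
        rows.append(
            {
                "ID": locus.sequence_id,
                "SSR nr.": per_seq[locus.sequence_id],
                "SSR type": locus.ssr_type,
                "SSR": locus.annotation(),
                "size": locus.length,
                "start": locus.start,
                "end": locus.end,
            }
        )
    return pd.DataFrame(
        rows, columns=["ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end"]
    )
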