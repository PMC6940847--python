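"""Presence/absence screening of candidate sex-linked markers.

Given k-mer indexes of a male and a female read set (or assembly), a marker
such as a candidate sex-determination gene fragment (the Dmrt1 use-case in
fishes with an XY system) is called present when a sufficient fraction of
its canonical k-mers occurs in the target. A marker that is present in one
sex and essentially absent from the other is flagged sex-specific. Against
assembled targets, a global-alignment percent identity over the best-matching
span is also reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from Bio import Align

from ._dna import encode, revcomp
from .errors import ValidationError
from .kmerspec import KmerIndex, _canonical_codes

DEFAULT_PRESENCE_THRESHOLD = 0.5


@dataclass
class MarkerHit:
    marker_id: str
    present: bool
    kmer_containment: float
    best_identity: Optional[float] = None  # percent, assembled targets only
    best_location: Optional[Tuple[str, int, int]] = None  # (seq id, start, end) 0-based


@dataclass
class MarkerScreenResult:
    male: MarkerHit
    female: MarkerHit
    male_specific: bool
    female_specific: bool


def kmer_containment(marker: str, target_index: KmerIndex, k: int) -> float:
    """Fraction of the marker's canonical k-mers present in the target index."""
    if k != target_index.k:
        raise ValidationError(f"index was built at k={target_index.k}, requested k={k}")
    if len(marker) < k:
        raise ValidationError(f"marker shorter than k={k} (length {len(marker)})")
    codes = _canonical_codes(encode(marker.upper()), k)
    if codes.size == 0:
        raise ValidationError("marker has no N-free k-mer window")
    return float((target_index.lookup(codes) >= 1).mean())


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def percent_identity(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Identity of the optimal global alignment: 100 x matches / columns."""
    if not a or not b:
        raise ValidationError("percent_identity requires nonempty sequences")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()  # gaps, identities, mismatches
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns


def best_alignment_hit(
    marker: str,
    sequences: Mapping[str, str],
    k: int = 17,
    pad: int = 0,
) -> Tuple[Optional[float], Optional[Tuple[str, int, int]]]:
    """Best percent identity of the marker against assembled sequences.

    Anchors candidate placements with exact k-mer seeds sampled along the
    marker (both strands), aligns the marker globally to a marker-length
    window at each anchor (``pad`` extra bases on each side tolerate small
    indels at the cost of gap columns), and returns the best identity with
    its location. Returns ``(None, None)`` when no seed matches.
    """
    marker = marker.upper()
    m = len(marker)
    if m < k:
        raise ValidationError(f"marker shorter than k={k}")
    seeds = [(off, marker[off : off + k]) for off in range(0, m - k + 1, k)]
    best: Tuple[float, Optional[Tuple[str, int, int]]] = (-1.0, None)
    for sid, seq in sequences.items():
        seq = seq.upper()
        for strand in (1, -1):
            query = marker if strand == 1 else revcomp(marker)
            for off, _ in seeds:
                seed = query[off : off + k]
                pos = seq.find(seed)
                while pos != -1:
                    start = max(0, pos - off - pad)
                    end = min(len(seq), pos - off + m + pad)
                    window = seq[start:end]
                    ident = percent_identity(query, window)
                    if ident > best[0]:
                        best = (ident, (sid, start, end))
                    pos = seq.find(seed, pos + 1)
    if best[0] < 0:
        return None, None
    return best[0], best[1]


def screen_marker(
    marker: str,
    male_index: KmerIndex,
    female_index: KmerIndex,
    k: int = 17,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    male_assembly: Optional[Mapping[str, str]] = None,
    female_assembly: Optional[Mapping[str, str]] = None,
    marker_id: str = "marker",
) -> MarkerScreenResult:
    """Call a marker present/absent in each sex and flag sex-specificity.

    Present means containment >= ``presence_threshold``; "absent from the
    other sex" means containment < ``1 - presence_threshold``. Sex-specific =
    present in one sex and absent from the other (both directions reported).
    """
    if male_index.k != female_index.k:
        raise ValidationError(
            f"male and female indexes disagree on k ({male_index.k} vs {female_index.k})"
        )
    hits = {}
    for sex, index, assembly in (
        ("male", male_index, male_assembly),
        ("female", female_index, female_assembly),
    ):
        containment = kmer_containment(marker, index, k)
        identity, location = (None, None)
        if assembly:
            identity, location = best_alignment_hit(marker, assembly, k=k)
        hits[sex] = MarkerHit(
            marker_id=marker_id,
            present=containment >= presence_threshold,
            kmer_containment=containment,
            best_identity=identity,
            best_location=location,
        )
    absent_female = hits["female"].kmer_containment < 1.0 - presence_threshold
    absent_male = hits["male"].kmer_containment < 1.0 - presence_threshold
    return MarkerScreenResult(
        male=hits["male"],
        female=hits["female"],
        male_specific=hits["male"].present and absent_female,
        female_specific=hits["female"].present and absent_male,
    )
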