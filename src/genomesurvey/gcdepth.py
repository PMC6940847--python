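"""GC content and sequencing depth in fixed non-overlapping windows.

The GC-versus-depth scatter over 10-kb windows exposes compositional
sequencing bias and, in heterozygous genomes, a half-depth layer of windows.
Depth here is estimated alignment-free: the mean read-set multiplicity of a
window's canonical k-mers. Because a read of length L contributes L-k+1
windows, the raw k-mer multiplicity underestimates fold coverage by the
factor (L-k+1)/L; pass ``read_length`` to correct for it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
from Bio import SeqIO

from ._dna import encode
from .errors import EstimationError, ValidationError
from .kmerspec import KmerIndex, _canonical_codes

DEFAULT_WINDOW = 10_000


@dataclass
class GcDepthWindow:
    sequence_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    gc_percent: float  # nan when the window is all N
    mean_depth: float = float("nan")


def load_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _as_sequences(assembly) -> Dict[str, str]:
    if isinstance(assembly, (str, Path)):
        return load_fasta(assembly)
    return dict(assembly)


def window_gc(assembly, window: int = DEFAULT_WINDOW) -> List[GcDepthWindow]:
    """Per-window GC percent over full windows; trailing partials are dropped.

    GC is computed over non-N bases; an all-N window gets ``nan``.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    seqs = _as_sequences(assembly)
    if not seqs:
        raise EstimationError("empty assembly: no sequences to window")
    out: List[GcDepthWindow] = []
    for sid, seq in seqs.items():
        arr = encode(seq)
        for w in range(len(seq) // window):
            start, end = w * window, (w + 1) * window
            sub = arr[start:end]
            gc = int(((sub == 1) | (sub == 2)).sum())
            at = int(((sub == 0) | (sub == 3)).sum())
            pct = 100.0 * gc / (gc + at) if (gc + at) else float("nan")
            out.append(GcDepthWindow(sid, start, end, pct))
    return out


def window_depth(
    windows: List[GcDepthWindow],
    assembly,
    index: KmerIndex,
    k: int,
    read_length: Optional[int] = None,
) -> List[GcDepthWindow]:
    """Fill ``mean_depth``: mean read-set count of each window's canonical k-mers.

    Windows with no valid (N-free) k-mer get depth 0. With ``read_length``
    the read-edge factor L/(L-k+1) converts k-mer multiplicity to an estimate
    of fold coverage.
    """
    if k != index.k:
        raise ValidationError(f"index was built at k={index.k}, requested k={k}")
    seqs = _as_sequences(assembly)
    corr = 1.0
    if read_length is not None:
        if read_length <= k:
            raise ValidationError(f"read_length must exceed k={k}")
        corr = read_length / (read_length - k + 1)
    for win in windows:
        seq = seqs[win.sequence_id][win.start : win.end]
        codes = _canonical_codes(encode(seq), k)
        if codes.size == 0:
            win.mean_depth = 0.0
        else:
            win.mean_depth = float(index.lookup(codes).mean()) * corr
    return windows


def windows_to_tsv(windows: Iterable[GcDepthWindow], path: str | Path) -> None:
    """Scatter-ready TSV; all-N (gc undefined) windows are excluded."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tstart\tend\tgc_percent\tmean_depth\n")
        for w in windows:
            if math.isnan(w.gc_percent):
                continue
            depth = "" if math.isnan(w.mean_depth) else f"{w.mean_depth:.4f}"
            fh.write(f"{w.sequence_id}\t{w.start}\t{w.end}\t{w.gc_percent:.4f}\t{depth}\n")
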