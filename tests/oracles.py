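"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation's code paths: plain Python
dictionaries and string handling for k-mer counting, regex backreferences
for SSR detection, and exhaustive recursion for tiny global alignments.
"""
from __future__ import annotations

import re
from itertools import product
from typing import Dict, List, Set, Tuple

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def naive_kmer_histogram(sequences, k: int) -> Dict[int, int]:
    """Canonical k-mer depth histogram by dictionary counting."""
    counts: Dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) - set("ACGT"):
                continue
            canon = min(w, revcomp(w))
            counts[canon] = counts.get(canon, 0) + 1
    hist: Dict[int, int] = {}
    for depth in counts.values():
        hist[depth] = hist.get(depth, 0) + 1
    return hist


def _primitive(motif: str) -> bool:
    u = len(motif)
    return not any(u % d == 0 and motif == motif[:d] * (u // d) for d in range(1, u))


def regex_ssrs(seq: str, thresholds: Dict[int, int]) -> Set[Tuple[int, int, str]]:
    """Maximal perfect tandem runs via regex backreferences.

    Returns {(start_1based, end_1based, motif)} for primitive motifs meeting
    their unit-length threshold; partial trailing units are excluded by the
    backreference itself.
    """
    seq = seq.upper()
    out: Set[Tuple[int, int, str]] = set()
    for u, min_reps in thresholds.items():
        pat = re.compile(r"([ACGT]{%d})\1{%d,}" % (u, min_reps - 1))
        for start in range(len(seq) - u * min_reps + 1):
            if seq[start] != seq[start + u]:  # cheap pre-check, no run here
                continue
            m = pat.match(seq, start)
            if not m:
                continue
            motif = m.group(1)
            if not _primitive(motif):
                continue
            # left-maximality: the run must not extend one base left
            if start > 0 and seq[start - 1] in "ACGT" and seq[start - 1] == seq[start + u - 1]:
                continue
            reps = (m.end() - start) // u
            out.add((start + 1, start + u * reps, motif))
    return out


def exhaustive_global_alignments(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """All optimal global alignments of two tiny strings by recursion.

    Returns (best_score, set of identity percents over optimal alignments).
    """
    best: Dict[Tuple[int, int], float] = {}

    def score(i: int, j: int) -> float:
        if (i, j) in best:
            return best[(i, j)]
        if i == len(a) and j == len(b):
            s = 0.0
        elif i == len(a):
            s = gap * (len(b) - j)
        elif j == len(b):
            s = gap * (len(a) - i)
        else:
            s = max(
                score(i + 1, j + 1) + (match if a[i] == b[j] else mismatch),
                score(i + 1, j) + gap,
                score(i, j + 1) + gap,
            )
        best[(i, j)] = s
        return s

    top = score(0, 0)
    idents: Set[float] = set()

    def walk(i: int, j: int, matches: int, columns: int) -> None:
        if i == len(a) and j == len(b):
            idents.add(100.0 * matches / columns)
            return
        if i < len(a) and j < len(b):
            step = match if a[i] == b[j] else mismatch
            if score(i + 1, j + 1) + step == score(i, j):
                walk(i + 1, j + 1, matches + (a[i] == b[j]), columns + 1)
        if i < len(a) and score(i + 1, j) + gap == score(i, j):
            walk(i + 1, j, matches, columns + 1)
        if j < len(b) and score(i, j + 1) + gap == score(i, j):
            walk(i, j + 1, matches, columns + 1)

    walk(0, 0, 0, 0)
    return top, idents
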