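"""Low-level DNA encoding shared across modules.

Bases are packed as A=0, C=1, G=2, T=3; anything else (N, lowercase handled
separately) encodes to 4 and marks the position as invalid for k-mer windows.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES.encode()):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)
_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array (A=0 C=1 G=2 T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 renders as N."""
    return bytes(_DEC[arr]).decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N, case preserved)."""
    return seq.translate(_RC_TABLE)[::-1]


_DNA_SET = frozenset("ACGTacgt")
_DNA_N_SET = frozenset("ACGTNacgtn")


def is_dna(seq: str, allow_n: bool = True) -> bool:
    return set(seq) <= (_DNA_N_SET if allow_n else _DNA_SET)
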