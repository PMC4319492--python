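"""Low-level DNA sequence helpers shared across modules.

Sequences are plain Python strings over the alphabet ACGT at the API
surface; internally most routines work on uint8 code arrays (A=0, C=1,
G=2, T=3) so that comparisons vectorize.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

BASES = "ACGT"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A",
         "a": "t", "c": "g", "g": "c", "t": "a"}
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array; rejects non-ACGT."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(BASES[c] for c in arr)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_CODE[arr[::-1]]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (half-up), as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
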