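"""Low-level nucleotide helpers shared across modules.

Sequences are plain upper-case strings over {A,C,G,T,N}; hot paths work on
uint8 code arrays (A=0, C=1, G=2, T=3, N=4).
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
GAP_CODE = 5  # used by MSA machinery; never appears in plain sequences

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN-", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 4:
        bad = chr(ord(seq[int(np.argmax(arr > 4))]))
        raise ValueError(f"non-ACGTN character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def is_valid_alphabet(seq: str, allow_n: bool = True) -> bool:
    allowed = set("ACGTN" if allow_n else "ACGT")
    return set(seq) <= allowed
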