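"""Small DNA helpers shared across modules.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3; anything else maps to a
code >= 4 and is treated as "unknown" by downstream counting. With this
encoding the complement of a valid code ``c`` is ``3 - c``.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENCODE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (read-only view)."""
    return np.frombuffer(seq.encode("ascii").translate(_ENCODE), dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes (all < 4) back into a DNA string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
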