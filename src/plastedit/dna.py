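"""Small sequence helpers shared across the package.

Bases are handled in two forms: Python strings (external interfaces,
FASTA/FASTQ) and numpy uint8 code arrays with A=0, C=1, G=2, T=3
(internal pileup arithmetic).  Complementation in code space is ``3 - b``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array."""
    codes = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains a non-ACGT character")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGT string."""
    return _DECODE[codes].tobytes().decode()


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes).astype(np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return complement_codes(codes)[::-1]


def circular_slice(codes: np.ndarray, start0: int, length: int) -> np.ndarray:
    """Slice ``length`` bases starting at 0-based ``start0``, wrapping the origin."""
    n = codes.shape[0]
    idx = (start0 + np.arange(length)) % n
    return codes[idx]
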