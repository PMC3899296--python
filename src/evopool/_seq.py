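"""Nucleotide encoding helpers.

Bases are coded A=0, C=1, G=2, T=3 throughout the package; sequences are
held as ``uint8`` numpy arrays so pileup counting can be fully vectorised.
"""
from __future__ import annotations

import numpy as np

from .errors import InvalidArgument

BASE_BYTES = b"ACGT"
BASES = tuple("ACGT")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASE_BYTES):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(BASE_BYTES, dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array; rejects other symbols."""
    raw = np.frombuffer(seq.encode() if isinstance(seq, str) else seq, dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise InvalidArgument(f"sequence contains non-ACGT symbol {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - np.asarray(codes, dtype=np.uint8))[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
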