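"""Nucleotide encoding shared across modules.

Bases are stored as uint8 codes A=0, C=1, G=2, T=3; 4 means N/other.
All genome arrays, read matrices and allele fields use this encoding;
strings appear only at file-format boundaries.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    """Decode uint8 codes back into an uppercase string."""
    return _DECODE_BYTES[arr].tobytes().decode("ascii")


def decode_rows(mat: np.ndarray) -> list[str]:
    """Decode each row of a 2-D code matrix into a string."""
    n, L = mat.shape
    ascii_mat = _DECODE_BYTES[mat]
    flat = ascii_mat.tobytes()
    return [flat[i * L:(i + 1) * L].decode("ascii") for i in range(n)]


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (N maps to N)."""
    comp = np.where(arr < 4, 3 - arr, N_CODE).astype(np.uint8)
    return comp[::-1]
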