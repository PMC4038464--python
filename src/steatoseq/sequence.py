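"""Small nucleotide <-> integer-code helpers shared by the simulator and mapper.

Bases are coded A=0, C=1, G=2, T=3, N=4 in uint8 arrays; 32-mers over
{A,C,G,T} pack exactly into one uint64 (2 bits/base, first base in the
highest bits so integer order equals lexicographic order).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
N_CODE = 4

_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(BASES):
    _ENCODE[ord(b)] = i
    _ENCODE[ord(b.lower())] = i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """String -> uint8 code array; raises on characters outside ACGTN."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"unexpected character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the code alphabet (N stays N)."""
    comp = codes[..., ::-1].copy()
    acgt = comp < 4
    comp[acgt] = 3 - comp[acgt]
    return comp


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def pack_kmers(codes: np.ndarray, k: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer of a code vector into uint64 keys.

    Returns ``(keys, valid)`` of length ``len(codes) - k + 1``; ``valid`` is
    False wherever the window contains a non-ACGT code. Requires ``k <= 32``.
    """
    if k > 32:
        raise ValueError("k must be <= 32 to fit in uint64")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    keys = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.uint64)
    invalid = codes >= 4
    for j in range(k):
        keys <<= np.uint64(2)
        keys |= np.where(invalid[j:j + n], np.uint64(0), c[j:j + n])
        bad |= invalid[j:j + n]
    return keys, ~bad


def pack_rows(code_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pack each row (length <= 32) of a 2-D code array into a uint64 key."""
    n, k = code_rows.shape
    if k > 32:
        raise ValueError("row length must be <= 32")
    keys = np.zeros(n, dtype=np.uint64)
    invalid = code_rows >= 4
    c = code_rows.astype(np.uint64)
    for j in range(k):
        keys <<= np.uint64(2)
        keys |= np.where(invalid[:, j], np.uint64(0), c[:, j])
    return keys, ~invalid.any(axis=1)
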