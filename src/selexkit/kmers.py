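"""Shared k-mer machinery: integer encoding, reverse complement, canonical keys.

Everything downstream (background models, counting, affinity estimation, the
simulator) works on 2-bit integer codes; ``N`` is carried as code 4 so that
windows touching an ambiguous base can be masked out cheaply.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
#: base -> code; N deliberately maps to 4 (out of alphabet)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Palindromic (reverse-complement-symmetric) k-mers map to themselves.
    """
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def encode(sequences: list[str] | np.ndarray) -> np.ndarray:
    """Encode equal-length sequences to an (n, L) int8 code matrix (A,C,G,T,N -> 0..4).

    Raises ``ValueError`` on letters outside {A,C,G,T,N}.
    """
    if isinstance(sequences, np.ndarray) and sequences.dtype == np.int8:
        return sequences
    joined = "".join(sequences)
    flat = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if (flat < 0).any():
        bad = set(joined) - set("ACGTNacgtn")
        raise ValueError(f"sequences contain letters outside ACGTN: {sorted(bad)!r}")
    n = len(sequences)
    return flat.reshape(n, -1) if n else flat.reshape(0, 0)


def decode(codes: np.ndarray) -> list[str]:
    """Inverse of :func:`encode` for an (n, L) code matrix."""
    alph = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return [bytes(alph[row]).decode("ascii") for row in np.asarray(codes, dtype=np.int64)]


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All length-``k`` windows of each row as packed base-4 integers.

    Returns ``(fwd, rc, valid)``: forward codes, reverse-complement codes and a
    boolean mask that is False for windows overlapping an N.  Shapes are
    ``(n, L-k+1)``.
    """
    codes = np.asarray(codes)
    n, L = codes.shape
    if k > L:
        raise ValueError(f"k={k} exceeds read length {L}")
    win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)  # (n, L-k+1, k)
    valid = ~(win == 4).any(axis=2)
    w = win.astype(np.int64)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = (np.where(w == 4, 0, w) * pw).sum(axis=2)
    # revcomp: complement (3-c) read right-to-left
    rc = ((3 - np.where(w == 4, 0, w)) * pw[::-1]).sum(axis=2)
    return fwd, rc, valid


def pack(codes: np.ndarray) -> np.ndarray:
    """Pack an (n, k) code matrix (no N) into base-4 integers."""
    codes = np.asarray(codes, dtype=np.int64)
    k = codes.shape[1]
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return codes @ pw


def unpack(packed: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`pack` -> (n, k) int8 code matrix."""
    packed = np.asarray(packed, dtype=np.int64).reshape(-1, 1)
    shifts = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return ((packed // shifts) % 4).astype(np.int8)


def rc_packed(packed: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes."""
    return pack(3 - unpack(packed, k)[:, ::-1])


def kmer_string(code: int, k: int) -> str:
    """Decode one packed k-mer integer to a string."""
    return decode(unpack(np.array([code]), k))[0]


def n_canonical_kmers(k: int) -> int:
    """Number of distinct canonical k-mers: (4^k + #palindromes)/2.

    Odd k has no reverse-complement palindromes; even k has 4^(k/2).
    """
    pal = 0 if k % 2 else 4 ** (k // 2)
    return (4**k + pal) // 2
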