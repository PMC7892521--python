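"""CArG-box enumeration and A-tract analysis.

MADS-domain dimers bind the 10-bp CArG-box; the SRF-type consensus is
CC(A/T)6GG.  Counted modulo reverse complement there are exactly 36 distinct
SRF-type boxes (64 centres, 8 of them reverse-complement palindromic).
A-tracts — runs of at least four consecutive A·T base pairs with all A's
before all T's (A^n T^m, n+m >= 4, no intervening TpA step) — rigidify the
helix and narrow the minor groove, and are the structural feature behind the
preference of SEPALLATA3-like proteins for particular CArG centres.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .kmers import canonical as _canonical
from .kmers import revcomp


def canonicalize(seq: str) -> str:
    """Lexicographic min of ``seq`` and its reverse complement."""
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in {seq!r}")
    return _canonical(seq)


def has_a_tract(seq: str, min_len: int = 4) -> tuple[bool, tuple[int, int] | None]:
    """Does ``seq`` contain an A-tract (A^n T^m substring, n+m >= min_len)?

    Pure A-runs and pure T-runs qualify (n or m may be zero).  Returns the
    leftmost longest qualifying interval as 0-based half-open coordinates, or
    ``None``.  TpA steps break a tract, ApT steps do not.
    """
    best: tuple[int, int] | None = None
    i, L = 0, len(seq)
    while i < L:
        if seq[i] not in "AT":
            i += 1
            continue
        # maximal A^n T^m segment starting at i
        j = i
        while j < L and seq[j] == "A":
            j += 1
        while j < L and seq[j] == "T":
            j += 1
        if j - i >= min_len and (best is None or j - i > best[1] - best[0]):
            best = (i, j)
        # next segment can start inside a T-run only at a fresh A (TpA breaks),
        # or at the first base after this segment
        nxt = i + 1
        while nxt < j and seq[nxt] == "A":
            nxt += 1
        i = max(nxt, i + 1)
    return (best is not None), best


@dataclass(frozen=True)
class CargBoxRecord:
    """One canonical SRF-type CArG-box with its annotations."""

    sequence: str  # canonical 10-mer
    center: str  # 6-mer between the CC and GG borders
    has_a_tract: bool
    affinity: float | None = None
    count: int | None = None
    missing: bool = False  # True when absent from the joined affinity table


def is_srf_cargbox(seq: str) -> bool:
    """Exact match to CC(A/T)6GG on either strand."""
    for s in (seq, revcomp(seq)):
        if len(s) == 10 and s[:2] == "CC" and s[8:] == "GG" and set(s[2:8]) <= set("AT"):
            return True
    return False


def enumerate_srf_cargboxes() -> list[CargBoxRecord]:
    """All distinct canonical CC(A/T)6GG boxes, lexicographically sorted.

    36 records: 64 W6 centres collapse modulo reverse complement
    (8 centres are self-reverse-complementary).
    """
    seen: dict[str, CargBoxRecord] = {}
    for center in map("".join, product("AT", repeat=6)):
        seq = f"CC{center}GG"
        canon = _canonical(seq)
        if canon not in seen:
            tract, _ = has_a_tract(canon[2:8])
            seen[canon] = CargBoxRecord(
                sequence=canon, center=canon[2:8], has_a_tract=tract
            )
    return [seen[s] for s in sorted(seen)]


def atract_affinity_table(aff) -> list[CargBoxRecord]:
    """The 36 SRF-type CArG-boxes joined with a 10-mer affinity table, ranked.

    Sorted by affinity descending with lexicographic tie-break; boxes absent
    from the table get affinity 0 and a ``missing`` flag rather than being
    dropped.
    """
    if aff.k != 10:
        raise ValueError(f"CArG-box analysis needs k=10 affinities, got k={aff.k}")
    rows = []
    for rec in enumerate_srf_cargboxes():
        a = aff.affinities.get(rec.sequence)
        cnt = aff.counts.get(rec.sequence) if aff.counts is not None else None
        rows.append(
            CargBoxRecord(
                sequence=rec.sequence,
                center=rec.center,
                has_a_tract=rec.has_a_tract,
                affinity=float(a) if a is not None else 0.0,
                count=int(cnt) if cnt is not None else None,
                missing=a is None,
            )
        )
    rows.sort(key=lambda r: (-r.affinity, r.sequence))
    return rows


def top_kmers(aff, n: int = 21) -> list[tuple[str, float]]:
    """The n highest-affinity canonical k-mers, ties broken lexicographically."""
    items = sorted(aff.affinities.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(w, float(a)) for w, a in items[:n]]
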