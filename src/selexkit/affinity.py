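"""K-mer counting, motif-length selection and relative-affinity estimation.

Relative affinity of a k-mer w after r selection rounds is estimated as
(observed count / expected count under the R0 background)^(1/r), normalised
so the strongest k-mer scores exactly 1.  The motif length is chosen by the
information gain IG(k) — the Kullback–Leibler divergence between the
selected-round k-mer distribution and the background — which saturates once
k covers the physical binding site; the smallest k within ``plateau_tol`` of
the maximum is selected (KL is non-decreasing under refinement, so the
printed "maximum" is a saturation onset).

All counting is strand-merged onto canonical keys by default: occupancy has
no strand, so w and its reverse complement are the same binding event.

IG uses the plug-in estimator restricted to k-mers observed at least
``min_count`` times (default 5, the same reliability floor the affinity
table flags).  Without the floor the sparse-cell noise of large k inflates
the estimate without bound; with it, IG measures only what is reliably
observed, which is what saturates at the true site length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background import MarkovBackground
from .kmers import canonical, decode, rc_packed, unpack, window_codes
from .probes import ReadPool, write_tsv


@dataclass
class KmerCountTable:
    """Sliding-window k-mer counts, canonicalised when ``merge_revcomp``."""

    k: int
    merge_revcomp: bool
    total_windows: int
    packed: np.ndarray = field(repr=False)  # unique (canonical) k-mer codes
    values: np.ndarray = field(repr=False)  # counts, same order

    file_suffix = ".counts.tsv"
    export_name = "kmer_counts"
    _counts: dict | None = field(default=None, repr=False, compare=False)

    @property
    def counts(self) -> dict[str, int]:
        """k-mer string -> count (built lazily)."""
        if self._counts is None:
            strings = decode(unpack(self.packed, self.k))
            self._counts = dict(zip(strings, self.values.tolist()))
        return self._counts

    def save(self, path) -> None:
        rows = [{"kmer": w, "count": c} for w, c in sorted(self.counts.items())]
        write_tsv(rows, path, ["kmer", "count"])


def count_kmers(pool: ReadPool, k: int, merge_revcomp: bool = True) -> KmerCountTable:
    """Count all length-k windows; windows overlapping an N are skipped."""
    if not pool.sequences:
        raise ValueError("cannot count k-mers in an empty pool")
    if k > pool.read_length:
        raise ValueError(f"k={k} exceeds read length {pool.read_length}")
    fwd, rc, valid = window_codes(pool.codes(), k)
    keys = np.minimum(fwd, rc) if merge_revcomp else fwd
    uniq, counts = np.unique(keys[valid], return_counts=True)
    return KmerCountTable(
        k=k,
        merge_revcomp=merge_revcomp,
        total_windows=int(valid.sum()),
        packed=uniq,
        values=counts,
    )


def _merged_background_probs(
    bg: MarkovBackground, packed: np.ndarray, k: int, merge_revcomp: bool
) -> np.ndarray:
    """Background probability of each (canonical) packed k-mer.

    With merging, P(canonical w) = P(w) + P(revcomp w), palindromes unchanged;
    the merged probabilities sum to 1 over canonical keys, so no further
    renormalisation is needed.
    """
    p = np.exp(bg.kmer_log_probs(unpack(packed, k)))
    if not merge_revcomp:
        return p
    rc = rc_packed(packed, k)
    p_rc = np.exp(bg.kmer_log_probs(unpack(rc, k)))
    return np.where(rc == packed, p, p + p_rc)


def information_gain(
    pool_r: ReadPool,
    bg: MarkovBackground,
    k: int,
    *,
    min_count: int = 5,
    merge_revcomp: bool = True,
) -> float:
    """IG(k) = sum_w f(w) * log2(f(w) / p0(w)) in bits, over reliable k-mers.

    f are observed window frequencies, p0 the background probabilities merged
    onto canonical keys; the sum runs over k-mers observed at least
    ``min_count`` times (unobserved cells contribute 0 by continuity).
    """
    table = count_kmers(pool_r, k, merge_revcomp)
    keep = table.values >= max(1, min_count)
    if not keep.any():
        return 0.0
    f = table.values[keep] / table.total_windows
    p0 = _merged_background_probs(bg, table.packed[keep], k, merge_revcomp)
    return float((f * np.log2(f / p0)).sum())


def plateau_onset(profile: dict[int, float], tol: float = 0.01) -> int:
    """Smallest k whose IG reaches (1 - tol) of the profile maximum.

    KL divergence is non-decreasing under refinement, so "the maximal k" is
    read as the onset of saturation rather than a literal argmax.
    """
    if not profile:
        raise ValueError("empty profile")
    ig_max = max(profile.values())
    threshold = (1.0 - tol) * ig_max
    return min(k for k, ig in profile.items() if ig >= threshold)


def select_k(
    pool_r: ReadPool,
    bg: MarkovBackground,
    k_range=range(6, 15),
    plateau_tol: float = 0.01,
    *,
    min_count: int = 5,
) -> tuple[int, dict[int, float]]:
    """Plateau-onset motif length: smallest k with IG(k) >= (1-tol) * max IG."""
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k range")
    if ks != list(range(min(ks), max(ks) + 1)):
        raise ValueError("k range must be contiguous")
    profile = {k: information_gain(pool_r, bg, k, min_count=min_count) for k in ks}
    return plateau_onset(profile, plateau_tol), profile


@dataclass
class AffinityTable:
    """Canonical k-mer -> relative affinity in (0, 1], max exactly 1."""

    k: int
    round_used: int
    provenance: str  # "R1", "R2", ..., or "loess"
    affinities: dict[str, float]
    counts: dict[str, int] | None = None
    expected: dict[str, float] | None = None
    raw: dict[str, float] | None = None
    low_confidence: set[str] = field(default_factory=set)

    file_suffix = ".affinity.tsv"
    export_name = "affinities"

    def affinity(self, kmer: str) -> float:
        """Affinity of a k-mer queried in either orientation."""
        return self.affinities[canonical(kmer)]

    def save(self, path) -> None:
        rows = []
        for w in sorted(self.affinities):
            rows.append(
                {
                    "kmer": w,
                    "count": self.counts.get(w, "") if self.counts else "",
                    "expected": self.expected.get(w, "") if self.expected else "",
                    "raw": self.raw.get(w, "") if self.raw else "",
                    "affinity": self.affinities[w],
                    "flag": "low_count" if w in self.low_confidence else "ok",
                }
            )
        write_tsv(rows, path, ["kmer", "count", "expected", "raw", "affinity", "flag"])

    @classmethod
    def load(cls, path, k: int | None = None, provenance: str = "file") -> "AffinityTable":
        affinities: dict[str, float] = {}
        counts: dict[str, int] = {}
        expected: dict[str, float] = {}
        raw: dict[str, float] = {}
        low: set[str] = set()
        with open(path) as fh:
            header = fh.readline()
            while header.startswith("#"):
                header = fh.readline()
            idx = {c: i for i, c in enumerate(header.rstrip("\n").split("\t"))}
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                w = fields[idx["kmer"]]
                affinities[w] = float(fields[idx["affinity"]])
                if fields[idx["count"]]:
                    counts[w] = int(fields[idx["count"]])
                if fields[idx["expected"]]:
                    expected[w] = float(fields[idx["expected"]])
                if fields[idx["raw"]]:
                    raw[w] = float(fields[idx["raw"]])
                if fields[idx["flag"]] == "low_count":
                    low.add(w)
        k = k if k is not None else len(next(iter(affinities)))
        return cls(
            k=k,
            round_used=0,
            provenance=provenance,
            affinities=affinities,
            counts=counts or None,
            expected=expected or None,
            raw=raw or None,
            low_confidence=low,
        )


def estimate_affinities(
    pool_r: ReadPool,
    bg: MarkovBackground,
    k: int,
    r: int | None = None,
    *,
    merge_revcomp: bool = True,
    count_floor: int = 5,
) -> AffinityTable:
    """Relative affinities from one selected round.

    raw(w) = (observed / expected)^(1/r); affinities are raw / max(raw).
    k-mers observed fewer than ``count_floor`` times are kept but flagged
    low-confidence rather than removed.
    """
    r = r if r is not None else pool_r.round_index
    if r < 1:
        raise ValueError("affinity estimation needs a selected round (r >= 1)")
    table = count_kmers(pool_r, k, merge_revcomp)
    p0 = _merged_background_probs(bg, table.packed, k, merge_revcomp)
    exp_counts = table.total_windows * p0
    raw = (table.values / exp_counts) ** (1.0 / r)
    aff = raw / raw.max()
    strings = decode(unpack(table.packed, k))
    low = {w for w, c in zip(strings, table.values) if c < count_floor}
    return AffinityTable(
        k=k,
        round_used=r,
        provenance=f"R{r}",
        affinities=dict(zip(strings, aff.tolist())),
        counts=dict(zip(strings, table.values.tolist())),
        expected=dict(zip(strings, exp_counts.tolist())),
        raw=dict(zip(strings, raw.tolist())),
        low_confidence=low,
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    return np.clip(1 - np.abs(u) ** 3, 0, None) ** 3


def local_linear_fit(
    x: np.ndarray, y: np.ndarray, x0: np.ndarray, span: float
) -> np.ndarray:
    """Degree-1 tricube local regression of y on x evaluated at x0.

    For each evaluation point the ceil(span*n) nearest data points get
    tricube weights scaled by the span radius, then a weighted straight line
    is fitted.  Plain and per-point; quadratic cost, intended for n up to a
    few thousand.
    """
    n = len(x)
    q = max(2, int(np.ceil(span * n)))
    fitted = np.empty(len(x0))
    for i, c in enumerate(x0):
        d = np.abs(x - c)
        if q < n:
            idx = np.argpartition(d, q - 1)[:q]
        else:
            idx = np.arange(n)
        dmax = d[idx].max()
        w = np.ones(len(idx)) if dmax == 0 else _tricube(d[idx] / dmax)
        xw, yw = x[idx], y[idx]
        sw = w.sum()
        mx = (w * xw).sum() / sw
        my = (w * yw).sum() / sw
        sxx = (w * (xw - mx) ** 2).sum()
        slope = 0.0 if sxx == 0 else (w * (xw - mx) * (yw - my)).sum() / sxx
        fitted[i] = my + slope * (c - mx)
    return fitted


def loess_combine(
    aff_r1: AffinityTable,
    aff_r2: AffinityTable,
    span: float = 0.5,
    *,
    max_exact: int = 2000,
    grid_size: int = 201,
) -> AffinityTable:
    """Integrate two rounds: LOESS of log(aff_r2) on log(aff_r1).

    Enrichment is multiplicative across rounds, hence the log scale.  The
    combined estimate is exp(fitted value), renormalised to max 1.  Above
    ``max_exact`` shared keys the smoother is evaluated on a grid and
    interpolated (numerically indistinguishable at default grid size).
    """
    if aff_r1.k != aff_r2.k:
        raise ValueError("affinity tables have different k")
    shared = sorted(set(aff_r1.affinities) & set(aff_r2.affinities))
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared k-mers; need at least 10")
    x = np.log(np.array([aff_r1.affinities[w] for w in shared]))
    y = np.log(np.array([aff_r2.affinities[w] for w in shared]))
    if len(shared) <= max_exact:
        fitted = local_linear_fit(x, y, x, span)
    else:
        grid = np.linspace(x.min(), x.max(), grid_size)
        fg = local_linear_fit(x, y, grid, span)
        fitted = np.interp(x, grid, fg)
    combined = np.exp(fitted)
    combined = combined / combined.max()
    counts = (
        {w: aff_r2.counts[w] for w in shared if w in aff_r2.counts}
        if aff_r2.counts
        else None
    )
    return AffinityTable(
        k=aff_r1.k,
        round_used=aff_r2.round_used,
        provenance="loess",
        affinities=dict(zip(shared, combined.tolist())),
        counts=counts,
        low_confidence=aff_r1.low_confidence | aff_r2.low_confidence,
    )
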