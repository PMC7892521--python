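"""Markov background models of the initial (R0) SELEX library.

Even "random" synthesis libraries carry composition biases (synthesis
chemistry, PCR).  Relative enrichment is therefore measured against an
order-m Markov model fitted to R0 rather than against a uniform expectation.
The order is chosen by cross-replicate prediction: a model trained on one R0
replicate predicts 8-mer counts in the other, scored by the coefficient of
determination R²; the smallest order within 0.001 of the best R² wins
(near-ties between neighbouring orders are common, parsimony breaks them).

Each read window is treated as starting from the m-mer marginal estimated
from all read positions ("stationary-style"); at the 25-nt read lengths used
here, end effects are negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmers import kmer_string, pack, rc_packed, unpack
from .probes import ReadPool


@dataclass
class MarkovBackground:
    """Order-m background: initial m-mer marginal + P(base | previous m bases)."""

    order: int
    initial: np.ndarray  # (4^m,) distribution over m-mers
    conditionals: np.ndarray  # (4^m, 4), rows sum to 1
    pseudocount: float

    file_suffix = ".background.txt"
    export_name = "background"

    def __post_init__(self) -> None:
        if not np.allclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.conditionals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional distributions must sum to 1")

    # -- probabilities ------------------------------------------------------

    def kmer_log_probs(self, codes: np.ndarray) -> np.ndarray:
        """log P(w) for each row of an (n, k) code matrix (codes 0..3, no N)."""
        codes = np.asarray(codes, dtype=np.int64)
        n, k = codes.shape
        m = self.order
        with np.errstate(divide="ignore"):
            log_init = np.log(self.initial)
            log_cond = np.log(self.conditionals)
        if k <= m:
            # marginalise the initial m-mer distribution over the suffix
            marg = self.initial.reshape(4**k, -1).sum(axis=1)
            with np.errstate(divide="ignore"):
                return np.log(marg)[pack(codes)]
        out = log_init[pack(codes[:, :m])] if m > 0 else np.zeros(n)
        ctx = pack(codes[:, :m]) if m > 0 else np.zeros(n, dtype=np.int64)
        for i in range(m, k):
            b = codes[:, i]
            out = out + log_cond[ctx, b]
            ctx = (ctx * 4 + b) % (4**m) if m > 0 else ctx
        return out

    def kmer_prob(self, seq: str) -> float:
        from .kmers import encode

        return float(np.exp(self.kmer_log_probs(encode([seq]))[0]))

    def all_kmer_probs(self, k: int) -> np.ndarray:
        """P(w) for every k-mer, indexed by packed code (feasible for k <= ~10)."""
        m = self.order
        if k <= m:
            return self.initial.reshape(4**k, -1).sum(axis=1)
        p = self.initial.copy()
        for t in range(m, k):
            ctx = np.arange(4**t, dtype=np.int64) % (4**m)
            p = (p[:, None] * self.conditionals[ctx]).ravel()
        return p

    def log_likelihood(self, pool: ReadPool) -> float:
        """Total log-likelihood of a pool's reads under the chained model."""
        return float(self.kmer_log_probs(pool.codes()).sum())

    # -- serialisation ------------------------------------------------------

    def save(self, path) -> None:
        m = self.order
        with open(path, "w") as out:
            out.write(f"# selexkit Markov background\norder\t{m}\n")
            out.write(f"pseudocount\t{float(self.pseudocount)!r}\n")
            out.write("[initial]\n")
            for code, p in enumerate(self.initial):
                out.write(f"{kmer_string(code, m) if m else '-'}\t{float(p)!r}\n")
            out.write("[conditionals]\n")
            for code, row in enumerate(self.conditionals):
                ctx = kmer_string(code, m) if m else "-"
                out.write(ctx + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def load(cls, path) -> "MarkovBackground":
        order = None
        alpha = 0.0
        init: list[float] = []
        cond: list[list[float]] = []
        section = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if line == "[initial]":
                    section = "init"
                    continue
                if line == "[conditionals]":
                    section = "cond"
                    continue
                fields = line.split("\t")
                if section is None:
                    if fields[0] == "order":
                        order = int(fields[1])
                    elif fields[0] == "pseudocount":
                        alpha = float(fields[1])
                elif section == "init":
                    init.append(float(fields[1]))
                else:
                    cond.append([float(x) for x in fields[1:]])
        return cls(
            order=order,
            initial=np.array(init),
            conditionals=np.array(cond),
            pseudocount=alpha,
        )


def fit_markov(pool: ReadPool, order: int, pseudocount: float = 0.5) -> MarkovBackground:
    """Additive-smoothing ML fit from all read positions (forward strand only).

    The initial distribution is the m-mer marginal over all length-m read
    windows; conditionals come from all (m+1)-windows.
    """
    m = order
    if m < 0:
        raise ValueError("order must be >= 0")
    codes = pool.codes()
    if codes.shape[1] < m + 1:
        raise ValueError(f"order {m} needs reads of length >= {m + 1}")
    if (codes == 4).any():
        raise ValueError("background fitting does not accept reads containing N")
    alpha = float(pseudocount)

    if m == 0:
        initial = np.ones(1)
        base_counts = np.bincount(codes.ravel(), minlength=4).astype(float) + alpha
        conditionals = (base_counts / base_counts.sum()).reshape(1, 4)
        return MarkovBackground(m, initial, conditionals, alpha)

    win = np.lib.stride_tricks.sliding_window_view(codes, m, axis=1)
    mcodes = pack(win.reshape(-1, m))
    init_counts = np.bincount(mcodes, minlength=4**m).astype(float) + alpha
    initial = init_counts / init_counts.sum()

    win1 = np.lib.stride_tricks.sliding_window_view(codes, m + 1, axis=1)
    codes1 = pack(win1.reshape(-1, m + 1))
    joint = np.bincount(codes1, minlength=4 ** (m + 1)).astype(float).reshape(4**m, 4)
    joint += alpha
    rowsum = joint.sum(axis=1, keepdims=True)
    # contexts never observed (possible only at alpha = 0) fall back to uniform
    conditionals = np.where(rowsum > 0, joint / np.where(rowsum == 0, 1, rowsum), 0.25)
    return MarkovBackground(m, initial, conditionals, alpha)


def expected_kmer_counts(
    bg: MarkovBackground,
    k: int,
    n_reads: int,
    read_length: int,
    merge_revcomp: bool = False,
) -> dict[str, float]:
    """Expected k-mer counts for a pool of ``n_reads`` reads of ``read_length``.

    Expected count = n_reads * (read_length - k + 1) * P(w).  With
    ``merge_revcomp`` the expectations of w and its reverse complement are
    summed onto the canonical (lexicographically smaller) key; palindromes map
    to themselves.
    """
    if k > read_length:
        raise ValueError("k exceeds read length")
    windows = n_reads * (read_length - k + 1)
    p = bg.all_kmer_probs(k)
    expected = windows * p
    if not merge_revcomp:
        from .kmers import decode

        strings = decode(unpack(np.arange(4**k), k))
        return dict(zip(strings, expected.tolist()))
    codes = np.arange(4**k, dtype=np.int64)
    rc = rc_packed(codes, k)
    canon_mask = codes <= rc
    merged = expected.copy()
    nonpal = codes < rc
    merged[nonpal] += expected[rc[nonpal]]
    from .kmers import decode

    keep = codes[canon_mask]
    strings = decode(unpack(keep, k))
    return dict(zip(strings, merged[canon_mask].tolist()))


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(((observed - predicted) ** 2).sum())
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def select_order(
    poolA: ReadPool,
    poolB: ReadPool,
    orders=range(0, 6),
    k: int = 8,
    pseudocount: float = 0.5,
    tol: float = 0.001,
) -> tuple[int, dict[int, float]]:
    """Cross-replicate order selection: best order + full R² profile.

    For each candidate order a model fitted on one replicate predicts the
    other replicate's observed 8-mer counts; R² over all 4^8 8-mers is
    averaged over both directions.  Returns the smallest order whose R² is
    within ``tol`` of the maximum.
    """
    if poolA is poolB or poolA.sequences is poolB.sequences:
        raise ValueError(
            "order selection needs two R0 replicates; with a single pool, "
            "split it in half and pass the halves"
        )
    orders = list(orders)
    if not orders:
        raise ValueError("no candidate orders given")

    def observed_vector(pool: ReadPool) -> np.ndarray:
        fwd, _, valid = _windows(pool, k)
        return np.bincount(fwd[valid], minlength=4**k).astype(float)

    def _windows(pool: ReadPool, k: int):
        from .kmers import window_codes

        return window_codes(pool.codes(), k)

    obs = {id(p): observed_vector(p) for p in (poolA, poolB)}
    profile: dict[int, float] = {}
    for m in orders:
        r2s = []
        for train, test in ((poolA, poolB), (poolB, poolA)):
            bg = fit_markov(train, m, pseudocount)
            windows = len(test) * (test.read_length - k + 1)
            predicted = windows * bg.all_kmer_probs(k)
            r2s.append(_r2(obs[id(test)], predicted))
        profile[m] = float(np.mean(r2s))
    best_r2 = max(profile.values())
    best = min(m for m, r in profile.items() if r >= best_r2 - tol)
    return best, profile
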