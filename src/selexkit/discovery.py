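"""Affinity-weighted de novo PWM discovery and guided flank analysis.

The training set for discovery is the high-affinity k-mers (score > 0.4),
each padded with k/2 N's on both sides and weighted by 10^3 times its
affinity.  A one-occurrence-per-sequence (OOPS) EM then searches all window
positions on both strands for a single PWM of length 10: because both
complete boxes and incomplete ones (borders swallowed by the adapter) are in
the set, the latent window alignment is what lines them up.  N positions are
marginalised: they contribute an emission factor of 1 under both the motif
and the uniform background, which keeps likelihoods comparable across
sequences with different N counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .cargbox import is_srf_cargbox
from .kmers import revcomp
from .probes import ReadPool

_IUPAC_PAIRS = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}

IUPAC_SETS = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "M": {"A", "C"},
    "R": {"A", "G"},
    "W": {"A", "T"},
    "S": {"C", "G"},
    "Y": {"C", "T"},
    "K": {"G", "T"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

BASES = "ACGT"


@dataclass
class WeightedSequenceSet:
    """Equal-length sequences over ACGTN with strictly positive weights."""

    sequences: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.sequences) != len(self.weights):
            raise ValueError("sequences and weights differ in length")
        if (self.weights <= 0).any():
            raise ValueError("weights must be strictly positive")
        if self.sequences:
            L = len(self.sequences[0])
            if any(len(s) != L for s in self.sequences):
                raise ValueError("sequences must have equal length")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass
class PositionWeightMatrix:
    """L x 4 column-stochastic motif model (columns A, C, G, T)."""

    probs: np.ndarray
    pseudocount: float = 0.0
    orientation: str = "+"

    file_suffix = ".meme"
    export_name = "pwm"
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be L x 4")
        if (self.probs < 0).any():
            raise ValueError("PWM probabilities must be >= 0")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PositionWeightMatrix":
        pwm = PositionWeightMatrix(
            probs=self.probs[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            orientation="-" if self.orientation == "+" else "+",
        )
        pwm.name = self.name
        return pwm

    def consensus(self) -> str:
        return iupac_consensus(self)

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (2 - entropy)."""
        p = np.clip(self.probs, 1e-12, None)
        return 2.0 + (p * np.log2(p)).sum(axis=1)

    # MEME minimal motif format ------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as out:
            out.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            out.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
            out.write(f"MOTIF {self.name}\n")
            out.write(
                f"letter-probability matrix: alength= 4 w= {len(self)} "
                f"nsites= 20 E= 0\n"
            )
            for row in self.probs:
                out.write(" ".join("%.6f" % x for x in row) + "\n")

    @classmethod
    def load(cls, path) -> "PositionWeightMatrix":
        rows = []
        name = "motif"
        with open(path) as fh:
            in_matrix = False
            for line in fh:
                line = line.strip()
                if line.startswith("MOTIF"):
                    name = line.split()[1]
                if line.startswith("letter-probability matrix"):
                    in_matrix = True
                    continue
                if in_matrix:
                    if not line:
                        break
                    rows.append([float(x) for x in line.split()])
        probs = np.array(rows)
        probs = probs / probs.sum(axis=1, keepdims=True)
        pwm = cls(probs=probs)
        pwm.name = name
        return pwm

    def logo_table(self) -> list[dict]:
        """Numeric logo rows: position, base, probability, IC contribution."""
        ic = self.information_content()
        rows = []
        for j in range(len(self)):
            for b, base in enumerate(BASES):
                rows.append(
                    {
                        "position": j + 1,
                        "base": base,
                        "probability": float(self.probs[j, b]),
                        "bits": float(self.probs[j, b] * ic[j]),
                    }
                )
        return rows


def iupac_consensus(pwm: PositionWeightMatrix) -> str:
    """Per-column consensus: single base if dominant (p1 >= 0.5 and p1 >= 2 p2),
    two-letter IUPAC code if p1 + p2 >= 0.75, else N."""
    out = []
    for col in pwm.probs:
        order = np.argsort(-col, kind="stable")
        p1, p2 = col[order[0]], col[order[1]]
        if p1 >= 0.5 and p1 >= 2 * p2:
            out.append(BASES[order[0]])
        elif p1 + p2 >= 0.75:
            out.append(_IUPAC_PAIRS[frozenset({BASES[order[0]], BASES[order[1]]})])
        else:
            out.append("N")
    return "".join(out)


def consensus_matches(consensus: str, pattern: str) -> int:
    """Number of positions where two IUPAC strings are compatible
    (non-empty intersection of their base sets)."""
    if len(consensus) != len(pattern):
        raise ValueError("length mismatch")
    return sum(
        1 for a, b in zip(consensus, pattern) if IUPAC_SETS[a] & IUPAC_SETS[b]
    )


def build_training_set(
    aff, cutoff: float = 0.4, scale: float = 1e3
) -> WeightedSequenceSet:
    """High-affinity k-mers, N-padded by k/2 on each side, weight = scale * affinity."""
    if not aff.affinities:
        raise ValueError("empty affinity table")
    k = aff.k
    pad = "N" * (k // 2)
    seqs, weights = [], []
    for w in sorted(aff.affinities):
        a = aff.affinities[w]
        if a > cutoff:
            seqs.append(pad + w + pad)
            weights.append(scale * a)
    if not seqs:
        raise ValueError(
            f"no k-mer has affinity > {cutoff}; lower the cutoff"
        )
    return WeightedSequenceSet(sequences=seqs, weights=np.array(weights))


def _one_hot(sequences: list[str]) -> np.ndarray:
    """(n, L, 4) one-hot; N rows are all-zero (marginalised)."""
    from .kmers import encode

    codes = encode(sequences)
    n, L = codes.shape
    X = np.zeros((n, L, 4))
    mask = codes < 4
    idx = np.nonzero(mask)
    X[idx[0], idx[1], codes[idx]] = 1.0
    return X


def _em_run(
    X: np.ndarray,
    weights: np.ndarray,
    L: int,
    p0: np.ndarray,
    *,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    """One EM run; returns (ML motif probs, final weighted LL, LL trace)."""
    n, Ls, _ = X.shape
    n_pos = Ls - L + 1
    Xc = X[:, :, ::-1]  # complemented channels; with reversed window = revcomp
    # constant part: uniform background over all non-N positions
    non_n = X.sum(axis=2)  # (n, Ls)
    log_bg = non_n.sum(axis=1) * np.log(0.25)
    p = p0.copy()
    ll_trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        delta = np.log(np.clip(p, 1e-12, None)) - np.log(0.25)  # (L, 4)
        S_plus = np.zeros((n, n_pos))
        S_minus = np.zeros((n, n_pos))
        for j in range(L):
            lut_p = X @ delta[j]  # (n, Ls); 0 at N positions
            lut_m = Xc @ delta[j]
            S_plus += lut_p[:, j : j + n_pos]
            # motif pos j on minus strand sits at sequence pos o + L-1-j
            S_minus += lut_m[:, L - 1 - j : L - 1 - j + n_pos]
        S = np.concatenate([S_plus, S_minus], axis=1)  # (n, 2*n_pos)
        smax = S.max(axis=1, keepdims=True)
        ex = np.exp(S - smax)
        Z = ex.sum(axis=1)
        ll = float(
            (weights * (log_bg + smax[:, 0] + np.log(Z) - np.log(2 * n_pos))).sum()
        )
        R = ex / Z[:, None] * weights[:, None]  # responsibilities * weight
        counts = np.zeros((L, 4))
        Rp, Rm = R[:, :n_pos], R[:, n_pos:]
        for o in range(n_pos):
            wp = Rp[:, o]
            wm = Rm[:, o]
            counts += np.tensordot(wp, X[:, o : o + L, :], axes=(0, 0))
            counts += np.tensordot(wm, Xc[:, o : o + L, :][:, ::-1, :], axes=(0, 0))
        p = counts + 1e-9
        p = p / p.sum(axis=1, keepdims=True)
        ll_trace.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return p, ll_trace[-1], ll_trace


def discover_pwm(
    wset: WeightedSequenceSet,
    L: int = 10,
    restarts: int = 200,
    seed: int = 0,
    *,
    pseudocount: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> PositionWeightMatrix:
    """Best-of-``restarts`` OOPS EM for a single PWM on both strands.

    The weighted log-likelihood is asserted non-decreasing within each run.
    The winning run's motif gets ``pseudocount`` added per cell, and the
    orientation is canonicalised so the consensus places CC before GG when
    that rule discriminates (lexicographic tie-break when it does not).
    """
    if not wset.sequences:
        raise ValueError("empty training set")
    if wset.length < L:
        raise ValueError(f"sequences of length {wset.length} cannot hold a motif of {L}")
    X = _one_hot(wset.sequences)
    if X.sum() == 0:
        raise ValueError("degenerate training set: all positions are N")
    rng = np.random.default_rng(seed)
    best: tuple[float, str, np.ndarray] | None = None
    for _ in range(max(1, restarts)):
        p0 = rng.dirichlet(np.ones(4), size=L)
        p, ll, trace = _em_run(X, wset.weights, L, p0, max_iter=max_iter, tol=tol)
        diffs = np.diff(trace)
        assert (diffs >= -1e-6 * max(1.0, abs(trace[-1]))).all(), (
            "EM log-likelihood decreased"
        )
        cons = iupac_consensus(PositionWeightMatrix(p / p.sum(axis=1, keepdims=True)))
        key = (ll, cons)
        if best is None or ll > best[0] + 1e-9 or (abs(ll - best[0]) <= 1e-9 and cons < best[1]):
            best = (ll, cons, p)
    pwm = PositionWeightMatrix(
        probs=_smooth(best[2], pseudocount, len(wset)),
        pseudocount=pseudocount,
        orientation="+",
    )
    return _canonical_orientation(pwm)


def _smooth(probs: np.ndarray, pseudocount: float, n_sequences: int) -> np.ndarray:
    """Re-express ML probabilities as pseudocounted frequencies.

    Each training sequence counts as one observation per column regardless
    of its weight, so the smoothing — and hence the reported PWM — is
    invariant under rescaling all weights.
    """
    counts = probs * n_sequences + pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def _cc_before_gg(consensus: str) -> bool:
    i = consensus.find("CC")
    j = consensus.rfind("GG")
    return i != -1 and j != -1 and i < j


def _canonical_orientation(pwm: PositionWeightMatrix) -> PositionWeightMatrix:
    flipped = pwm.reverse_complement()
    c, cf = pwm.consensus(), flipped.consensus()
    ok, okf = _cc_before_gg(c), _cc_before_gg(cf)
    if ok and not okf:
        return pwm
    if okf and not ok:
        return flipped
    if ok and okf:
        return pwm if c <= cf else flipped
    return pwm


# ---------------------------------------------------------------------------
# Guided flank analysis
# ---------------------------------------------------------------------------


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile(
        "".join(
            "[" + "".join(sorted(IUPAC_SETS[c])) + "]" for c in pattern
        )
    )


def flank_extract_orient(
    pool: ReadPool,
    core: str = "CCWWWWWWGG",
    flank: int = 4,
    seed: int = 0,
    *,
    max_iter: int = 200,
) -> tuple[WeightedSequenceSet, PositionWeightMatrix]:
    """Extract N4-core-N4 windows from raw reads and strand-orient them.

    Every window of length ``flank + len(core) + flank`` whose centre matches
    the core pattern on either strand is extracted (minus-strand matches are
    reverse-complemented so the core reads in forward orientation).  Because
    the SRF-type core is closed under reverse complement, a two-fold
    orientation ambiguity remains; it is resolved by a two-component
    orientation-mixture EM over all columns, seeded randomly.  Returns the
    oriented set (unit weights) and its PWM.
    """
    width = flank + len(core) + flank
    if pool.read_length < width:
        raise ValueError(f"reads shorter than window length {width}")
    codes = pool.codes()
    win = np.lib.stride_tricks.sliding_window_view(codes, width, axis=1)
    no_n = ~(win == 4).any(axis=2)
    allowed = np.zeros((len(core), 5), dtype=bool)
    for j, c in enumerate(core):
        for b in IUPAC_SETS[c]:
            allowed[j, "ACGT".index(b)] = True
    centre = win[:, :, flank : flank + len(core)]
    fwd_hit = allowed[np.arange(len(core)), centre].all(axis=2) & no_n
    # minus-strand core match: revcomp(window) centre matches the pattern
    rc_centre = 3 - centre[:, :, ::-1]
    rc_hit = (
        allowed[np.arange(len(core)), np.clip(rc_centre, 0, 4)].all(axis=2) & no_n
    )
    windows: list[str] = []
    from .kmers import decode

    ii, oo = np.nonzero(fwd_hit | rc_hit)
    for i, o in zip(ii, oo):
        s = decode(win[i, o][None, :])[0]
        windows.append(s if fwd_hit[i, o] else revcomp(s))
    if not windows:
        raise ValueError("no window matches the core pattern")

    X = _one_hot(windows)
    n, Lw, _ = X.shape
    Xr = X[:, ::-1, ::-1]  # reverse complement representation
    rng = np.random.default_rng(seed)
    base = X.mean(axis=0)
    theta = base + rng.uniform(0, 0.05, size=base.shape)
    theta = theta / theta.sum(axis=1, keepdims=True)
    post = None
    for _ in range(max_iter):
        logt = np.log(np.clip(theta, 1e-12, None))
        lf = np.einsum("nlb,lb->n", X, logt)
        lr = np.einsum("nlb,lb->n", Xr, logt)
        m = np.maximum(lf, lr)
        pf = np.exp(lf - m)
        pr = np.exp(lr - m)
        post = pf / (pf + pr)
        counts = (
            np.einsum("n,nlb->lb", post, X) + np.einsum("n,nlb->lb", 1 - post, Xr)
        ) + 0.5
        new_theta = counts / counts.sum(axis=1, keepdims=True)
        if np.abs(new_theta - theta).max() < 1e-9:
            theta = new_theta
            break
        theta = new_theta
    oriented = [
        windows[i] if post[i] >= 0.5 else revcomp(windows[i]) for i in range(n)
    ]
    wset = WeightedSequenceSet(sequences=oriented, weights=np.ones(n))
    counts = _one_hot(oriented).sum(axis=0) + 0.5
    pwm = PositionWeightMatrix(
        probs=counts / counts.sum(axis=1, keepdims=True), pseudocount=0.5
    )
    # deterministic global flip: lexicographically smaller consensus wins
    flipped = pwm.reverse_complement()
    if flipped.consensus() < pwm.consensus():
        pwm = flipped
        wset = WeightedSequenceSet(
            sequences=[revcomp(s) for s in oriented], weights=np.ones(n)
        )
    return wset, pwm


# ---------------------------------------------------------------------------
# Position-bias diagnostics
# ---------------------------------------------------------------------------

INCOMPLETE_PATTERN = "WWNNNNNNWW"


def classify_kmer(kmer: str, incomplete_pattern: str = INCOMPLETE_PATTERN) -> str:
    """complete (SRF-type CArG-box), incomplete (W2 N6 W2 on either strand), other."""
    if is_srf_cargbox(kmer):
        return "complete"
    rx = _iupac_regex(incomplete_pattern)
    if rx.fullmatch(kmer) or rx.fullmatch(revcomp(kmer)):
        return "incomplete"
    return "other"


def position_bias(
    pool: ReadPool,
    kmer_list: list[str],
    incomplete_pattern: str = INCOMPLETE_PATTERN,
) -> dict[str, tuple[np.ndarray, str]]:
    """Forward-strand match offsets (1-based) and class label per k-mer."""
    from .kmers import encode, pack, window_codes

    out: dict[str, tuple[np.ndarray, str]] = {}
    L = pool.read_length
    by_k: dict[int, np.ndarray] = {}
    for kmer in kmer_list:
        k = len(kmer)
        if k > L:
            raise ValueError(f"k-mer {kmer!r} longer than reads")
        if k not in by_k:
            fwd, _, valid = window_codes(pool.codes(), k)
            by_k[k] = np.where(valid, fwd, -1)
        code = int(pack(encode([kmer]))[0])
        hist = (by_k[k] == code).sum(axis=0)
        out[kmer] = (hist.astype(int), classify_kmer(kmer, incomplete_pattern))
    return out


def position_bias_table(result: dict[str, tuple[np.ndarray, str]]) -> list[dict]:
    rows = []
    for kmer, (hist, label) in sorted(result.items()):
        for o, c in enumerate(hist, start=1):
            rows.append({"kmer": kmer, "class": label, "offset": o, "count": int(c)})
    return rows
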