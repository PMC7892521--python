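"""Intra-motif dependence models and the intra-motif complexity (IMC) measure.

A PWM treats motif positions as independent.  Dependence models relax this:
each position may be conditioned on positions strictly preceding it (an
acyclic left-to-right factorisation, so the joint is always a proper
distribution).  *Proximal* models fix the parents to the d immediately
preceding positions; *distal* models learn, per position, the best parent
subset of size <= d among all predecessors by exhaustive search under a
BIC-penalised weighted log-likelihood.  Optionally, context symbols can be
merged by choosing, per conditioning level, the set-partition of {A,C,G,T}
that maximises BIC (a parsimonious context tree).

IMC is the mean per-sequence log-likelihood gain over the mononucleotide
(PWM) model, in bits, weighted by the sequence weights.  It is 0 for the PWM
itself by definition and, for unpenalised maximum-likelihood fits, is
non-negative and non-decreasing in model flexibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .discovery import WeightedSequenceSet
from .kmers import encode
from .probes import write_tsv

# the 15 set-partitions of {A,C,G,T}, as tuples of blocks (base indices)
def _set_partitions(items: tuple[int, ...]) -> list[list[tuple[int, ...]]]:
    if len(items) == 1:
        return [[items]]
    first, rest = items[0], items[1:]
    out = []
    for part in _set_partitions(rest):
        for i in range(len(part)):
            out.append(part[:i] + [(first,) + part[i]] + part[i + 1 :])
        out.append([(first,)] + part)
    return out


PARTITIONS_4 = _set_partitions((0, 1, 2, 3))  # 15 partitions (Bell number B4)


@dataclass
class DependenceModel:
    """Per-position parent sets and conditional distributions."""

    model_type: str  # "proximal" | "distal"
    order: int
    parents: list[tuple[int, ...]]  # parents[j] strictly precede j
    conditionals: list[np.ndarray]  # shape (4^|parents[j]|, 4) each
    context_maps: list[np.ndarray] | None  # context code -> merged bucket, or None
    log_likelihood: float
    effective_n: float
    pseudocount: float

    file_suffix = ".dependence.txt"
    export_name = "dependence"

    def __post_init__(self) -> None:
        for j, par in enumerate(self.parents):
            if any(p >= j or p < 0 for p in par):
                raise ValueError(f"parents of position {j} must strictly precede it")
        for tab in self.conditionals:
            if not np.allclose(tab.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("conditional distributions must sum to 1")

    @property
    def length(self) -> int:
        return len(self.parents)

    def sequence_log2_probs(self, codes: np.ndarray) -> np.ndarray:
        """log2 P(sequence) for each row of an (n, L) code matrix."""
        codes = np.asarray(codes, dtype=np.int64)
        n, L = codes.shape
        if L != self.length:
            raise ValueError(f"model has length {self.length}, data {L}")
        out = np.zeros(n)
        for j in range(L):
            ctx = _context_codes(codes, self.parents[j])
            if self.context_maps is not None and self.context_maps[j] is not None:
                ctx = self.context_maps[j][ctx]
            out += np.log2(self.conditionals[j][ctx, codes[:, j]])
        return out

    def save(self, path) -> None:
        with open(path, "w") as out:
            out.write("# selexkit dependence model\n")
            out.write(f"model_type\t{self.model_type}\norder\t{self.order}\n")
            out.write(f"log_likelihood\t{self.log_likelihood!r}\n")
            out.write(f"effective_n\t{self.effective_n!r}\n")
            for j in range(self.length):
                par = ",".join(map(str, self.parents[j])) or "-"
                out.write(f"[position {j}] parents={par}\n")
                for c, row in enumerate(self.conditionals[j]):
                    out.write(
                        f"{c}\t" + "\t".join(repr(float(x)) for x in row) + "\n"
                    )


def _context_codes(codes: np.ndarray, parents: tuple[int, ...]) -> np.ndarray:
    """Pack the parent columns into a base-4 context code per sequence."""
    n = codes.shape[0]
    ctx = np.zeros(n, dtype=np.int64)
    for p in parents:
        ctx = ctx * 4 + codes[:, p]
    return ctx


def _weighted_table(
    ctx: np.ndarray, x: np.ndarray, w: np.ndarray, n_ctx: int
) -> np.ndarray:
    """(n_ctx, 4) weighted joint counts."""
    flat = ctx * 4 + x
    return np.bincount(flat, weights=w, minlength=n_ctx * 4).reshape(n_ctx, 4)


def _cond_loglik(table: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Smoothed conditionals and the weighted log-likelihood of the data
    under them (natural log)."""
    smoothed = table + alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = smoothed / smoothed.sum(axis=1, keepdims=True)
    if alpha == 0:
        # ML plug-in: empty contexts get a uniform row (never hit by data)
        rowsum = table.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(rowsum > 0, table / np.where(rowsum == 0, 1, rowsum), 0.25)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    ll = float(np.where(table > 0, table * logp, 0.0).sum())
    return probs, ll


def _merge_contexts_bic(
    table: np.ndarray, alpha: float, penalty_scale: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy per-level context-tree merge via the 15 partitions of {A,C,G,T}.

    Works on the flattened context table by treating the most recent parent
    symbol as the partition level (single-level merge; applied only when
    requested).  Returns (context map, merged conditionals, loglik).
    """
    n_ctx = table.shape[0]
    if n_ctx == 1:
        probs, ll = _cond_loglik(table, alpha)
        return np.zeros(1, dtype=np.int64), probs, ll
    # group contexts by all-but-last-symbol; partition the last symbol
    n_hi = n_ctx // 4
    best_map = None
    best_score = -np.inf
    best_tabs = None
    for part in PARTITIONS_4:
        cmap = np.empty(n_ctx, dtype=np.int64)
        merged_rows = []
        bucket = 0
        for hi in range(n_hi):
            for block in part:
                rows = [hi * 4 + b for b in block]
                merged_rows.append(table[rows].sum(axis=0))
                for rix in rows:
                    cmap[rix] = bucket
                bucket += 1
        merged = np.vstack(merged_rows)
        _, ll = _cond_loglik(merged, alpha)
        n_params = 3 * merged.shape[0]
        score = ll - penalty_scale * n_params
        if score > best_score:
            best_score, best_map = score, cmap
            best_tabs = merged
    probs, ll = _cond_loglik(best_tabs, alpha)
    return best_map, probs, ll


def fit_dependence(
    wset: WeightedSequenceSet,
    model_type: str = "distal",
    d: int = 1,
    penalty: str | None = "BIC",
    *,
    pseudocount: float = 0.5,
    merge_contexts: bool = False,
) -> DependenceModel:
    """Fit a proximal or distal dependence model of order ``d``.

    Proximal parents are exactly the d adjacent predecessors (truncated at
    the left edge).  Distal parents are found by exhaustive subset search
    (size <= d) maximising ``logL - (free params / 2) * ln(N_eff)`` when
    ``penalty="BIC"``, or the raw weighted log-likelihood when ``penalty``
    is None (in which case larger parent sets always win — useful for
    nestedness checks).  N_eff is Kish's effective sample size of the
    weights.  Sequences containing N are dropped with a warning.
    """
    if model_type not in ("proximal", "distal"):
        raise ValueError("model_type must be 'proximal' or 'distal'")
    if d < 0:
        raise ValueError("order must be >= 0")
    seqs, w = wset.sequences, wset.weights
    keep = [i for i, s in enumerate(seqs) if "N" not in s]
    if len(keep) < len(seqs):
        warnings.warn(
            f"dropping {len(seqs) - len(keep)} sequences containing N", stacklevel=2
        )
        seqs = [seqs[i] for i in keep]
        w = w[keep]
    if not seqs:
        raise ValueError("no usable sequences")
    codes = encode(seqs)
    n, L = codes.shape
    if L < 2:
        raise ValueError("dependence models need length >= 2")
    n_eff = float(w.sum()) ** 2 / float((w**2).sum())
    penalty_scale = 0.5 * np.log(n_eff) if penalty == "BIC" else 0.0
    # rescale weights so the log-likelihood is on the N_eff scale: BIC then
    # compares like-for-like between structures
    w_scaled = w * (n_eff / w.sum())

    parents: list[tuple[int, ...]] = []
    conditionals: list[np.ndarray] = []
    context_maps: list[np.ndarray] | None = [] if merge_contexts else None
    total_ll = 0.0
    for j in range(L):
        if model_type == "proximal":
            candidates = [tuple(range(max(0, j - d), j))]
        else:
            preds = range(j)
            candidates = [()]
            for size in range(1, d + 1):
                candidates += [c for c in combinations(preds, size)]
        best = None
        for par in candidates:
            n_ctx = 4 ** len(par)
            table = _weighted_table(
                _context_codes(codes, par), codes[:, j], w_scaled, n_ctx
            )
            if merge_contexts and len(par) > 0:
                cmap, probs, ll = _merge_contexts_bic(table, pseudocount, penalty_scale)
                n_params = 3 * probs.shape[0]
            else:
                cmap = None
                probs, ll = _cond_loglik(table, pseudocount)
                n_params = 3 * n_ctx
            score = ll - penalty_scale * n_params
            key = (score, -len(par), tuple(sorted(par)))
            if best is None or key > best[0]:
                best = (key, par, probs, ll, cmap)
        _, par, probs, ll, cmap = best
        parents.append(par)
        conditionals.append(probs)
        if context_maps is not None:
            context_maps.append(cmap)
        total_ll += ll
    return DependenceModel(
        model_type=model_type,
        order=d,
        parents=parents,
        conditionals=conditionals,
        context_maps=context_maps,
        log_likelihood=total_ll,
        effective_n=n_eff,
        pseudocount=pseudocount,
    )


def fit_pwm_baseline(
    wset: WeightedSequenceSet, *, pseudocount: float = 0.5
) -> DependenceModel:
    """Mononucleotide (order-0) baseline: the PWM as a dependence model."""
    return fit_dependence(
        wset, "proximal", d=0, penalty=None, pseudocount=pseudocount
    )


def imc(model: DependenceModel, wset: WeightedSequenceSet) -> float:
    """Intra-motif complexity in bits.

    Mean weighted per-sequence log2-likelihood gain of ``model`` over the
    mononucleotide PWM fitted (with the same pseudocount) on the same data.
    Exactly 0 when the model *is* the PWM.
    """
    seqs = [s for s in wset.sequences if "N" not in s]
    w = wset.weights[[i for i, s in enumerate(wset.sequences) if "N" not in s]]
    codes = encode(seqs)
    if codes.shape[1] != model.length:
        raise ValueError("model and sequence lengths differ")
    baseline = fit_pwm_baseline(
        WeightedSequenceSet(sequences=seqs, weights=w), pseudocount=model.pseudocount
    )
    gain = model.sequence_log2_probs(codes) - baseline.sequence_log2_probs(codes)
    return float((w * gain).sum() / w.sum())


def imc_table(wset: WeightedSequenceSet, *, penalty: str | None = "BIC",
              pseudocount: float = 0.5, merge_contexts: bool = False) -> list[dict]:
    """The proximal/distal x order 1/2 IMC report (4 rows)."""
    rows = []
    for model_type in ("proximal", "distal"):
        for order in (1, 2):
            model = fit_dependence(
                wset, model_type, order, penalty,
                pseudocount=pseudocount, merge_contexts=merge_contexts,
            )
            rows.append(
                {
                    "model": model_type,
                    "order": order,
                    "imc_bits": imc(model, wset),
                }
            )
    return rows


def save_imc_table(rows: list[dict], path) -> None:
    write_tsv(rows, path, ["model", "order", "imc_bits"])
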