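"""Motif comparison: per-position Jensen-Shannon divergence and difference logos.

JSD between two probability columns p and q (log base 2) is
H((p+q)/2) - (H(p)+H(q))/2, bounded in [0, 1] bits, symmetric, and zero iff
the columns agree.  Aggregated over positions (sum by default) it quantifies
how far apart two binding motifs are: replicate motifs of the same protein
score near zero while motifs of proteins with altered specificity score high.

Because discovery strand is arbitrary, the comparison also evaluates the
second motif reverse-complemented and keeps the orientation with the smaller
aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discovery import PositionWeightMatrix
from .probes import write_tsv

BASES = "ACGT"


def _entropy2(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits along the last axis; 0*log(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p), 0.0)
    return -t.sum(axis=-1)


def jsd_columns(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-position JSD in bits for two (L, 4) column-stochastic matrices."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    return _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))


def pwm_jsd(
    p: PositionWeightMatrix,
    q: PositionWeightMatrix,
    aggregate: str = "sum",
    try_revcomp: bool = True,
) -> tuple[float, np.ndarray, str]:
    """Aggregate JSD between two PWMs of equal length.

    Returns (aggregate value, per-position vector, orientation used), where
    orientation is "+" when q was compared as given and "-" when its reverse
    complement gave the smaller aggregate.
    """
    if len(p) != len(q):
        raise ValueError(f"PWM lengths differ: {len(p)} vs {len(q)}")
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")

    def agg(v: np.ndarray) -> float:
        return float(v.sum() if aggregate == "sum" else v.mean())

    v_fwd = jsd_columns(p.probs, q.probs)
    best = (agg(v_fwd), v_fwd, "+")
    if try_revcomp:
        qr = q.reverse_complement()
        v_rev = jsd_columns(p.probs, qr.probs)
        if agg(v_rev) < best[0]:
            best = (agg(v_rev), v_rev, "-")
    return best


@dataclass
class DifferenceLogo:
    """Numeric difference logo between two motifs.

    Stack height at a position is the JSD of the two columns; each letter
    gets a signed share proportional to its probability difference (positive
    = enriched in the first motif).  Signed letter heights sum to 0 per
    position.
    """

    per_position: np.ndarray  # (L,) JSD in bits
    letter_heights: np.ndarray  # (L, 4), signed
    aggregate: float
    aggregate_mode: str

    file_suffix = ".difflogo.tsv"
    export_name = "difference_logo"

    def save(self, path) -> None:
        rows = []
        for j in range(len(self.per_position)):
            for b, base in enumerate(BASES):
                rows.append(
                    {
                        "position": j + 1,
                        "base": base,
                        "signed_height": float(self.letter_heights[j, b]),
                        "position_jsd_bits": float(self.per_position[j]),
                    }
                )
        write_tsv(
            rows, path, ["position", "base", "signed_height", "position_jsd_bits"]
        )


def difference_logo(
    p: PositionWeightMatrix,
    q: PositionWeightMatrix,
    aggregate: str = "sum",
) -> DifferenceLogo:
    """Difference logo of p vs q (orientation must already be resolved)."""
    if len(p) != len(q):
        raise ValueError("PWM lengths differ")
    jsd = jsd_columns(p.probs, q.probs)
    diff = p.probs - q.probs
    denom = np.abs(diff).sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(denom > 0, diff / denom, 0.0)
    heights = jsd[:, None] * share
    agg = float(jsd.sum() if aggregate == "sum" else jsd.mean())
    return DifferenceLogo(
        per_position=jsd,
        letter_heights=heights,
        aggregate=agg,
        aggregate_mode=aggregate,
    )


def pairwise_jsd_matrix(
    pwms: dict[str, PositionWeightMatrix],
    aggregate: str = "sum",
    try_revcomp: bool = True,
) -> list[dict]:
    """Upper-triangular pairwise divergence table for a set of named motifs."""
    names = list(pwms)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            value, _, orientation = pwm_jsd(
                pwms[a], pwms[b], aggregate=aggregate, try_revcomp=try_revcomp
            )
            rows.append(
                {"motif_a": a, "motif_b": b, "jsd": value, "orientation": orientation}
            )
    return rows
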