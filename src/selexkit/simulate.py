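"""Synthetic SELEX-seq generator with a planted CArG-box binding model.

Selection is modelled as weighted resampling: every probe gets an occupancy
weight ``eps + sum over 10-nt windows on both strands of exp(beta * score)``,
where the score of a window is the negative positional binding energy plus
flank bonuses plus an A-tract shape-readout bonus when the central 6 bp form
an A-tract (A^n T^m, n+m >= 4).  The Boltzmann *sum* over windows (rather
than a max) keeps the target of the (obs/exp)^(1/r) affinity estimator
analytically predictable.  Scanning covers the tail of the 5' adapter and the
head of the barcode/3' adapter, so the constant ``CT`` adapter terminus can
act as the 5' border of a near-complete binding site — the mechanism behind
the position-bias artifact seen in real libraries.

The inverse temperature ``beta`` scales the whole score, so ``beta = 0`` is
exactly selection-free whatever the preset: a convenient null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background import MarkovBackground
from .cargbox import has_a_tract
from .kmers import decode, encode, pack
from .probes import ProbeDesign, ReadPool

MOTIF_WIDTH = 10

#: fixed positive-control variable region (carries the CArG-box CCTTTTAAGG);
#: used as the carry-over contaminant
CONTROL_VARIABLE_REGION = "GATCGTCCTTTTAAGGACGATCGTG"

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class BindingModel:
    """Planted dimer binding model over 10-nt windows.

    core_energy: (10, 4) positional energies (columns A,C,G,T; lower = tighter).
    flank_bonus: {(offset, base): bonus} with offset -1, -2, ... upstream of the
        window start and +1, +2, ... downstream of the window end, read on the
        binding strand.
    atract_bonus: score bonus when the window's central 6 bp contain an A-tract
        (strand-symmetric by construction); emulates minor-groove shape readout
        that a purely positional energy matrix cannot express.
    beta: inverse-temperature scaling of the whole score.
    nonspecific: strictly positive baseline weight eps.
    """

    core_energy: np.ndarray
    flank_bonus: dict[tuple[int, str], float] = field(default_factory=dict)
    beta: float = 1.0
    nonspecific: float = 1.0
    atract_bonus: float = 0.0

    def __post_init__(self) -> None:
        E = np.asarray(self.core_energy, dtype=float)
        if E.shape != (MOTIF_WIDTH, 4):
            raise ValueError(f"core_energy must be {MOTIF_WIDTH}x4, got {E.shape}")
        object.__setattr__(self, "core_energy", E)
        if self.nonspecific <= 0:
            raise ValueError("nonspecific weight eps must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def _energies(rows: dict[int, dict[str, float]], default: float = 4.0) -> np.ndarray:
    E = np.full((MOTIF_WIDTH, 4), default)
    for pos, prefs in rows.items():
        for base, e in prefs.items():
            E[pos, _BASE_INDEX[base]] = e
    return E


def wildtype_model(beta: float = 1.4) -> BindingModel:
    """WT-like preset: consensus CCAAAAATGG with a W-tolerant centre.

    Matched positions carry a recognition bonus (energy -0.2 per position),
    hard outer borders, a graded A/T centre, an A-tract shape-readout bonus,
    weak TTN-/-NAA flank preferences, and a mild tolerance for T at position
    2 (and its mirror A at position 9) so the adapter's CT terminus can
    substitute for the CC border — the source of the position-bias artifact
    and of "CArG-box-like" high-affinity sequences.
    """
    g = -0.19  # per-position recognition bonus at the consensus base
    E = _energies(
        {
            0: {"C": g, "A": 1.8, "G": 1.8, "T": 1.8},
            1: {"C": g, "T": 0.25, "A": 1.8, "G": 1.8},
            2: {"A": g, "T": g + 0.24, "C": 1.4, "G": 1.4},
            3: {"A": g, "T": g + 0.24, "C": 1.4, "G": 1.4},
            4: {"A": g, "T": g + 0.24, "C": 1.4, "G": 1.4},
            5: {"A": g, "T": g + 0.24, "C": 1.4, "G": 1.4},
            6: {"A": g, "T": g + 0.24, "C": 1.4, "G": 1.4},
            7: {"T": g, "A": g + 0.24, "C": 1.4, "G": 1.4},
            8: {"G": g, "A": 0.25, "C": 1.8, "T": 1.8},
            9: {"G": g, "A": 1.8, "C": 1.8, "T": 1.8},
        },
        default=1.6,
    )
    flanks = {
        (-2, "T"): 0.15,
        (-1, "T"): 0.15,
        (1, "A"): 0.15,
        (2, "A"): 0.15,
    }
    return BindingModel(
        core_energy=E,
        flank_bonus=flanks,
        beta=beta,
        nonspecific=1.0,
        atract_bonus=0.55,
    )


def mutant_model(beta: float = 1.4) -> BindingModel:
    """Mutant-like preset: shorter A-rich core with S (C/G) tolerated at the
    centre borders — consensus CCSAAAASGG — and no A-tract shape readout."""
    g = -0.19
    E = _energies(
        {
            0: {"C": g, "A": 1.8, "G": 1.8, "T": 1.8},
            1: {"C": g, "T": 0.25, "A": 1.8, "G": 1.8},
            2: {"C": g, "G": g, "A": g + 0.25, "T": g + 0.6},
            3: {"A": g, "T": g + 0.3, "C": 1.4, "G": 1.4},
            4: {"A": g, "T": g + 0.3, "C": 1.4, "G": 1.4},
            5: {"A": g, "T": g + 0.3, "C": 1.4, "G": 1.4},
            6: {"A": g, "T": g + 0.3, "C": 1.4, "G": 1.4},
            7: {"C": g, "G": g, "A": g + 0.25, "T": g + 0.6},
            8: {"G": g, "A": 0.25, "C": 1.8, "T": 1.8},
            9: {"G": g, "A": 1.8, "C": 1.8, "T": 1.8},
        },
        default=1.6,
    )
    flanks = {
        (-2, "T"): 0.15,
        (-1, "T"): 0.15,
        (1, "A"): 0.15,
        (2, "A"): 0.15,
    }
    return BindingModel(
        core_energy=E,
        flank_bonus=flanks,
        beta=beta,
        nonspecific=1.0,
        atract_bonus=0.0,
    )


PRESETS = {"wildtype": wildtype_model, "mutant": mutant_model}


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions for one library."""

    n_reads: int
    n_rounds: int = 2
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    background: MarkovBackground | None = None
    pcr_bias_gamma: float = 0.0
    contamination_fraction: float = 0.0
    contaminant: str = CONTROL_VARIABLE_REGION
    seed: int = 0
    #: candidate-pool oversampling cap for the deep-library sampling mode:
    #: round r draws n_reads from up to library_oversample * n_reads fresh
    #: candidate molecules, emulating a synthesis library whose complexity
    #: vastly exceeds sequencing depth
    library_oversample: int = 200

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")


def simulate_r0(
    config: SimConfig,
    design: ProbeDesign,
    *,
    label: str = "sim",
    rng: np.random.Generator | None = None,
) -> ReadPool:
    """Draw an unselected library: i.i.d. base composition or a Markov chain."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    codes = _r0_codes(config, design, config.n_reads, rng)
    return ReadPool(round_index=0, library_label=label, sequences=decode(codes))


def _r0_codes(
    config: SimConfig, design: ProbeDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    L = design.variable_length
    bg = config.background
    if bg is None:
        comp = np.asarray(config.base_composition)
        if np.allclose(comp, 0.25):
            codes = rng.integers(0, 4, size=(n, L), dtype=np.int8)
        else:
            codes = rng.choice(4, size=(n, L), p=comp).astype(np.int8)
    else:
        m = bg.order
        codes = np.empty((n, L), dtype=np.int64)
        if m == 0:
            for j in range(L):
                codes[:, j] = rng.choice(4, size=n, p=bg.conditionals[0])
        else:
            first = rng.choice(4**m, size=n, p=bg.initial)
            for j in range(m):
                codes[:, j] = (first // 4 ** (m - 1 - j)) % 4
            ctx = first.copy()
            u_all = rng.random((n, L - m))
            cum = np.cumsum(bg.conditionals, axis=1)
            for j in range(m, L):
                u = u_all[:, j - m, None]
                codes[:, j] = (u >= cum[ctx]).sum(axis=1)
                ctx = (ctx * 4 + codes[:, j]) % 4**m
        codes = codes.astype(np.int8)
    return codes


# ---------------------------------------------------------------------------
# Occupancy weights
# ---------------------------------------------------------------------------


def _atract_table() -> np.ndarray:
    """tract indicator over all 4^6 centre codes (cached)."""
    global _ATRACT_TABLE
    try:
        return _ATRACT_TABLE
    except NameError:
        pass
    tab = np.zeros(4**6, dtype=bool)
    from .kmers import unpack

    centers = decode(unpack(np.arange(4**6), 6))
    for code, s in enumerate(centers):
        tab[code] = has_a_tract(s)[0]
    _ATRACT_TABLE = tab
    return tab


def _strand_profiles(model: BindingModel):
    """Per-strand (core profile, flank terms) in forward coordinates.

    Core profiles are (10, 5) score tables (-energy; column 4 = N, scored
    -inf so windows overlapping N drop out).  Flank terms are
    (rho, base_code, bonus) with rho the offset from the window start.
    """
    E = model.core_energy
    neg_inf = np.full((MOTIF_WIDTH, 1), -np.inf)
    plus = np.hstack([-E, neg_inf])
    minus_core = np.empty_like(E)
    for j in range(MOTIF_WIDTH):
        for b in range(4):
            minus_core[j, b] = E[MOTIF_WIDTH - 1 - j, 3 - b]
    minus = np.hstack([-minus_core, neg_inf])

    plus_flanks, minus_flanks = [], []
    for (delta, base), bonus in model.flank_bonus.items():
        if delta == 0:
            raise ValueError("flank offset 0 is inside the window")
        b = _BASE_INDEX[base]
        if delta < 0:
            plus_flanks.append((delta, b, bonus))
            minus_flanks.append((MOTIF_WIDTH - 1 - delta, 3 - b, bonus))
        else:
            plus_flanks.append((MOTIF_WIDTH - 1 + delta, b, bonus))
            minus_flanks.append((-delta, 3 - b, bonus))
    return (plus, plus_flanks), (minus, minus_flanks)


def sequence_weights(model: BindingModel, codes: np.ndarray) -> np.ndarray:
    """Occupancy weight of each row of an (n, L) code matrix.

    eps + Boltzmann sum over all full 10-nt windows on both strands; windows
    overlapping an N contribute nothing.
    """
    codes = np.asarray(codes)
    n, L = codes.shape
    n_win = L - MOTIF_WIDTH + 1
    if n_win <= 0:
        return np.full(n, model.nonspecific)
    codes64 = codes.astype(np.intp)
    tract = None
    if model.atract_bonus:
        win6 = np.lib.stride_tricks.sliding_window_view(codes, 6, axis=1)
        centers = win6[:, 2 : 2 + n_win, :]
        ok = ~(centers == 4).any(axis=2)
        packed = pack(np.where(centers == 4, 0, centers).reshape(-1, 6)).reshape(n, n_win)
        tract = (_atract_table()[packed] & ok).astype(np.float32)

    # -1e4 at N keeps exp() at exactly 0 without inf arithmetic
    total = np.zeros(n)
    for core, flanks in _strand_profiles(model):
        prof = np.where(np.isneginf(core), -1e4, core).astype(np.float32)
        S = np.zeros((n, n_win), dtype=np.float32)
        for j in range(MOTIF_WIDTH):
            S += prof[j][codes64[:, j : j + n_win]]
        for rho, b, bonus in flanks:
            lo = max(0, -rho)
            hi = min(n_win, L - rho)
            if lo < hi:
                S[:, lo:hi] += np.float32(bonus) * (
                    codes[:, lo + rho : hi + rho] == b
                )
        if tract is not None:
            S += np.float32(model.atract_bonus) * tract
        with np.errstate(over="ignore", under="ignore"):
            total += np.exp(np.float64(model.beta) * S, dtype=np.float64).sum(axis=1)
    return model.nonspecific + total


def scan_context(design: ProbeDesign, variable: str, barcode: str = "") -> str:
    """Adapter tail + variable region + barcode/adapter head used for scanning."""
    tail = design.adapter5[-(MOTIF_WIDTH - 1) :]
    head = (barcode + design.adapter3)[: MOTIF_WIDTH - 1]
    return tail + variable + head


def probe_weight(
    model: BindingModel, variable: str, design: ProbeDesign, barcode: str = ""
) -> float:
    """Occupancy weight of one probe in its adapter context."""
    if len(variable) != design.variable_length:
        raise ValueError("variable region length does not match design")
    ctx = scan_context(design, variable, barcode)
    return float(sequence_weights(model, encode([ctx]))[0])


def pool_weights(
    model: BindingModel, pool: ReadPool, design: ProbeDesign, barcode: str = ""
) -> np.ndarray:
    """Vectorised probe weights for a whole pool (shared adapter context)."""
    tail = encode([design.adapter5[-(MOTIF_WIDTH - 1) :]])
    head = encode([(barcode + design.adapter3)[: MOTIF_WIDTH - 1]])
    codes = pool.codes()
    n = codes.shape[0]
    ctx = np.hstack(
        [np.repeat(tail, n, axis=0), codes, np.repeat(head, n, axis=0)]
    )
    return sequence_weights(model, ctx)


def run_rounds(
    model: BindingModel,
    r0: ReadPool,
    config: SimConfig,
    design: ProbeDesign | None = None,
    barcode: str = "",
) -> list[ReadPool]:
    """Simulate selection rounds 1..n_rounds by weighted resampling.

    Sampling probability is probe weight times an optional smooth PCR factor
    exp(gamma * (GC - 0.5)); the positive-control contaminant is spiked in
    after selection at the configured fraction (carry-over).
    """
    if not r0.sequences:
        raise ValueError("r0 pool is empty")
    design = design if design is not None else ProbeDesign()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pools: list[ReadPool] = []
    current = r0
    for r in range(1, config.n_rounds + 1):
        w = pool_weights(model, current, design, barcode)
        if config.pcr_bias_gamma:
            codes = current.codes()
            gc = ((codes == 1) | (codes == 2)).mean(axis=1)
            w = w * np.exp(config.pcr_bias_gamma * (gc - 0.5))
        p = w / w.sum()
        idx = rng.choice(len(current), size=config.n_reads, replace=True, p=p)
        seqs = [current.sequences[i] for i in idx]
        if config.contamination_fraction > 0:
            n_cont = rng.binomial(config.n_reads, config.contamination_fraction)
            if n_cont:
                where = rng.choice(config.n_reads, size=n_cont, replace=False)
                cont = config.contaminant[: design.variable_length]
                for i in where:
                    seqs[i] = cont
        current = ReadPool(round_index=r, library_label=r0.library_label, sequences=seqs)
        pools.append(current)
    return pools


def _candidate_codes(
    config: SimConfig, design: ProbeDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Fresh molecules from the R0 generative distribution, as codes."""
    return _r0_codes(config, design, n, rng)


def sample_round(
    model: BindingModel,
    config: SimConfig,
    design: ProbeDesign,
    r: int,
    *,
    rng: np.random.Generator,
    label: str = "sim",
    barcode: str = "",
    chunk: int = 250_000,
) -> ReadPool:
    """Draw round-r reads from the selection-tilted library distribution.

    The physical synthesis library is far more complex than any sequencing
    sample, so the sequenced reads of round r are modelled as draws from
    q0(s) * weight(s)^r (times the PCR factor per round) rather than as a
    resample of the previously *sequenced* molecules.  Implemented by
    importance resampling from ``library_oversample * n_reads`` fresh
    candidates; the finite-pool alternative is :func:`run_rounds`.
    """
    if r < 1:
        raise ValueError("selection rounds start at 1")
    # later rounds tilt by weight^r, concentrating mass on a smaller carrier
    # set; oversample more aggressively there to keep per-molecule sequencing
    # multiplicity realistic
    oversample = min(config.library_oversample, 50 * 4 ** (r - 1))
    M = oversample * config.n_reads
    tail = encode([design.adapter5[-(MOTIF_WIDTH - 1) :]])
    head = encode([(barcode + design.adapter3)[: MOTIF_WIDTH - 1]])
    # two passes over an identical candidate stream: weights first, then the
    # sampled molecules are regenerated -- avoids holding M candidate codes
    stream_seed = int(rng.integers(2**31))
    logw = np.empty(M)
    gen = np.random.default_rng(stream_seed)
    for start in range(0, M, chunk):
        stop = min(M, start + chunk)
        c = _candidate_codes(config, design, stop - start, gen)
        ctx = np.hstack(
            [
                np.repeat(tail, stop - start, axis=0),
                c,
                np.repeat(head, stop - start, axis=0),
            ]
        )
        w = sequence_weights(model, ctx)
        if config.pcr_bias_gamma:
            gc = ((c == 1) | (c == 2)).mean(axis=1)
            w = w * np.exp(config.pcr_bias_gamma * (gc - 0.5))
        logw[start:stop] = r * np.log(w)
    logw -= logw.max()
    p = np.exp(logw)
    p /= p.sum()
    idx = np.sort(rng.choice(M, size=config.n_reads, replace=True, p=p))
    out = np.empty((config.n_reads, design.variable_length), dtype=np.int8)
    gen = np.random.default_rng(stream_seed)
    pos = 0
    for start in range(0, M, chunk):
        stop = min(M, start + chunk)
        c = _candidate_codes(config, design, stop - start, gen)
        sel = idx[(idx >= start) & (idx < stop)] - start
        out[pos : pos + len(sel)] = c[sel]
        pos += len(sel)
    order = rng.permutation(config.n_reads)
    seqs = decode(out[order])
    if config.contamination_fraction > 0:
        n_cont = rng.binomial(config.n_reads, config.contamination_fraction)
        if n_cont:
            where = rng.choice(config.n_reads, size=n_cont, replace=False)
            cont = config.contaminant[: design.variable_length]
            for i in where:
                seqs[i] = cont
    return ReadPool(round_index=r, library_label=label, sequences=seqs)


def simulate_experiment(
    config: SimConfig,
    design: ProbeDesign | None = None,
    model: BindingModel | None = None,
    *,
    label: str = "sim",
    barcode: str = "",
    finite_pool: bool = False,
) -> list[ReadPool]:
    """Convenience wrapper: R0 plus all selection rounds, fully seeded.

    By default rounds are sampled in the deep-library regime
    (:func:`sample_round`); ``finite_pool=True`` switches to resampling the
    sequenced R0 molecules themselves (:func:`run_rounds`), which at desk
    scale introduces molecular-duplication artifacts real libraries do not
    show.
    """
    design = design if design is not None else ProbeDesign()
    model = model if model is not None else wildtype_model()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    r0 = simulate_r0(config, design, label=label, rng=rng)
    if finite_pool:
        return [r0] + run_rounds(model, r0, config, design, barcode)
    pools = [r0]
    for r in range(1, config.n_rounds + 1):
        pools.append(
            sample_round(
                model, config, design, r, rng=rng, label=label, barcode=barcode
            )
        )
    return pools
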