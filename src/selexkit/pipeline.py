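"""End-to-end orchestration: simulated or file-based runs to a report bundle.

A run covers one or more libraries (protein x replicate).  For each library
the pipeline executes: load/simulate reads -> contamination QC -> background
order selection -> motif-length selection -> relative affinities (R1, R2 and
the LOESS combination) -> affinity-weighted motif discovery -> guided flank
analysis -> position-bias diagnostics -> dependence models + IMC table ->
CArG-box/A-tract tables; afterwards all libraries are compared pairwise by
JSD with difference-logo tables.  Every numeric output lands under the
output directory as TSV with a comment line carrying the seed and config
hash, so a rerun with the stored config reproduces the bundle byte for byte.

Contamination above threshold is recorded as a warning and the run continues
(exclusion of contaminated libraries is a judgement call, not automated).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import affinity as aff_mod
from . import background as bg_mod
from .cargbox import atract_affinity_table, top_kmers
from .compare import difference_logo, pairwise_jsd_matrix
from .dependence import imc_table, save_imc_table
from .discovery import (
    WeightedSequenceSet,
    build_training_set,
    discover_pwm,
    flank_extract_orient,
    position_bias,
    position_bias_table,
)
from .probes import ProbeDesign, ReadPool, contamination_fraction, parse_reads, write_tsv
from .simulate import (
    CONTROL_VARIABLE_REGION,
    PRESETS,
    SimConfig,
    simulate_experiment,
)

log = logging.getLogger("selexkit")


@dataclass
class LibrarySpec:
    """One library: either a simulation preset or per-round read files."""

    label: str
    preset: str | None = "wildtype"  # None when reading files
    round_files: dict[int, str] = field(default_factory=dict)
    beta: float | None = None


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    outdir: str
    seed: int = 0
    libraries: list[LibrarySpec] = field(
        default_factory=lambda: [LibrarySpec(label="wt_rep1"), LibrarySpec(label="wt_rep2")]
    )
    design: ProbeDesign = field(default_factory=ProbeDesign)
    n_reads: int = 20_000
    n_rounds: int = 2
    analysis_round: int = 2  # the paper-style default analysis round
    background_orders: tuple[int, ...] = (0, 1, 2, 3)
    k_min: int = 6
    k_max: int = 14
    affinity_cutoff: float = 0.4
    restarts: int = 200
    dependence_on: str = "flanks"  # "flanks" | "kmers"
    contamination_threshold: float = 0.05
    contamination_fraction: float = 0.0
    pcr_bias_gamma: float = 0.0
    loess_span: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "design" in raw and isinstance(raw["design"], dict):
            raw["design"] = ProbeDesign.from_dict(raw["design"])
        if "libraries" in raw:
            raw["libraries"] = [
                LibrarySpec(**lib) if isinstance(lib, dict) else lib
                for lib in raw["libraries"]
            ]
        if "background_orders" in raw:
            raw["background_orders"] = tuple(raw["background_orders"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = self.design.to_dict()
        return d

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _simulate_library(
    config: RunConfig, lib: LibrarySpec, lib_index: int
) -> list[ReadPool]:
    builder = PRESETS[lib.preset]
    model = builder() if lib.beta is None else builder(beta=lib.beta)
    sim = SimConfig(
        n_reads=config.n_reads,
        n_rounds=config.n_rounds,
        contamination_fraction=config.contamination_fraction,
        pcr_bias_gamma=config.pcr_bias_gamma,
        seed=int(config.seed + 1000 * (lib_index + 1)),
    )
    return simulate_experiment(sim, config.design, model, label=lib.label)


def _load_library(config: RunConfig, lib: LibrarySpec) -> list[ReadPool]:
    pools = []
    for r in sorted(lib.round_files):
        demux = parse_reads(
            lib.round_files[r], config.design, round_index=r
        )
        if lib.label not in demux.pools:
            raise ValueError(f"library {lib.label!r} not found in {lib.round_files[r]}")
        pools.append(demux[lib.label])
    return pools


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns a summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={config.seed} config={config.config_hash()}"
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "libraries": {},
        "warnings": [],
    }
    pwms = {}
    rng = np.random.default_rng(config.seed)

    for i, lib in enumerate(config.libraries):
        lib_dir = outdir / lib.label
        lib_dir.mkdir(exist_ok=True)
        lib_summary: dict = {}

        pools = (
            _simulate_library(config, lib, i)
            if lib.preset is not None
            else _load_library(config, lib)
        )
        by_round = {p.round_index: p for p in pools}
        r_an = config.analysis_round
        if r_an not in by_round:
            raise ValueError(f"analysis round {r_an} missing for {lib.label}")

        # --- QC ------------------------------------------------------------
        signature = CONTROL_VARIABLE_REGION[: config.design.variable_length]
        qc_rows = []
        for r, pool in sorted(by_round.items()):
            frac, flagged = contamination_fraction(
                pool, signature, config.contamination_threshold
            )
            qc_rows.append({"round": r, "fraction": frac, "flagged": flagged})
            if flagged:
                msg = f"{lib.label} round {r}: contamination {frac:.3f} above threshold"
                log.warning(msg)
                summary["warnings"].append(msg)
        write_tsv(qc_rows, lib_dir / "contamination_qc.tsv",
                  ["round", "fraction", "flagged"], comment=stamp)

        # --- background ----------------------------------------------------
        r0 = by_round[0]
        half = len(r0) // 2
        r0a = ReadPool(0, lib.label + "_a", r0.sequences[:half])
        r0b = ReadPool(0, lib.label + "_b", r0.sequences[half:])
        best_m, profile = bg_mod.select_order(
            r0a, r0b, orders=config.background_orders
        )
        write_tsv(
            [{"order": m, "r2": v} for m, v in sorted(profile.items())],
            lib_dir / "background_order.tsv", ["order", "r2"], comment=stamp,
        )
        bg = bg_mod.fit_markov(r0, best_m)
        bg.save(lib_dir / "background.txt")
        lib_summary["background_order"] = best_m

        # --- motif length --------------------------------------------------
        k_star, ig_profile = aff_mod.select_k(
            by_round[r_an], bg, range(config.k_min, config.k_max + 1)
        )
        write_tsv(
            [{"k": k, "information_gain_bits": v} for k, v in sorted(ig_profile.items())],
            lib_dir / "information_gain.tsv",
            ["k", "information_gain_bits"], comment=stamp,
        )
        lib_summary["selected_k"] = k_star

        # --- affinities ----------------------------------------------------
        tables = {}
        for r in sorted(by_round):
            if r == 0:
                continue
            tables[r] = aff_mod.estimate_affinities(by_round[r], bg, k_star, r)
            tables[r].save(lib_dir / f"affinity_R{r}.tsv")
        aff = tables[r_an]
        if 1 in tables and 2 in tables:
            try:
                loess = aff_mod.loess_combine(tables[1], tables[2], config.loess_span)
                loess.save(lib_dir / "affinity_loess.tsv")
            except ValueError as exc:
                summary["warnings"].append(f"{lib.label}: LOESS skipped ({exc})")

        # --- CArG-box / A-tract tables --------------------------------------
        if k_star == 10:
            carg = atract_affinity_table(aff)
            write_tsv(
                [
                    {
                        "cargbox": r.sequence,
                        "center": r.center,
                        "a_tract": r.has_a_tract,
                        "affinity": r.affinity,
                        "count": r.count if r.count is not None else "",
                        "flag": "missing" if r.missing else "ok",
                    }
                    for r in carg
                ],
                lib_dir / "cargbox_atract.tsv",
                ["cargbox", "center", "a_tract", "affinity", "count", "flag"],
                comment=stamp,
            )
        top21 = top_kmers(aff, 21)
        write_tsv(
            [{"kmer": w, "affinity": a} for w, a in top21],
            lib_dir / "top21.tsv", ["kmer", "affinity"], comment=stamp,
        )

        # --- motif discovery -------------------------------------------------
        training = build_training_set(aff, cutoff=config.affinity_cutoff)
        lib_summary["n_training"] = len(training)
        pwm = discover_pwm(
            training, L=k_star, restarts=config.restarts,
            seed=int(rng.integers(2**31)),
        )
        pwm.name = lib.label
        pwm.save(lib_dir / "motif.meme")
        write_tsv(pwm.logo_table(), lib_dir / "motif_logo.tsv",
                  ["position", "base", "probability", "bits"], comment=stamp)
        lib_summary["consensus"] = pwm.consensus()
        pwms[lib.label] = pwm

        # --- flank analysis ---------------------------------------------------
        flank_set = None
        try:
            flank_set, flank_pwm = flank_extract_orient(
                by_round[r_an], seed=int(rng.integers(2**31))
            )
            write_tsv(flank_pwm.logo_table(), lib_dir / "flank_logo.tsv",
                      ["position", "base", "probability", "bits"], comment=stamp)
            lib_summary["flank_consensus"] = flank_pwm.consensus()
        except ValueError as exc:
            summary["warnings"].append(f"{lib.label}: flank analysis skipped ({exc})")

        # --- position bias ----------------------------------------------------
        top100 = [w for w, _ in top_kmers(aff, 100)]
        bias = position_bias(by_round[r_an], top100)
        write_tsv(position_bias_table(bias), lib_dir / "position_bias.tsv",
                  ["kmer", "class", "offset", "count"], comment=stamp)

        # --- dependence / IMC -------------------------------------------------
        if config.dependence_on == "flanks" and flank_set is not None:
            dep_set = flank_set
        else:
            dep_set = WeightedSequenceSet(
                sequences=[w for w, _ in top_kmers(aff, len(aff.affinities))
                           if aff.affinities[w] > config.affinity_cutoff],
                weights=np.array(
                    [1e3 * a for _, a in top_kmers(aff, len(aff.affinities))
                     if a > config.affinity_cutoff]
                ),
            )
        imc_rows = imc_table(dep_set)
        save_imc_table(imc_rows, lib_dir / "imc_table.tsv")
        lib_summary["imc"] = {
            f"{r['model']}_{r['order']}": r["imc_bits"] for r in imc_rows
        }

        summary["libraries"][lib.label] = lib_summary

    # --- cross-library comparison ---------------------------------------------
    if len(pwms) >= 2:
        rows = pairwise_jsd_matrix(pwms)
        write_tsv(rows, outdir / "pairwise_jsd.tsv",
                  ["motif_a", "motif_b", "jsd", "orientation"], comment=stamp)
        names = list(pwms)
        ref = names[0]
        for other in names[1:]:
            from .compare import pwm_jsd

            _, _, orientation = pwm_jsd(pwms[ref], pwms[other])
            q = pwms[other] if orientation == "+" else pwms[other].reverse_complement()
            dl = difference_logo(pwms[ref], q)
            dl.save(outdir / f"difflogo_{ref}_vs_{other}.tsv")

    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return summary
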