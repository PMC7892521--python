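"""Probe design, read parsing/demultiplexing, contamination QC and shared file IO.

A SELEX probe is a fixed 5' adapter, a randomised variable region (25 nt by
default), a library barcode (4 nt) identifying which protein/replicate the
library was incubated with, and a fixed 3' adapter — 99 nt in total.  The last
two bases of the 5' adapter are the dinucleotide ``CT``, which matters
downstream: protein binding can recruit that constant context as the 5' end of
a near-complete binding site and produce a position bias in the variable
region.

All coordinates are 0-based, half-open.  Barcode matching is exact: 4-nt
barcodes carry no redundancy for error correction.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .kmers import encode

DEFAULT_VARIABLE_LENGTH = 25
DEFAULT_BARCODE_LENGTH = 4
DEFAULT_PROBE_LENGTH = 99

# Synthetic placeholder adapters (the vendor sequences are not part of this
# package); lengths 33 + 37 complete the 99-nt probe and the 5' adapter ends in
# the load-bearing "CT" terminus.
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATCAACGCCT"
DEFAULT_ADAPTER3 = "GATCGTCGGACTGTAGAACTCTGAACGTGTAGATCTC"

DEFAULT_BARCODES = {
    "wt_rep1": "TGAC",
    "r3a_rep1": "ACTG",
    "r3k_rep1": "GTCA",
    "wt_rep2": "CAGT",
    "r3a_rep2": "TCGA",
    "r3k_rep2": "AGCT",
    "positive_control": "CTAG",
}


@dataclass(frozen=True)
class ProbeDesign:
    """Layout of a SELEX probe: adapter5 + variable + barcode + adapter3."""

    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3
    variable_length: int = DEFAULT_VARIABLE_LENGTH
    barcode_length: int = DEFAULT_BARCODE_LENGTH
    barcodes: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    total_length: int = DEFAULT_PROBE_LENGTH

    def __post_init__(self) -> None:
        got = len(self.adapter5) + self.variable_length + self.barcode_length + len(self.adapter3)
        if got != self.total_length:
            raise ValueError(
                f"probe layout sums to {got} nt, declared total is {self.total_length}"
            )
        if not self.adapter5.endswith("CT"):
            raise ValueError("adapter5 must end with the dinucleotide 'CT'")
        bcs = list(self.barcodes.values())
        if len(set(bcs)) != len(bcs):
            raise ValueError("barcodes must be distinct")
        for label, bc in self.barcodes.items():
            if len(bc) != self.barcode_length:
                raise ValueError(
                    f"barcode {bc!r} for {label!r} has length {len(bc)}, "
                    f"expected {self.barcode_length}"
                )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProbeDesign":
        return cls(**dict(d))

    def to_dict(self) -> dict:
        return {
            "adapter5": self.adapter5,
            "adapter3": self.adapter3,
            "variable_length": self.variable_length,
            "barcode_length": self.barcode_length,
            "barcodes": dict(self.barcodes),
            "total_length": self.total_length,
        }


@dataclass
class ReadPool:
    """Variable-region sequences of one library at one selection round."""

    round_index: int
    library_label: str
    sequences: list[str]

    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.round_index < 0:
            raise ValueError("round_index must be >= 0")
        if self.sequences:
            L = len(self.sequences[0])
            if any(len(s) != L for s in self.sequences):
                raise ValueError("all sequences in a pool must have identical length")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def read_length(self) -> int:
        if not self.sequences:
            raise ValueError("empty pool has no read length")
        return len(self.sequences[0])

    def codes(self) -> np.ndarray:
        """(n, L) int8 encoding, cached; validates the alphabet."""
        if self._codes is None or self._codes.shape[0] != len(self.sequences):
            self._codes = encode(self.sequences)
        return self._codes


def assemble_probe(design: ProbeDesign, variable: str, barcode: str) -> str:
    """Full forward-strand probe: adapter5 + variable + barcode + adapter3."""
    if len(variable) != design.variable_length:
        raise ValueError(
            f"variable region length {len(variable)} != design {design.variable_length}"
        )
    if len(barcode) != design.barcode_length:
        raise ValueError(f"barcode length {len(barcode)} != design {design.barcode_length}")
    return design.adapter5 + variable + barcode + design.adapter3


@dataclass
class DemuxResult:
    """Demultiplexed pools plus bookkeeping on unassigned reads."""

    pools: dict[str, ReadPool]
    unmatched: int
    total: int

    def __getitem__(self, label: str) -> ReadPool:
        return self.pools[label]

    def __iter__(self) -> Iterator[str]:
        return iter(self.pools)

    @property
    def unmatched_fraction(self) -> float:
        return self.unmatched / self.total if self.total else 0.0

    def summary(self) -> dict:
        return {
            "total": self.total,
            "unmatched": self.unmatched,
            "assigned": {label: len(p) for label, p in self.pools.items()},
        }


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    if ext in {".fa", ".fasta", ".txt"}:
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def parse_reads(
    path,
    design: ProbeDesign,
    *,
    variable_start: int = 0,
    round_index: int = 0,
    fmt: str | None = None,
) -> DemuxResult:
    """Split reads into variable region + barcode and demultiplex by exact barcode.

    The variable region is ``[variable_start, variable_start+variable_length)``
    and the barcode the ``barcode_length`` bases immediately following it.
    Reads whose barcode matches no library are counted as unmatched, never
    silently dropped.
    """
    fmt = fmt or _sniff_format(path)
    v0, v1 = variable_start, variable_start + design.variable_length
    b1 = v1 + design.barcode_length
    by_barcode = {bc: label for label, bc in design.barcodes.items()}
    assigned: dict[str, list[str]] = {label: [] for label in design.barcodes}
    unmatched = 0
    total = 0
    with _open_maybe_gzip(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, fmt)):
            seq = str(rec.seq).upper()
            if len(seq) < b1:
                raise ValueError(
                    f"record {i} ({rec.id!r}) is {len(seq)} nt long, "
                    f"need at least {b1} for variable region + barcode"
                )
            if set(seq) - set("ACGTN"):
                raise ValueError(
                    f"record {i} ({rec.id!r}) contains letters outside ACGTN"
                )
            total += 1
            label = by_barcode.get(seq[v1:b1])
            if label is None:
                unmatched += 1
            else:
                assigned[label].append(seq[v0:v1])
    pools = {
        label: ReadPool(round_index=round_index, library_label=label, sequences=seqs)
        for label, seqs in assigned.items()
    }
    return DemuxResult(pools=pools, unmatched=unmatched, total=total)


def contamination_fraction(
    pool: ReadPool, control_signature: str, threshold: float = 0.05
) -> tuple[float, bool]:
    """Fraction of reads containing a control signature subsequence, plus a flag.

    Carry-over of the positive-control probe into later selection rounds is a
    known failure mode; the flag trips when the fraction exceeds ``threshold``.
    """
    if not pool.sequences:
        raise ValueError("contamination check on an empty pool")
    hits = sum(control_signature in s for s in pool.sequences)
    frac = hits / len(pool.sequences)
    return frac, frac > threshold


def write_reads(pool: ReadPool, path, *, fmt: str | None = None) -> None:
    """Write a pool as FASTA or FASTQ (dummy 'I' qualities), optionally gzipped."""
    fmt = fmt or _sniff_format(path)
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for i, seq in enumerate(pool.sequences):
            name = f"{pool.library_label}_r{pool.round_index}_{i}"
            if fmt == "fastq":
                out.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            else:
                out.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Result-table export
# ---------------------------------------------------------------------------

_FLOAT = "%.17g"  # round-trips IEEE doubles exactly


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return _FLOAT % x
    return str(x)


def write_tsv(rows: list[dict], path, columns: list[str], comment: str | None = None) -> None:
    """Plain TSV with header; floats serialised losslessly.

    An optional comment (e.g. seed/config provenance) goes on a leading
    '#' line; all readers in this package skip such lines.
    """
    with open(path, "w") as out:
        if comment:
            out.write(f"# {comment}\n")
        out.write("\t".join(columns) + "\n")
        for row in rows:
            out.write("\t".join(_fmt(row[c]) for c in columns) + "\n")


def export_tables(objects, path_prefix, *, metadata: dict | None = None) -> list[Path]:
    """Write any mix of pipeline result objects next to each other.

    Dispatch is by capability: every result type knows how to save itself
    (``save(path)``) and declares its file suffix (``file_suffix``).  A
    metadata sidecar (seeds, parameters) is written as JSON when given.
    Returns the written paths.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not isinstance(objects, (list, tuple)):
        objects = [objects]
    for i, obj in enumerate(objects):
        if not hasattr(obj, "save") or not hasattr(obj, "file_suffix"):
            raise TypeError(f"object {type(obj).__name__} is not exportable")
        tag = getattr(obj, "export_name", None) or f"{i}"
        path = prefix.parent / f"{prefix.name}.{tag}{obj.file_suffix}"
        obj.save(path)
        written.append(path)
    if metadata is not None:
        meta_path = prefix.parent / f"{prefix.name}.meta.json"
        with open(meta_path, "w") as out:
            json.dump(metadata, out, indent=2, sort_keys=True)
            out.write("\n")
        written.append(meta_path)
    return written
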