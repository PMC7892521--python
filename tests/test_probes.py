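"""Probe design, demultiplexing, contamination QC and table round-trips."""

import numpy as np
import pytest
from scipy import stats

import selexkit as sk
from selexkit.probes import DEFAULT_BARCODES, write_reads


def test_default_design_layout(design):
    assert len(design.adapter5) + design.variable_length + design.barcode_length + len(
        design.adapter3
    ) == design.total_length == 99
    assert design.adapter5.endswith("CT")


def test_design_rejects_inconsistent_layout():
    with pytest.raises(ValueError, match="sums to"):
        sk.ProbeDesign(variable_length=24)
    with pytest.raises(ValueError, match="CT"):
        sk.ProbeDesign(adapter5="A" * 33, adapter3="G" * 37)
    with pytest.raises(ValueError, match="distinct"):
        sk.ProbeDesign(barcodes={"a": "GATC", "b": "GATC"})


def test_assemble_probe_examples(design):
    probe = sk.assemble_probe(design, "A" * 25, "GATC")
    assert len(probe) == 99
    assert probe.endswith(design.adapter3)
    small = sk.ProbeDesign(
        adapter5="CT", adapter3="", variable_length=25, barcode_length=2,
        barcodes={"x": "AA"}, total_length=29,
    )
    assert len(sk.assemble_probe(small, "G" * 25, "AA")) == 29
    with pytest.raises(ValueError):
        sk.assemble_probe(design, "A" * 24, "GATC")


def _write_fasta(path, seqs):
    with open(path, "w") as out:
        for i, s in enumerate(seqs):
            out.write(f">r{i}\n{s}\n")


def test_parse_reads_exact_split(tmp_path, design):
    d = sk.ProbeDesign(barcodes={"lib1": "GATC"})
    path = tmp_path / "reads.fa"
    _write_fasta(path, ["A" * 25 + "GATC"])
    res = sk.parse_reads(path, d)
    assert len(res["lib1"]) == 1
    assert res["lib1"].sequences[0] == "A" * 25
    assert res.unmatched == 0


def test_parse_reads_unknown_barcode_counted(tmp_path):
    d = sk.ProbeDesign(barcodes={"lib1": "TTTT"})
    path = tmp_path / "reads.fa"
    _write_fasta(path, ["A" * 25 + "GATC"])
    res = sk.parse_reads(path, d)
    assert len(res["lib1"]) == 0
    assert res.unmatched == 1
    assert res.summary()["total"] == 1


def test_parse_reads_rejects_bad_letters(tmp_path, design):
    path = tmp_path / "reads.fa"
    _write_fasta(path, ["A" * 24 + "X" + "GATC"])
    with pytest.raises(ValueError, match="record 0"):
        sk.parse_reads(path, design)


def test_parse_reads_rejects_short_records(tmp_path, design):
    path = tmp_path / "reads.fa"
    _write_fasta(path, ["ACGT"])
    with pytest.raises(ValueError, match="record 0"):
        sk.parse_reads(path, design)


def test_demultiplex_conservation_and_bookkeeping(tmp_path, rng):
    """Assigned + unmatched reads must equal the input total."""
    d = sk.ProbeDesign(barcodes={"a": "GATC", "b": "CTAG"})
    barcodes = ["GATC"] * 500 + ["CTAG"] * 500 + ["AAAA"] * 37
    rng.shuffle(barcodes)
    seqs = []
    for bc in barcodes:
        var = "".join("ACGT"[c] for c in rng.integers(0, 4, 25))
        seqs.append(var + bc)
    path = tmp_path / "reads.fa"
    _write_fasta(path, seqs)
    res = sk.parse_reads(path, d)
    assert len(res["a"]) == 500
    assert len(res["b"]) == 500
    assert res.unmatched == 37
    assert len(res["a"]) + len(res["b"]) + res.unmatched == res.total == len(seqs)


def test_parse_recovers_assembled_probes(tmp_path, design, rng):
    """parse_reads composed with assemble_probe is the identity on (variable, barcode)."""
    labels = list(DEFAULT_BARCODES)[:3]
    expected = {}
    probes = []
    for label in labels:
        var = "".join("ACGT"[c] for c in rng.integers(0, 4, 25))
        expected[label] = var
        probes.append(sk.assemble_probe(design, var, design.barcodes[label]))
    path = tmp_path / "probes.fa"
    _write_fasta(path, probes)
    res = sk.parse_reads(path, design, variable_start=len(design.adapter5))
    for label in labels:
        assert res[label].sequences == [expected[label]]


def test_parse_reads_fastq_gzip(tmp_path, design):
    import gzip

    d = sk.ProbeDesign(barcodes={"lib1": "GATC"})
    path = tmp_path / "reads.fq.gz"
    with gzip.open(path, "wt") as out:
        out.write("@r0\n" + "C" * 25 + "GATC\n+\n" + "I" * 29 + "\n")
    res = sk.parse_reads(path, d)
    assert res["lib1"].sequences == ["C" * 25]


def test_contamination_fraction_examples():
    pool = sk.ReadPool(2, "x", ["TTTT" + "A" * 21] * 10 + ["C" * 25] * 90)
    frac, flagged = sk.contamination_fraction(pool, "TTTT" + "A" * 21)
    assert frac == pytest.approx(0.10)
    assert flagged
    frac, flagged = sk.contamination_fraction(pool, "G" * 25)
    assert frac == 0.0
    assert not flagged
    with pytest.raises(ValueError):
        sk.contamination_fraction(sk.ReadPool(0, "e", []), "AAAA")


def test_contamination_spike_recovered_within_binomial_interval(design):
    """A 30% simulated spike is detected at the binomially plausible rate."""
    n = 4000
    cfg = sk.SimConfig(
        n_reads=n, n_rounds=1, contamination_fraction=0.3, seed=42,
        library_oversample=5,
    )
    pools = sk.simulate_experiment(cfg, design, sk.wildtype_model())
    sig = cfg.contaminant
    frac, flagged = sk.contamination_fraction(pools[1], sig)
    lo, hi = stats.binom.interval(0.99, n, 0.3)
    assert lo / n <= frac <= hi / n
    assert flagged


def test_write_and_reparse_reads_roundtrip(tmp_path):
    pool = sk.ReadPool(1, "lib", ["ACGTN" + "A" * 20, "T" * 25])
    for name in ("out.fa", "out.fq", "out.fq.gz"):
        path = tmp_path / name
        write_reads(pool, path)
        from Bio import SeqIO

        from selexkit.probes import _open_maybe_gzip, _sniff_format

        with _open_maybe_gzip(path) as fh:
            seqs = [str(r.seq) for r in SeqIO.parse(fh, _sniff_format(path))]
        assert seqs == pool.sequences


def test_export_tables_roundtrip(tmp_path, rng):
    aff = sk.AffinityTable(
        k=4,
        round_used=2,
        provenance="R2",
        affinities={"AAAA": 1.0, "ACGT": 1 / 3},
        counts={"AAAA": 30, "ACGT": 10},
        expected={"AAAA": 10.0, "ACGT": 10.0},
        raw={"AAAA": 3.0, "ACGT": 1.0},
        low_confidence=set(),
    )
    pwm = sk.PositionWeightMatrix(
        probs=rng.dirichlet(np.ones(4), size=10), pseudocount=0.5
    )
    paths = sk.export_tables([aff, pwm], tmp_path / "run", metadata={"seed": 1})
    assert len(paths) == 3
    back = sk.AffinityTable.load([p for p in paths if p.suffix == ".tsv"][0])
    assert back.affinities == aff.affinities
    assert back.counts == aff.counts
    meme = [p for p in paths if p.suffix == ".meme"][0]
    back_pwm = sk.PositionWeightMatrix.load(meme)
    assert len(back_pwm) == 10
    assert np.allclose(back_pwm.probs, pwm.probs, atol=1e-5)
    assert sum(1 for _ in open(meme)) >= 10


def test_export_empty_affinity_table_writes_header_only(tmp_path):
    aff = sk.AffinityTable(k=4, round_used=1, provenance="R1", affinities={})
    paths = sk.export_tables([aff], tmp_path / "empty")
    lines = open(paths[0]).read().splitlines()
    assert lines == ["kmer\tcount\texpected\traw\taffinity\tflag"]
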