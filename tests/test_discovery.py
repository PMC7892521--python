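"""Training-set construction, EM motif discovery, flank analysis, position bias."""

import re
from itertools import product

import numpy as np
import pytest

import selexkit as sk
from selexkit.discovery import classify_kmer, consensus_matches
from selexkit.kmers import revcomp


class TestBuildTrainingSet:
    def test_cutoff_and_padding(self):
        aff = sk.AffinityTable(
            10, 2, "R2", {"CCAAAAATGG": 1.0, "CCGCGCGCGG": 0.39}
        )
        ts = sk.build_training_set(aff)
        assert ts.sequences == ["N" * 5 + "CCAAAAATGG" + "N" * 5]
        assert ts.weights[0] == pytest.approx(1000.0)

    def test_error_when_nothing_above_cutoff(self):
        aff = sk.AffinityTable(10, 2, "R2", {"CCAAAAATGG": 0.4})
        with pytest.raises(ValueError, match="cutoff"):
            sk.build_training_set(aff)

    def test_size_in_reported_working_range(self, wt_affinities):
        ts = sk.build_training_set(wt_affinities)
        assert 50 <= len(ts) <= 200


class TestIupacConsensus:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), "N"),
            ((0.45, 0.05, 0.05, 0.45), "W"),
            ((0.05, 0.9, 0.03, 0.02), "C"),
            ((0.48, 0.20, 0.17, 0.15), "N"),  # dominant but below every rule
            ((0.5, 0.25, 0.15, 0.1), "A"),  # exactly at the 0.5 / 2x boundary
            ((0.4, 0.4, 0.1, 0.1), "M"),
        ],
    )
    def test_column_rules(self, column, expected):
        pwm = sk.PositionWeightMatrix(np.array([column]))
        assert sk.iupac_consensus(pwm) == expected


class TestDiscoverPwm:
    def test_recovers_unambiguous_planted_motif(self):
        ts = sk.WeightedSequenceSet(
            ["NNNNNCCAAAATTGGNNNNN"] * 20, np.ones(20)
        )
        pwm = sk.discover_pwm(ts, L=10, restarts=20, seed=0)
        assert pwm.consensus() == "CCAAAATTGG"

    def test_reverse_complemented_set_gives_same_canonical_pwm(self):
        seqs = [
            "NNNNNCCAAAATTGGNNNNN",
            "NNNNNCCAAATTTGGNNNNN",
            "NNNNNCCTAAATTGGNNNNN",
        ] * 5
        ts = sk.WeightedSequenceSet(seqs, np.ones(15))
        ts_rc = sk.WeightedSequenceSet([revcomp(s) for s in seqs], np.ones(15))
        a = sk.discover_pwm(ts, L=10, restarts=10, seed=1)
        b = sk.discover_pwm(ts_rc, L=10, restarts=10, seed=1)
        assert np.allclose(a.probs, b.probs, atol=1e-6)

    def test_em_beats_every_hard_assignment(self):
        """Mixture likelihood bounds the best hard window/strand completion."""
        seqs = ["ACGTAC", "GTACGT", "AAACGT", "CGTAAA", "TTACGA", "ACGAAT"]
        weights = np.ones(len(seqs))
        L = 4
        ts = sk.WeightedSequenceSet(seqs, weights)
        pwm = sk.discover_pwm(ts, L=L, restarts=200, seed=0, pseudocount=0.0)
        from selexkit.discovery import _em_run, _one_hot

        X = _one_hot(seqs)
        _, best_ll, _ = _em_run(
            X, weights, L, pwm.probs, max_iter=200, tol=1e-9
        )
        n_pos = len(seqs[0]) - L + 1
        # enumerate all hard assignments of (window, strand) per sequence
        def seq_window(s, o, strand):
            win = s[o : o + L]
            return win if strand == 0 else revcomp(win)

        best_hard = -np.inf
        options = list(product(range(n_pos), (0, 1)))
        for assign in product(options, repeat=len(seqs)):
            wins = [seq_window(s, o, st) for s, (o, st) in zip(seqs, assign)]
            counts = np.zeros((L, 4))
            for w in wins:
                for j, b in enumerate(w):
                    counts[j, "ACGT".index(b)] += 1
            probs = counts / counts.sum(axis=1, keepdims=True)
            ll = 0.0
            for s, (o, st) in zip(seqs, assign):
                w = seq_window(s, o, st)
                ll += sum(
                    np.log(max(probs[j, "ACGT".index(b)], 1e-12))
                    for j, b in enumerate(w)
                )
                ll += (len(s) - L) * np.log(0.25)
                ll += np.log(1 / (2 * n_pos))
            best_hard = max(best_hard, ll)
        assert best_ll >= best_hard - 1e-6

    def test_weight_scale_invariance(self):
        seqs = ["NNNNNCCAAAATTGGNNNNN", "NNNNNCCATAATTGGNNNNN"] * 4
        a = sk.discover_pwm(
            sk.WeightedSequenceSet(seqs, np.full(8, 2.0)), L=10, restarts=5, seed=2
        )
        b = sk.discover_pwm(
            sk.WeightedSequenceSet(seqs, np.full(8, 4.0)), L=10, restarts=5, seed=2
        )
        assert np.allclose(a.probs, b.probs, atol=1e-9)

    def test_seeded_determinism(self, wt_affinities):
        ts = sk.build_training_set(wt_affinities)
        a = sk.discover_pwm(ts, L=10, restarts=5, seed=42)
        b = sk.discover_pwm(ts, L=10, restarts=5, seed=42)
        assert np.array_equal(a.probs, b.probs)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError, match="all positions are N"):
            sk.discover_pwm(
                sk.WeightedSequenceSet(["NNNNN"], np.ones(1)), L=3, restarts=1, seed=0
            )

    def test_wt_preset_consensus_recovery(self, wt_pwm):
        """Discovered motif matches CCNWAAATGG at >= 8/10 positions."""
        fwd = consensus_matches(wt_pwm.consensus(), "CCNWAAATGG")
        rev = consensus_matches(
            sk.iupac_consensus(wt_pwm.reverse_complement()), "CCNWAAATGG"
        )
        assert max(fwd, rev) >= 8


class TestFlankAnalysis:
    def test_extracts_planted_window(self):
        read = "TTAACCAAAAAAGGAAGTCGATCGA"
        pool = sk.ReadPool(2, "t", [read])
        wset, _ = sk.flank_extract_orient(pool, seed=0)
        assert any(
            s in (read[:18], revcomp(read[:18])) for s in wset.sequences
        )

    def test_minus_strand_window_is_flipped_to_core_orientation(self):
        fwd_window = "TTAACCAAAAAAGGAAGT"
        read = revcomp(fwd_window) + "CGATCGA"
        pool = sk.ReadPool(2, "t", [read])
        wset, _ = sk.flank_extract_orient(pool, seed=0)
        assert len(wset) == 1
        assert wset.sequences[0] in (fwd_window, revcomp(fwd_window))
        core = wset.sequences[0][4:14]
        assert re.fullmatch("CC[AT]{6}GG", core)

    def test_match_count_equals_regex_oracle(self, wt_experiment):
        pool = sk.ReadPool(2, "sub", wt_experiment[2].sequences[:2000])
        wset, _ = sk.flank_extract_orient(pool, seed=1)
        rx = re.compile("(?=[ACGT]{4}CC[AT]{6}GG[ACGT]{4})")
        expected = 0
        for s in pool.sequences:
            hits = {m.start() for m in rx.finditer(s)}
            hits |= {
                len(s) - 18 - m.start() for m in rx.finditer(revcomp(s))
            }
            expected += len(hits)
        assert len(wset) == expected

    def test_wt_flanks_prefer_t_upstream_a_downstream(self, wt_experiment):
        """The oriented flank PWM shows the TTN- / -NAA preference."""
        pool = sk.ReadPool(2, "sub", wt_experiment[2].sequences[:40_000])
        _, pwm = sk.flank_extract_orient(pool, seed=2)
        p = pwm.probs
        t_up = p[2, 3] + p[3, 3]  # T at the two positions closest to CC
        a_dn = p[14, 0] + p[15, 0]  # A at the two positions after GG
        flipped = p[::-1, ::-1]
        t_up_f = flipped[2, 3] + flipped[3, 3]
        a_dn_f = flipped[14, 0] + flipped[15, 0]
        score = max(t_up + a_dn, t_up_f + a_dn_f)
        assert score > 4 * 0.27  # clearly above the uniform expectation


class TestPositionBias:
    def test_planted_offsets_recovered(self):
        reads = ["GG" + "CCAAAAATGG" + "ACGTACGTACGTA"] * 3
        pool = sk.ReadPool(2, "t", reads)
        hist, label = sk.position_bias(pool, ["CCAAAAATGG"])["CCAAAAATGG"]
        assert label == "complete"
        assert hist[2] == 3 and hist.sum() == 3

    def test_paper_style_incomplete_example(self):
        assert classify_kmer("TTTATGGTAA") == "incomplete"
        assert classify_kmer("CCAAAAATGG") == "complete"
        assert classify_kmer("GCGCGCGCGC") == "other"

    def test_adapter_artifact_biases_incomplete_kmers_to_probe_start(
        self, wt_experiment, wt_affinities
    ):
        """Incomplete CArG-boxes among the top-100 pile up at offsets 1-2."""
        top100 = [w for w, _ in sk.top_kmers(wt_affinities, 100)]
        result = sk.position_bias(wt_experiment[2], top100)
        agg = None
        n_incomplete = 0
        for w, (hist, label) in result.items():
            if label == "incomplete":
                n_incomplete += 1
                agg = hist if agg is None else agg + hist
        assert n_incomplete > 0
        mode_offset = int(np.argmax(agg)) + 1
        assert mode_offset in (1, 2)
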