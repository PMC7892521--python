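"""K-mer counting, information gain, affinity estimation and LOESS refinement."""

import numpy as np
import pytest

import selexkit as sk
from selexkit.affinity import local_linear_fit, plateau_onset


def _pool(seqs, round_index=1):
    return sk.ReadPool(round_index, "t", seqs)


def _uniform_bg(order=0):
    return sk.MarkovBackground(
        order, np.full(4**order, 4.0**-order), np.full((4**order, 4), 0.25), 0.5
    )


class TestCountKmers:
    def test_unmerged_hand_example(self):
        t = sk.count_kmers(_pool(["ACGT"]), 2, merge_revcomp=False)
        assert t.counts == {"AC": 1, "CG": 1, "GT": 1}

    def test_merged_hand_example(self):
        # GT canonicalizes onto AC; CG is its own reverse complement
        t = sk.count_kmers(_pool(["ACGT"]), 2, merge_revcomp=True)
        assert t.counts == {"AC": 2, "CG": 1}

    def test_window_conservation(self, rng):
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, 25)) for _ in range(10_000)]
        for k in (2, 8):
            t = sk.count_kmers(_pool(seqs), k)
            assert t.values.sum() == t.total_windows == 10_000 * (25 - k + 1)

    def test_windows_with_n_are_skipped(self):
        t = sk.count_kmers(_pool(["ACGNT"]), 2, merge_revcomp=False)
        assert t.counts == {"AC": 1, "CG": 1}
        assert t.total_windows == 2


class TestInformationGain:
    def test_zero_when_observed_matches_background(self):
        # uniform pool fragments covering every 1-mer equally
        pool = _pool(["AC", "GT", "CA", "TG"])
        ig = sk.information_gain(pool, _uniform_bg(), 1, min_count=1)
        assert ig == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_analytic_value(self):
        # all windows are the self-complementary 2-mer AT: p0(AT) = 1/16
        pool = _pool(["AT"] * 50)
        ig = sk.information_gain(pool, _uniform_bg(), 2, min_count=1)
        assert ig == pytest.approx(4.0)

    def test_planted_selection_gains_more_at_site_length(
        self, wt_experiment, wt_background
    ):
        ig6 = sk.information_gain(wt_experiment[2], wt_background, 6)
        ig10 = sk.information_gain(wt_experiment[2], wt_background, 10)
        assert ig10 > ig6 > 0


class TestSelectK:
    def test_plateau_rule_forced_profiles(self):
        assert plateau_onset({6: 3.0, 8: 3.8, 10: 4.5, 12: 4.5, 14: 4.5}) == 10
        assert plateau_onset({6: 1.0, 7: 1.0, 8: 1.0}) == 6  # flat -> smallest
        assert plateau_onset({8: 2.0, 10: 2.019}, tol=0.01) == 8  # within 1%

    def test_rejects_bad_ranges(self, wt_experiment, wt_background):
        with pytest.raises(ValueError):
            sk.select_k(wt_experiment[2], wt_background, [])
        with pytest.raises(ValueError):
            sk.select_k(wt_experiment[2], wt_background, [6, 9, 10])

    def test_profile_reported_for_every_k(self, wt_experiment, wt_background):
        _, profile = sk.select_k(wt_experiment[2], wt_background, range(8, 12))
        assert sorted(profile) == [8, 9, 10, 11]


class TestEstimateAffinities:
    def test_single_round_ratio_normalisation(self):
        # single-window reads: counts are read multiplicities, expectations equal
        reads = ["AAAA"] * 40 + ["CCCC"] * 20 + ["GACC"] * 10
        table = sk.estimate_affinities(_pool(reads, 1), _uniform_bg(), 4, 1)
        a = table.affinities
        assert a["AAAA"] == 1.0
        assert a["CCCC"] == pytest.approx(0.5)
        assert a["GACC"] == pytest.approx(0.25)

    def test_second_round_square_root_rule(self):
        reads = ["AAAA"] * 16 + ["CCCC"] * 4
        table = sk.estimate_affinities(_pool(reads, 2), _uniform_bg(), 4, 2)
        assert table.affinities["AAAA"] == 1.0
        assert table.affinities["CCCC"] == pytest.approx(0.5)

    def test_scale_invariance(self):
        reads = ["AAAA"] * 8 + ["CCCC"] * 2
        t1 = sk.estimate_affinities(_pool(reads, 1), _uniform_bg(), 4, 1)
        t3 = sk.estimate_affinities(_pool(reads * 3, 1), _uniform_bg(), 4, 1)
        for w in t1.affinities:
            assert t1.affinities[w] == pytest.approx(t3.affinities[w])

    def test_strand_symmetric_queries(self, wt_affinities):
        some = list(wt_affinities.affinities)[:50]
        for w in some:
            assert wt_affinities.affinity(w) == wt_affinities.affinity(sk.revcomp(w))

    def test_max_affinity_exactly_one(self, wt_affinities):
        assert max(wt_affinities.affinities.values()) == 1.0

    def test_low_count_kmers_flagged_not_dropped(self):
        reads = ["AAAA"] * 20 + ["CCCC"] * 2
        table = sk.estimate_affinities(_pool(reads, 1), _uniform_bg(), 4, 1)
        assert "CCCC" in table.affinities
        assert "CCCC" in table.low_confidence
        assert "AAAA" not in table.low_confidence

    def test_requires_selected_round(self):
        with pytest.raises(ValueError):
            sk.estimate_affinities(_pool(["AAAA"], 0), _uniform_bg(), 4, 0)

    def test_selection_free_null_concentrates_near_uniform(self, design):
        """beta = 0: no 8-mer affinity exceeds 3x the median."""
        model = sk.wildtype_model(beta=0.0)
        cfg = sk.SimConfig(n_reads=100_000, n_rounds=2, seed=19)
        r0 = sk.simulate_r0(cfg, design)
        rounds = sk.run_rounds(model, r0, cfg, design)
        bg = sk.fit_markov(r0, 2)
        table = sk.estimate_affinities(rounds[-1], bg, 8, 2)
        vals = np.array(list(table.affinities.values()))
        assert vals.max() <= 3 * np.median(vals)


def _canonical_keys(n):
    from itertools import product

    keys = []
    for p in product("ACGT", repeat=4):
        k = "".join(p)
        if sk.canonical(k) == k:
            keys.append(k)
        if len(keys) == n:
            return keys
    raise AssertionError("not enough canonical 4-mers")


def test_affinity_estimates_recover_planted_ranking(
    design, wt_experiment, wt_affinities
):
    """Spearman >= 0.9 between estimated and planted affinities (top 100).

    The planted oracle for a k-mer is its RMS probe weight: the k-mer is
    planted into random probes (common random numbers across k-mers, base
    probes without strong co-occurring sites) and the root-mean-square
    occupancy weight is taken, matching the weight^2 tilt of two selection
    rounds.  This credits partially-overlapping ("shoulder") k-mers exactly
    as the counting estimator sees them.
    """
    from scipy.stats import spearmanr

    from selexkit.kmers import decode
    from selexkit.simulate import pool_weights

    model = sk.wildtype_model()
    top100 = [w for w, _ in sk.top_kmers(wt_affinities, 100)]
    rng = np.random.default_rng(0)
    L = design.variable_length
    base = []
    while len(base) < 4000:
        cand = decode(rng.integers(0, 4, size=(8000, L), dtype=np.int8))
        wts = pool_weights(model, sk.ReadPool(0, "b", cand), design)
        base += [s for s, x in zip(cand, wts) if x < 1.5]
    base = base[:4000]
    pos = rng.integers(0, L - 10 + 1, size=4000)
    planted = {}
    for w in top100:
        seqs = [s[:p] + w + s[p + 10 :] for s, p in zip(base, pos)]
        wts = pool_weights(model, sk.ReadPool(0, "o", seqs), design)
        planted[w] = float(np.sqrt((wts**2).mean()))
    rho = spearmanr(
        [wt_affinities.affinities[w] for w in top100],
        [planted[w] for w in top100],
    ).statistic
    assert rho >= 0.9


class TestLoess:
    def _tables(self, x, y):
        keys = _canonical_keys(len(x))
        t1 = sk.AffinityTable(4, 1, "R1", dict(zip(keys, x)))
        t2 = sk.AffinityTable(4, 2, "R2", dict(zip(keys, y)))
        return keys, t1, t2

    def test_identity_relation_reproduced(self, rng):
        x = np.sort(rng.uniform(0.05, 1.0, 40))
        x[-1] = 1.0
        _, t1, t2 = self._tables(x, x)
        out = sk.loess_combine(t1, t2)
        for w, v in out.affinities.items():
            assert v == pytest.approx(t2.affinities[w], abs=1e-6)

    def test_log_linear_relation_reproduced(self, rng):
        x = np.sort(rng.uniform(0.05, 1.0, 40))
        y = 0.7 * x
        _, t1, t2 = self._tables(x, y)
        out = sk.loess_combine(t1, t2)
        for w, v in out.affinities.items():
            assert v == pytest.approx(t2.affinities[w] / y.max(), abs=1e-6)

    def test_matches_bruteforce_weighted_least_squares(self, rng):
        """Fitted values agree with an independent per-point tricube WLS oracle."""
        n = 60
        x = np.sort(rng.uniform(0.02, 1.0, n))
        y = np.exp(np.log(0.8 * x) + rng.normal(0, 0.1, n))
        keys, t1, t2 = self._tables(x, y)
        span = 0.5
        out = sk.loess_combine(t1, t2, span=span)
        lx, ly = np.log(x), np.log(y)
        q = int(np.ceil(span * n))
        fitted = []
        for x0 in lx:
            d = np.abs(lx - x0)
            idx = np.argsort(d)[:q]
            dmax = d[idx].max()
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            coef = np.polyfit(lx[idx], ly[idx], 1, w=np.sqrt(w))
            fitted.append(np.polyval(coef, x0))
        fitted = np.exp(np.array(fitted))
        fitted /= fitted.max()
        for key, val in zip(keys, fitted):
            assert out.affinities[key] == pytest.approx(val, abs=1e-6)

    def test_agrees_with_statsmodels_on_linear_data(self, rng):
        """On exactly log-linear data both smoothers return the line."""
        import statsmodels.api as sm

        n = 50
        x = np.sort(rng.uniform(0.05, 1.0, n))
        y = np.clip(0.6 * x ** 1.2, None, 1.0)
        lx, ly = np.log(x), np.log(y)
        ours = local_linear_fit(lx, ly, lx, span=0.5)
        theirs = sm.nonparametric.lowess(
            ly, lx, frac=0.5, it=0, return_sorted=False
        )
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_requires_shared_keys(self):
        t1 = sk.AffinityTable(4, 1, "R1", {"AAAA": 1.0})
        t2 = sk.AffinityTable(4, 2, "R2", {"AAAA": 1.0})
        with pytest.raises(ValueError, match="shared"):
            sk.loess_combine(t1, t2)
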