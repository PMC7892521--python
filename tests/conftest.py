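"""Shared fixtures: simulated SELEX experiments reused across the suite.

The wildtype experiment is simulated once per session at the scale the
length-selection analysis needs (1e5 reads per round); the replicate and
mutant libraries are smaller since only motif-level summaries are taken
from them.
"""

import numpy as np
import pytest

import selexkit as sk


@pytest.fixture(scope="session")
def design():
    return sk.ProbeDesign()


@pytest.fixture(scope="session")
def wt_experiment(design):
    """(r0, r1, r2) for the wildtype preset at full desk scale."""
    cfg = sk.SimConfig(n_reads=100_000, n_rounds=2, seed=11)
    return sk.simulate_experiment(cfg, design, sk.wildtype_model(), label="wt_rep1")


@pytest.fixture(scope="session")
def wt_background(wt_experiment):
    return sk.fit_markov(wt_experiment[0], 2)


@pytest.fixture(scope="session")
def wt_affinities(wt_experiment, wt_background):
    return sk.estimate_affinities(wt_experiment[2], wt_background, 10, 2)


@pytest.fixture(scope="session")
def wt_replicate_experiment(design):
    """Second, smaller wildtype replicate (motif-level use only)."""
    cfg = sk.SimConfig(n_reads=30_000, n_rounds=2, seed=23)
    return sk.simulate_experiment(cfg, design, sk.wildtype_model(), label="wt_rep2")


@pytest.fixture(scope="session")
def mutant_experiment(design):
    cfg = sk.SimConfig(n_reads=30_000, n_rounds=2, seed=37)
    return sk.simulate_experiment(cfg, design, sk.mutant_model(), label="mut_rep1")


def discover_from_experiment(pools, seed, restarts=40):
    """Shared helper: R0->R2 analysis down to a discovered PWM."""
    r0, _, r2 = pools
    bg = sk.fit_markov(r0, 2)
    aff = sk.estimate_affinities(r2, bg, 10, 2)
    training = sk.build_training_set(aff)
    return sk.discover_pwm(training, L=10, restarts=restarts, seed=seed)


@pytest.fixture(scope="session")
def wt_pwm(wt_experiment):
    return discover_from_experiment(wt_experiment, seed=5)


@pytest.fixture(scope="session")
def wt_replicate_pwm(wt_replicate_experiment):
    return discover_from_experiment(wt_replicate_experiment, seed=7)


@pytest.fixture(scope="session")
def mutant_pwm(mutant_experiment):
    return discover_from_experiment(mutant_experiment, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
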