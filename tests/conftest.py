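import numpy as np
import pytest

from rxseq import (
    MixtureMarkovParams,
    build_all,
    preset_scenario,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-emulation cohort (n=2000, seed 1) shared across tests."""
    cfg = preset_scenario("paper_default", seed=1, n_patients=2000)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def paper_sequences(paper_cohort):
    _, cohort = paper_cohort
    sequences, summary = build_all(cohort.prescriptions, cohort.diagnoses)
    return sequences, summary


@pytest.fixture
def two_state_params():
    """Hand-checkable 2-state mixture: component 1 is component 0 'reversed'."""
    return MixtureMarkovParams(
        mixing=np.array([0.5, 0.5]),
        initial=np.array([[0.5, 0.5], [0.5, 0.5]]),
        transition=np.array(
            [[[0.9, 0.1], [0.2, 0.8]], [[0.8, 0.2], [0.1, 0.9]]]
        ),
    )


def random_params(rng, K, S):
    return MixtureMarkovParams(
        mixing=rng.dirichlet(np.ones(K)),
        initial=rng.dirichlet(np.ones(S), size=K),
        transition=rng.dirichlet(np.ones(S), size=(K, S)),
    )


def random_dataset(rng, n, K, S, max_len):
    """Draw sequences from random mixture params (the generative oracle)."""
    params = random_params(rng, K, S)
    seqs = []
    for _ in range(n):
        z = rng.choice(K, p=params.mixing)
        L = int(rng.integers(1, max_len + 1))
        s = [int(rng.choice(S, p=params.initial[z]))]
        for _ in range(L - 1):
            s.append(int(rng.choice(S, p=params.transition[z, s[-1]])))
        seqs.append(s)
    return seqs, params
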