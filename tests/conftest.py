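import numpy as np
import pytest

import conflictstop as cs


@pytest.fixture(scope="session")
def default_session():
    """One full 936-trial simulated session."""
    return cs.generate_session(seed=42)


@pytest.fixture(scope="session")
def small_truth():
    return cs.default_ground_truth(n_subjects=8, seed=3)


@pytest.fixture(scope="session")
def small_epochs(small_truth):
    return cs.simulate_epochs(small_truth, n_trials_per_condition=40)


@pytest.fixture(scope="session")
def small_decomps(small_epochs):
    dA = cs.decompose_condition(small_epochs, "congruent", seed=1)
    dB = cs.decompose_condition(small_epochs, "incongruent", seed=2)
    return dA, dB


@pytest.fixture(scope="session")
def small_pairs(small_decomps):
    return cs.match_components(*small_decomps, seed=5)


@pytest.fixture(scope="session")
def true_topographies(small_truth):
    return np.stack([s.topography for s in small_truth.sources])
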