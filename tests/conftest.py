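import numpy as np
import pytest

import aadm


@pytest.fixture(scope="session")
def small_dataset():
    """A complete synthetic experiment, 6 participants per gender."""
    scenario = aadm.default_scenario(n_per_gender=6, seed=202)
    return aadm.generate_dataset(scenario)


@pytest.fixture(scope="session")
def clean_trials(small_dataset):
    trials, _, _ = small_dataset
    trials, _ = aadm.exclude_participants(trials)
    trials, _ = aadm.filter_rts(trials)
    return trials


@pytest.fixture(scope="session")
def cell_summaries(clean_trials):
    return aadm.summarize_cells(clean_trials)


@pytest.fixture(scope="session")
def ez_estimates(cell_summaries):
    return aadm.estimate_all(cell_summaries)


@pytest.fixture()
def rng():
    return np.random.default_rng(8675309)
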