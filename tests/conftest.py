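import numpy as np
import pytest

from neurocmc.synth import (default_ground_truth, simulate_pseudo_trial_table,
                            synthesize_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """Two-participant synthetic dataset (trials, epochs, ground truth)."""
    return synthesize_dataset(n_participants=2, n_blocks=4,
                              trials_per_stimulus_per_block=20,
                              n_channels=32, rng_seed=42)


@pytest.fixture(scope="session")
def tiny_fit():
    """A small but converged-enough hierarchical fit for diagnostics tests."""
    from neurocmc.inference import build_model, sample_posterior
    truth = default_ground_truth(rng_seed=3)
    table = simulate_pseudo_trial_table(truth, n_participants=4,
                                        n_pseudo_per_participant=120,
                                        rng_seed=7)
    model = build_model(table)
    samples = sample_posterior(model, n_samples=700, burn_in=300, thin=4,
                               chains=2, rng_seed=5)
    return truth, table, model, samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
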