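import numpy as np
import pandas as pd
import pytest

from circaedes import conditioning, preprocess, synth


@pytest.fixture(scope="session")
def small_layout():
    """1 duplicate-2 probe, 1 triplicate, 1 quadruplicate, 2 spikes: 11 spots."""
    return synth.generate_layout(1, 1, 1, 2)


@pytest.fixture(scope="session")
def demo_layout():
    return synth.generate_layout(40, 3, 1, 6)


def make_dataset(n_probes, frac, amplitude, noise_sd, seed, smooth=False):
    """Simulate -> preprocess -> condition; returns (truth, conditioned matrix)."""
    layout = synth.generate_layout(n_probes, 0, 0, 10)
    truth = synth.make_truth_table(
        layout.probe_ids(), frac, amplitude, noise_sd, seed=seed
    )
    tables = synth.simulate_experiment(layout, truth, seed=seed + 1)
    matrix, _ = preprocess.preprocess_experiment(tables, layout)
    cond, _ = conditioning.condition_profiles(matrix, smooth=smooth)
    return truth, cond


@pytest.fixture(scope="session")
def noise_matrix():
    """2,000 flat white-noise profiles on the 12-point study grid."""
    rng = np.random.default_rng(1234)
    return pd.DataFrame(
        rng.standard_normal((2000, 12)),
        index=[f"p{i:05d}.1" for i in range(2000)],
        columns=np.arange(12) * 4.0,
    )
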