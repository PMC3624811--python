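import numpy as np
import pytest

from grnprior import (
    ConditionMeta,
    ExpressionDataset,
    random_network,
    simulate_dataset,
)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 conditions: one 2-step time series plus 2 steady states."""
    values = np.array([
        [1.0, 2.0, 1.5, 0.5],
        [0.5, 1.0, 2.0, 1.0],
        [2.0, 1.0, 0.5, 1.5],
    ])
    meta = [
        ConditionMeta("t0", is_time_series=True, is_first_in_series=True),
        ConditionMeta("t1", is_time_series=True, prev_condition="t0", delta_t=10.0),
        ConditionMeta("s0"),
        ConditionMeta("s1"),
    ]
    return ExpressionDataset(
        values=values,
        gene_ids=["g1", "g2", "g3"],
        condition_ids=["t0", "t1", "s0", "s1"],
        meta=meta,
        tf_ids=["g1", "g2"],
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulated dataset with known ground truth (session-cached)."""
    net = random_network(seed=7)
    dataset, gold, info = simulate_dataset(net, noise_sd=0.0, seed=107,
                                           return_info=True)
    return net, dataset, gold, info


@pytest.fixture(scope="session")
def noisy_sim():
    """Standard noisy simulated dataset (session-cached)."""
    net = random_network(seed=7)
    dataset, gold = simulate_dataset(net, noise_sd=0.1, seed=107)
    return net, dataset, gold
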