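import numpy as np
import pytest

from ventinv import surrogate, synthetic


@pytest.fixture(scope="session")
def clean_cohort():
    """600 noiseless, complete records from the ground-truth generator."""
    spec = synthetic.SyntheticCohortSpec(
        n_patients=20, records_per_patient=30, sigma=0.0,
        missing_fraction=0.0, seed=42, healthy_fraction=0.0,
    )
    observable, truth = synthetic.generate_cohort(spec)
    return observable, truth


@pytest.fixture(scope="session")
def trained_surrogate(clean_cohort):
    observable, _ = clean_cohort
    return surrogate.train_network(observable, seed=7)


@pytest.fixture(scope="session")
def linear_toy_model():
    """A purely linear, well-conditioned 8->7 surrogate (no hidden layers)."""
    rng = np.random.default_rng(3)
    w = rng.normal(size=(8, 7)) * 0.3
    b = rng.normal(size=7) * 0.1
    return surrogate.SurrogateModel(
        topology=(),
        weights=[w],
        biases=[b],
        input_bounds=surrogate.Bounds(np.zeros(8), np.ones(8) * 10.0),
        output_bounds=surrogate.Bounds(np.zeros(7), np.ones(7)),
        split_seed=0,
        total_error=0.0,
    )
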