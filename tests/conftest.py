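import numpy as np
import pytest

from popdecode.population import (
    InputPopulation,
    NeuronTuning,
    PopulationSpec,
    make_population,
    tuning_curve,
)


@pytest.fixture(scope="session")
def hom_pop():
    """Small homogeneous population with moderate correlations."""
    spec = PopulationSpec(n_neurons=64, kind="homogeneous",
                          max_correlation=0.25, n_stimuli=8, seed=42)
    return make_population(spec)


@pytest.fixture(scope="session")
def het_pop():
    """Small heterogeneous population with moderate correlations."""
    spec = PopulationSpec(n_neurons=64, kind="heterogeneous",
                          max_correlation=0.25, n_stimuli=8, seed=43)
    return make_population(spec)


@pytest.fixture()
def identity_cov_pop():
    """Hand-built 3-neuron population whose noise covariance is exactly I."""
    neurons = [NeuronTuning(0.0, 5.0, 4.0, p) for p in (-45.0, 0.0, 45.0)]
    spec = PopulationSpec(n_neurons=3, kind="homogeneous",
                          max_correlation=0.0, n_stimuli=4, seed=0)
    grid = spec.stimulus_grid
    mean_resp = np.column_stack([tuning_curve(n, grid) for n in neurons])
    return InputPopulation(
        neurons=neurons,
        mean_response_matrix=mean_resp,
        correlation_matrix=np.eye(3),
        covariance_matrix=np.eye(3),
        spec=spec,
    )
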