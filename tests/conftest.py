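import numpy as np
import pytest

import semnet as sn


@pytest.fixture(scope="session")
def cegs_baseline() -> sn.PathModel:
    return sn.build_baseline(population="cegs", covariance_variant="none")


@pytest.fixture(scope="session")
def dspr_baseline() -> sn.PathModel:
    return sn.build_baseline(population="dspr", covariance_variant="none")


@pytest.fixture(scope="session")
def chain_model() -> sn.PathModel:
    return sn.PathModel(genes=("x", "y", "z"), paths=(("x", "y"), ("y", "z")),
                        reporter="z")


@pytest.fixture(scope="session")
def cegs_data(cegs_baseline):
    """Large-sample data simulated from the CEGS baseline with known truth."""
    theta = sn.default_parameters(cegs_baseline)
    config = sn.SimulationConfig(model=cegs_baseline, parameters=theta,
                                 n=100_000, seed=20240101)
    data, truth = sn.generate_grn_dataset(config)
    return data, theta


@pytest.fixture(scope="session")
def cegs_moments(cegs_data):
    data, _ = cegs_data
    return sn.SampleMoments.from_data(data)


def random_dag_model(rng: np.random.Generator, n_genes: int, edge_prob: float = 0.35):
    """Random recursive PathModel with a reporter (for count/property tests)."""
    genes = tuple(f"g{i}" for i in range(n_genes))
    paths = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_prob:
                paths.append((genes[i], genes[j]))
    if not paths:  # ensure at least one endogenous gene for the reporter
        paths.append((genes[0], genes[-1]))
    reporter = paths[-1][1]
    return sn.PathModel(genes=genes, paths=tuple(paths), reporter=reporter)
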