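import numpy as np
import pytest

import polytome as pt


@pytest.fixture(scope="session")
def small_catalog() -> pt.GeneCatalog:
    return pt.generate_catalog(40, seed=7)


@pytest.fixture(scope="session")
def conditions() -> tuple[pt.ConditionParams, pt.ConditionParams]:
    return pt.optimal_condition(), pt.stress_condition()


@pytest.fixture(scope="session")
def small_truth(small_catalog, conditions) -> pt.SyntheticTruth:
    optimal, stress = conditions
    return pt.generate_truth(
        small_catalog, optimal, stress, seed=11, frac_silent=0.1
    )


@pytest.fixture(scope="session")
def zero_noise_tables(small_truth) -> list[pt.FractionIntensityTable]:
    return pt.simulate_arrays(small_truth, pt.NoiseModel.noiseless(seed=5), 3)


@pytest.fixture(scope="session")
def zero_noise_experiment(zero_noise_tables) -> pt.NormalizedExperiment:
    return pt.normalize_experiment(zero_noise_tables)


@pytest.fixture(scope="session")
def zero_noise_results(zero_noise_experiment, small_catalog, conditions):
    """Fitted translatome results per condition on the noiseless experiment."""
    optimal, stress = conditions
    out = {}
    for cond in (stress, optimal):
        model = pt.TranslatomeModel.from_experiment(
            zero_noise_experiment, cond, small_catalog, min_series=2
        )
        out[cond.name] = model.fit(n_iter=300, seed=13)
    return out
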