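import numpy as np
import pytest

from fuzzybase import (
    GeneratorConfig,
    TrainingConfig,
    fit_pipeline,
    make_training_files,
)


@pytest.fixture(scope="session")
def default_training_files():
    return make_training_files(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def trained_model(default_training_files):
    """Pipeline trained at default settings (500 epochs, seed 0); shared to
    keep the suite fast."""
    return fit_pipeline(default_training_files, TrainingConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_fis(rng, n_inputs, n_mfs, family=None, jitter=0.0):
    """A random grid-partitioned FIS used by oracle and property tests."""
    from fuzzybase import grid_partition, make_variable

    families = ("triangular", "trapezoidal", "gauss2")
    variables = []
    for j in range(n_inputs):
        fam = family or families[int(rng.integers(len(families)))]
        var = make_variable(f"x{j}", n_mfs=n_mfs, family=fam)
        if jitter:
            var.mfs = [
                mf.with_params(np.asarray(mf.params) + rng.normal(0, jitter, len(mf.params)))
                for mf in var.mfs
            ]
        variables.append(var)
    fis = grid_partition(variables)
    fis.consequents = rng.uniform(0.0, 1.0, fis.n_rules)
    return fis
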