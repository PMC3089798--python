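import numpy as np
import pytest

from ahrcross.dre import build_pwm
from ahrcross.expression import DifferentialExpressionModel
from ahrcross.simulate import (
    DRE_CONSENSUS_19MER,
    generate_chx_experiment,
    generate_dre_training_set,
    generate_experiment,
)


@pytest.fixture(scope="session")
def small_experiment():
    """Three species, two time points, planted categories at default effect size."""
    return generate_experiment(n_genes=80, times=(1.0, 4.0), seed=11)


@pytest.fixture(scope="session")
def de_results(small_experiment):
    table, sheet, _orth, _truth = small_experiment
    return DifferentialExpressionModel(table, sheet).fit()


@pytest.fixture(scope="session")
def chx_fixture():
    return generate_chx_experiment(n_genes=60, seed=5)


@pytest.fixture(scope="session")
def default_pwm():
    return build_pwm(generate_dre_training_set(DRE_CONSENSUS_19MER, 0.08, 200, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
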