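import numpy as np
import pytest

from forcediscrim.observer import (
    BlockSpec,
    ExperimentDesign,
    ObserverParams,
    default_population,
    make_design,
    simulate_participant,
)


@pytest.fixture(scope="session")
def exp1_design():
    return make_design("exp1")


@pytest.fixture(scope="session")
def exp1_population():
    return default_population("exp1")


def single_condition_design(n_trials: int, condition: str = "cond") -> ExperimentDesign:
    """A one-condition design for focused simulations."""
    return ExperimentDesign(
        experiment_id="exp1",
        conditions=(condition,),
        trials_per_condition={condition: n_trials},
        block_structure=(BlockSpec(condition, {condition: n_trials}),),
    )


@pytest.fixture(scope="session")
def clean_block():
    """7,000 clean trials from one logistic observer (pse 2.0, jnd 0.5)."""
    params = ObserverParams("obs", {"cond": (2.0, 0.5)})
    design = single_condition_design(7000, "cond")
    return simulate_participant(params, design, seed=11)


@pytest.fixture(scope="session")
def small_cohort(exp1_design, exp1_population):
    """A 8-participant exp1 cohort with no anomalies."""
    from forcediscrim.observer import simulate_cohort

    return simulate_cohort(8, exp1_design, exp1_population, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
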