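import numpy as np
import pytest

from pfcompare import (
    ConditionData,
    Dataset,
    ExperimentDesign,
    ModelSpec,
    ParamConstraint,
    PFParams,
    simulate_observer,
)

# The canonical two-condition Vernier-style design: five offsets, 50 trials
# each, guess and lapse rates 0.02, logistic shape.
LEVELS = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
TRIALS = 50
GUESS = LAPSE = 0.02


def fixed(v):
    return ParamConstraint.fixed(v)


def make_spec(alpha_mode, beta_mode, n_conditions=2, shape="logistic",
              alpha_fixed=0.0, beta_fixed=1.0):
    """Build a model from the 3x3 grid of location/slope constraint modes.

    Modes: 'u' (one free value per condition), 'c' (one shared free value),
    'f' (fixed). Guess and lapse rates are fixed at 0.02 throughout.
    """
    def con(mode, fixed_val):
        return {
            "u": ParamConstraint.unconstrained(),
            "c": ParamConstraint.constrained(),
            "f": ParamConstraint.fixed(fixed_val),
        }[mode]

    return ModelSpec(
        shape=shape,
        n_conditions=n_conditions,
        alpha=con(alpha_mode, alpha_fixed),
        beta=con(beta_mode, beta_fixed),
        gamma=fixed(GUESS),
        lambda_=fixed(LAPSE),
    )


GRID_MODES = [(a, b) for a in "ucf" for b in "ucf"]


def nested_grid_pairs():
    """All (fuller, lesser) mode pairs of the 3x3 grid with strict nesting."""
    rank = {"f": 0, "c": 1, "u": 2}
    pairs = []
    for fa, fb in GRID_MODES:
        for la, lb in GRID_MODES:
            if rank[la] <= rank[fa] and rank[lb] <= rank[fb] and (la, lb) != (fa, fb):
                pairs.append(((fa, fb), (la, lb)))
    return pairs


@pytest.fixture
def two_condition_design():
    return ExperimentDesign.uniform(LEVELS, TRIALS, n_conditions=2)


@pytest.fixture
def two_condition_data(two_condition_design):
    """Equal-slope data: the lesser model of the slope comparison is true."""
    truth = PFParams(0.0, 1.0, GUESS, LAPSE)
    return simulate_observer(two_condition_design, "logistic", truth, seed=20260928)


@pytest.fixture
def one_condition_data():
    truth = PFParams(0.0, 1.0, GUESS, LAPSE)
    design = ExperimentDesign.uniform(LEVELS, TRIALS, n_conditions=1)
    return simulate_observer(design, "logistic", truth, seed=11)


@pytest.fixture
def tiny_dataset():
    """Three hand-checkable cells: proportions 0.2, 0.5, 0.8."""
    return Dataset([ConditionData([-1.0, 0.0, 1.0], [10, 25, 40], [50, 50, 50])])
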