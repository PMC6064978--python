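"""Synthetic observer simulation.

Generates binomial response data with exactly the statistical structure the
models assume: every trial's outcome depends only on its stimulus level and
condition (independence), with constant response probabilities throughout
(stability). Cell counts are independent binomial draws with success
probability psi evaluated at the cell's level. Lapses are not a separate
response stream; they enter only through the upper asymptote 1 - lambda of
psi, consistent with the definition of the lapse rate as the probability of
a stimulus-independent negative response.

The default design mirrors a hypothetical Vernier-alignment experiment:
five stimulus offsets, 50 trials per offset, a logistic shape, and guess
and lapse rates of 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ConditionData, Dataset
from .exceptions import DomainError
from .shapes import PFParams, evaluate_pf

DEFAULT_LEVELS = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
DEFAULT_TRIALS = 50
DEFAULT_GUESS = 0.02
DEFAULT_LAPSE = 0.02


@dataclass
class ConditionDesign:
    """Stimulus levels and trials per level for one condition."""

    levels: np.ndarray
    trials: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, float)
        trials = np.asarray(self.trials, int)
        if trials.ndim == 0:
            trials = np.full(self.levels.shape, int(trials))
        self.trials = trials
        if self.trials.shape != self.levels.shape:
            raise DomainError("trials must be a scalar or match levels in length")
        if np.any(self.trials < 1):
            raise DomainError("every cell needs at least one trial")


@dataclass
class ExperimentDesign:
    """A list of per-condition designs."""

    conditions: list[ConditionDesign]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise DomainError("a design needs at least one condition")

    @classmethod
    def uniform(cls, levels=DEFAULT_LEVELS, trials=DEFAULT_TRIALS, n_conditions=1):
        """Same levels and trial counts in every condition."""
        return cls(
            [ConditionDesign(np.asarray(levels, float), trials) for _ in range(n_conditions)]
        )

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


def _as_param_list(generating_params, n_conditions: int) -> list[PFParams]:
    """Accept a list of PFParams, a single PFParams, or a (4, C) array."""
    if isinstance(generating_params, PFParams):
        return [generating_params] * n_conditions
    arr = np.asarray(generating_params, dtype=object)
    if arr.ndim == 1 and all(isinstance(p, PFParams) for p in generating_params):
        params = list(generating_params)
    else:
        native = np.asarray(generating_params, float)
        if native.shape != (4, n_conditions):
            raise DomainError(
                f"generating parameters must be (4, {n_conditions}) or PFParams"
            )
        params = [PFParams(*native[:, c]) for c in range(n_conditions)]
    if len(params) != n_conditions:
        raise DomainError("one parameter set per condition required")
    return params


def simulate_observer(
    design: ExperimentDesign,
    shape: str,
    generating_params,
    seed=None,
) -> Dataset:
    """Simulate a complete experiment from a generating psychometric function.

    Parameters
    ----------
    design : ExperimentDesign
        Stimulus levels and trial counts per condition.
    shape : str
        Sigmoid shape identifier.
    generating_params : PFParams, list of PFParams, or (4, C) array
        Native parameters per condition (rows alpha, beta, gamma, lambda
        for the array form). A single PFParams applies to all conditions.
    seed : int, numpy Generator, or None
        Randomness source; identical seeds give identical Datasets.

    Returns
    -------
    Dataset
        One binomial draw k ~ Bin(n, psi(level)) per cell.
    """
    rng = np.random.default_rng(seed)
    params = _as_param_list(generating_params, design.n_conditions)
    conditions = []
    for cond, p in zip(design.conditions, params):
        psi = evaluate_pf(shape, p, cond.levels)
        k = rng.binomial(cond.trials, psi)
        conditions.append(ConditionData(cond.levels.copy(), k, cond.trials.copy()))
    return Dataset(conditions)


def learning_curve_alphas(n_sessions: int, theta) -> np.ndarray:
    """Per-session locations alpha_s = theta1 + theta2 * exp(-theta3 (s-1))."""
    asymptote, amplitude, rate = (float(t) for t in theta)
    if rate < 0:
        raise DomainError(f"learning rate must be >= 0, got {rate}")
    s = np.arange(1, n_sessions + 1, dtype=float)
    return asymptote + amplitude * np.exp(-rate * (s - 1.0))


def make_learning_fixture(
    n_sessions: int,
    theta,
    levels=DEFAULT_LEVELS,
    trials=DEFAULT_TRIALS,
    beta: float = 1.0,
    gamma: float = DEFAULT_GUESS,
    lambda_: float = DEFAULT_LAPSE,
    shape: str = "logistic",
    seed=None,
):
    """Simulate a multi-session experiment whose locations follow a learning curve.

    Session s (one condition per session) gets location
    ``alpha_s = theta1 + theta2 * exp(-theta3 * (s - 1))``; slopes and the
    guess/lapse rates are shared across sessions. Returns the Dataset and
    the ground-truth per-session locations, for parameter-recovery tests of
    the matching custom constraint.
    """
    if n_sessions < 2:
        raise DomainError("a learning curve needs at least two sessions")
    alphas = learning_curve_alphas(n_sessions, theta)
    design = ExperimentDesign.uniform(levels, trials, n_conditions=n_sessions)
    params = [PFParams(a, beta, gamma, lambda_) for a in alphas]
    data = simulate_observer(design, shape, params, seed=seed)
    return data, alphas
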