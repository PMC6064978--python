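"""Psychometric-function shapes.

The psychometric function maps stimulus intensity ``x`` to the probability of
a "positive" response,

    psi(x; alpha, beta, gamma, lambda) = gamma + (1 - gamma - lambda) * F(x; alpha, beta)

where ``F`` is a sigmoid parameterized by a location ``alpha`` and a rate
(slope) ``beta``, ``gamma`` is the guess rate (lower asymptote) and
``lambda`` the lapse rate (the upper asymptote sits at ``1 - lambda``).

Four standard sigmoid families are provided:

``logistic``
    F = 1 / (1 + exp(-beta (x - alpha)));  alpha is the 0.5-point, beta the
    logistic rate.
``cumulative_normal``
    F = Phi(beta (x - alpha));  beta is the reciprocal of the Gaussian
    standard deviation.
``weibull``
    F = 1 - exp(-(x / alpha)^beta);  defined for x > 0, alpha > 0.
``gumbel``
    F = 1 - exp(-10^(beta (x - alpha)));  the log-Weibull, i.e. a Weibull on
    log10-transformed stimulus values.

All evaluators clip F to [1e-12, 1 - 1e-12] so downstream binomial
log-likelihoods stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DomainError

SHAPES = ("logistic", "cumulative_normal", "weibull", "gumbel")

_F_EPS = 1e-12


def _validate_shape(shape: str) -> str:
    if shape not in SHAPES:
        raise ConfigurationError(
            f"unknown sigmoid shape {shape!r}; expected one of {SHAPES}"
        )
    return shape


@dataclass(frozen=True)
class PFParams:
    """The four native parameters of one psychometric function.

    Attributes
    ----------
    alpha : float
        Location, in stimulus units (threshold / point of subjective
        equality).
    beta : float
        Slope (rate), in 1 / stimulus units. Must be positive for a
        well-formed increasing function; non-positive values are tolerated
        internally during optimization.
    gamma : float
        Guess rate, the lower asymptote of psi.
    lambda_ : float
        Lapse rate; the upper asymptote of psi is ``1 - lambda_``.
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    lambda_: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise DomainError(f"gamma must lie in [0, 1], got {self.gamma}")
        if not (0.0 <= self.lambda_ <= 1.0):
            raise DomainError(f"lambda must lie in [0, 1], got {self.lambda_}")
        if self.gamma + self.lambda_ >= 1.0:
            raise DomainError(
                f"gamma + lambda must be < 1, got {self.gamma + self.lambda_}"
            )


def evaluate_sigmoid(shape: str, alpha: float, beta: float, x):
    """Evaluate the base sigmoid F(x; alpha, beta) in (0, 1).

    Parameters
    ----------
    shape : str
        One of :data:`SHAPES`.
    alpha, beta : float
        Location and rate.
    x : float or array_like
        Stimulus intensity. For the Weibull, x must be strictly positive.

    Returns
    -------
    float or ndarray
        F clipped to [1e-12, 1 - 1e-12]; scalar in, scalar out.
    """
    _validate_shape(shape)
    xs = np.asarray(x, dtype=float)
    scalar = xs.ndim == 0
    xs = np.atleast_1d(xs)

    # Overflow in the inner power/exponential saturates F at an asymptote,
    # which the clip below makes exact; silence the spurious warning.
    with np.errstate(over="ignore"):
        if shape == "logistic":
            F = 1.0 / (1.0 + np.exp(-beta * (xs - alpha)))
        elif shape == "cumulative_normal":
            F = stats.norm.cdf(beta * (xs - alpha))
        elif shape == "weibull":
            if alpha <= 0:
                raise DomainError(f"weibull requires alpha > 0, got {alpha}")
            if np.any(xs <= 0):
                raise DomainError("weibull is defined only for stimulus values x > 0")
            F = 1.0 - np.exp(-((xs / alpha) ** beta))
        else:  # gumbel
            F = 1.0 - np.exp(-(10.0 ** (beta * (xs - alpha))))

    F = np.clip(F, _F_EPS, 1.0 - _F_EPS)
    return float(F[0]) if scalar else F


def evaluate_pf(shape: str, params: PFParams, x):
    """Evaluate psi(x) = gamma + (1 - gamma - lambda) F(x; alpha, beta)."""
    F = evaluate_sigmoid(shape, params.alpha, params.beta, x)
    return params.gamma + (1.0 - params.gamma - params.lambda_) * F


def _psi(shape: str, alpha, beta, gamma, lambda_, x):
    """Raw psi without PFParams validation; used by the fitting hot loop.

    Does not check the gamma/lambda invariants because optimizers may probe
    mildly invalid values in transformed space; clipping of F keeps the
    result usable.
    """
    F = evaluate_sigmoid(shape, alpha, beta, x)
    return gamma + (1.0 - gamma - lambda_) * F


def inverse_sigmoid(shape: str, alpha: float, beta: float, q: float) -> float:
    """Return x with F(x; alpha, beta) = q, for q in (0, 1)."""
    _validate_shape(shape)
    if not (0.0 < q < 1.0):
        raise DomainError(f"base-sigmoid probability must lie in (0, 1), got {q}")
    if shape == "logistic":
        return alpha + np.log(q / (1.0 - q)) / beta
    if shape == "cumulative_normal":
        return alpha + stats.norm.ppf(q) / beta
    if shape == "weibull":
        if alpha <= 0:
            raise DomainError(f"weibull requires alpha > 0, got {alpha}")
        return alpha * (-np.log1p(-q)) ** (1.0 / beta)
    # gumbel
    return alpha + np.log10(-np.log1p(-q)) / beta


def inverse_pf(shape: str, params: PFParams, p: float) -> float:
    """Invert the full psychometric function: return x with psi(x) = p.

    ``p`` must lie strictly between the asymptotes gamma and 1 - lambda.
    Useful for reading a threshold off a fitted function (e.g. the stimulus
    level at which the observer responds positively 75% of the time).
    """
    lo, hi = params.gamma, 1.0 - params.lambda_
    if not (lo < p < hi):
        raise DomainError(
            f"probability {p} outside the open asymptote interval ({lo}, {hi})"
        )
    q = (p - params.gamma) / (1.0 - params.gamma - params.lambda_)
    return float(inverse_sigmoid(shape, params.alpha, params.beta, q))
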