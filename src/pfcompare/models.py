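"""Cross-condition model specifications.

A :class:`ModelSpec` states, for each of the four psychometric-function
parameters (location alpha, slope beta, guess rate gamma, lapse rate
lambda), how that parameter may vary across the C experimental conditions.
Five constraint modes are supported:

``fixed``
    The parameter is not estimated; per-condition values are supplied.
``constrained``
    One free value shared by all conditions.
``unconstrained``
    One free value per condition.
``matrix``
    An M x C model matrix reparameterizes the C native values into M
    "effect" parameters theta (intercepts, trends, differences, ...).
    The engine reconstructs natives as ``native = M.T @ theta``; rows must
    be linearly independent. With the classic sum/difference matrix
    [[1, 1], [1, -1]] for two conditions, theta = (2, 1) yields slopes
    (3, 1). Because the rows are not unit-normalized, theta differs from
    the row-wise linear combinations of the natives by the per-row scaling
    ``M @ M.T`` (factor 2 for [1, 1] with C = 2); the fitted native
    parameters and likelihoods are unaffected by this convention.
``custom``
    An arbitrary mapping from a theta subvector to C native values, with a
    boolean mask saying which theta entries are estimated. The classic use
    case is a learning curve: locations over S sessions following
    ``alpha_s = theta1 + theta2 * exp(-theta3 * (s - 1))``.

Free parameters are counted per constraint: 0 (fixed), 1 (constrained),
C (unconstrained), M (matrix), or the number of free theta entries
(custom). Differences of these counts are the degrees of freedom of
nested-model likelihood-ratio tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError, DomainError, SpecificationError
from .shapes import SHAPES, _validate_shape

CONSTRAINT_MODES = ("fixed", "constrained", "unconstrained", "matrix", "custom")

PARAM_NAMES = ("alpha", "beta", "gamma", "lambda")


@dataclass
class ParamConstraint:
    """How one PF parameter varies across conditions.

    Construct via the classmethods :meth:`fixed`, :meth:`constrained`,
    :meth:`unconstrained`, :meth:`from_matrix`, :meth:`custom` rather than
    directly.
    """

    mode: str
    fixed_values: Optional[np.ndarray] = None
    matrix: Optional[np.ndarray] = None
    custom_map: Optional[Callable[[np.ndarray], np.ndarray]] = None
    theta_init: Optional[np.ndarray] = None
    theta_free: Optional[np.ndarray] = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def fixed(cls, values) -> "ParamConstraint":
        """Fix the parameter at the given value(s); a scalar broadcasts."""
        return cls(mode="fixed", fixed_values=np.atleast_1d(np.asarray(values, float)))

    @classmethod
    def constrained(cls) -> "ParamConstraint":
        """One shared free value across all conditions."""
        return cls(mode="constrained")

    @classmethod
    def unconstrained(cls) -> "ParamConstraint":
        """An independent free value in every condition."""
        return cls(mode="unconstrained")

    @classmethod
    def from_matrix(cls, rows) -> "ParamConstraint":
        """Model-matrix reparameterization; natives are ``rows.T @ theta``."""
        M = np.atleast_2d(np.asarray(rows, float))
        if np.linalg.matrix_rank(M) < M.shape[0]:
            raise SpecificationError("model-matrix rows must be linearly independent")
        return cls(mode="matrix", matrix=M)

    @classmethod
    def custom(cls, custom_map, theta_init, theta_free=None) -> "ParamConstraint":
        """Arbitrary theta -> per-condition mapping.

        Parameters
        ----------
        custom_map : callable
            Maps the full theta subvector (free and fixed entries) to C
            native values.
        theta_init : sequence of float
            Starting values; fixed entries keep these values.
        theta_free : sequence of bool, optional
            Which entries are estimated (default: all).
        """
        init = np.asarray(theta_init, float)
        free = (
            np.ones(init.shape, bool)
            if theta_free is None
            else np.asarray(theta_free, bool)
        )
        if init.shape != free.shape:
            raise SpecificationError(
                "theta_init and theta_free must have equal length"
            )
        return cls(mode="custom", custom_map=custom_map, theta_init=init, theta_free=free)

    # -- behaviour --------------------------------------------------------
    def validate(self, n_conditions: int) -> None:
        if self.mode not in CONSTRAINT_MODES:
            raise ConfigurationError(f"unknown constraint mode {self.mode!r}")
        if self.mode == "fixed":
            nv = len(self.fixed_values)
            if nv not in (1, n_conditions):
                raise SpecificationError(
                    f"fixed values have length {nv}; expected 1 or {n_conditions}"
                )
        elif self.mode == "matrix":
            if self.matrix.shape[1] != n_conditions:
                raise SpecificationError(
                    f"model matrix has {self.matrix.shape[1]} columns; "
                    f"expected {n_conditions}"
                )
            if self.matrix.shape[0] > n_conditions:
                raise SpecificationError("model matrix has more rows than conditions")
        elif self.mode == "custom":
            out = np.asarray(self.custom_map(self.theta_init), float)
            if out.shape != (n_conditions,) or not np.all(np.isfinite(out)):
                raise SpecificationError(
                    "custom map must return exactly "
                    f"{n_conditions} finite values on theta_init"
                )

    def n_free(self, n_conditions: int) -> int:
        """Number of free parameters this constraint contributes."""
        if self.mode == "fixed":
            return 0
        if self.mode == "constrained":
            return 1
        if self.mode == "unconstrained":
            return n_conditions
        if self.mode == "matrix":
            return self.matrix.shape[0]
        return int(np.sum(self.theta_free))

    def expand(self, theta_free: np.ndarray, n_conditions: int) -> np.ndarray:
        """Map this constraint's free theta entries to C native values."""
        k = self.n_free(n_conditions)
        theta_free = np.asarray(theta_free, float)
        if theta_free.shape != (k,):
            raise SpecificationError(
                f"theta subvector has length {theta_free.shape}, expected ({k},)"
            )
        if self.mode == "fixed":
            return np.broadcast_to(self.fixed_values, (n_conditions,)).astype(float)
        if self.mode == "constrained":
            return np.full(n_conditions, theta_free[0])
        if self.mode == "unconstrained":
            return theta_free.copy()
        if self.mode == "matrix":
            return self.matrix.T @ theta_free
        theta_full = self.theta_init.copy()
        theta_full[self.theta_free] = theta_free
        out = np.asarray(self.custom_map(theta_full), float)
        if out.shape != (n_conditions,):
            raise SpecificationError(
                f"custom map returned {out.shape}, expected ({n_conditions},)"
            )
        if not np.all(np.isfinite(out)):
            raise SpecificationError("custom map returned non-finite values")
        return out


@dataclass
class ModelSpec:
    """A complete model: one sigmoid shape plus four parameter constraints."""

    shape: str
    n_conditions: int
    alpha: ParamConstraint
    beta: ParamConstraint
    gamma: ParamConstraint = field(default_factory=lambda: ParamConstraint.fixed(0.0))
    lambda_: ParamConstraint = field(default_factory=lambda: ParamConstraint.fixed(0.0))

    def __post_init__(self) -> None:
        _validate_shape(self.shape)
        if self.n_conditions < 1:
            raise SpecificationError("n_conditions must be >= 1")
        for c in self.constraints():
            c.validate(self.n_conditions)

    def constraints(self) -> tuple:
        return (self.alpha, self.beta, self.gamma, self.lambda_)


def count_free_params(spec: ModelSpec) -> int:
    """Total free parameters of a model; the basis of test degrees of freedom."""
    return sum(c.n_free(spec.n_conditions) for c in spec.constraints())


def theta_slices(spec: ModelSpec) -> list[slice]:
    """Slices of the packed theta vector belonging to alpha, beta, gamma, lambda."""
    out, start = [], 0
    for c in spec.constraints():
        k = c.n_free(spec.n_conditions)
        out.append(slice(start, start + k))
        start += k
    return out


def expand_parameters(spec: ModelSpec, theta) -> np.ndarray:
    """Map the packed free-parameter vector to native parameters.

    Returns a (4, C) array with rows alpha, beta, gamma, lambda.
    """
    theta = np.asarray(theta, float)
    k = count_free_params(spec)
    if theta.shape != (k,):
        raise SpecificationError(
            f"theta has shape {theta.shape}; model has {k} free parameters"
        )
    C = spec.n_conditions
    rows = [
        c.expand(theta[s], C)
        for c, s in zip(spec.constraints(), theta_slices(spec))
    ]
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Custom-map registry (named families usable from config files; arbitrary
# callables are accepted only through the programmatic API so that data
# files never trigger code execution).
# ---------------------------------------------------------------------------

def exp_decay_learning(n_sessions: int) -> Callable[[np.ndarray], np.ndarray]:
    """Exponential-decay learning curve over consecutive sessions.

    theta = (asymptote, amplitude, rate) maps to per-session locations
    ``alpha_s = asymptote + amplitude * exp(-rate * (s - 1))`` for sessions
    s = 1..n_sessions, so alpha_1 = asymptote + amplitude and alpha_s tends
    to the asymptote as practice accumulates.
    """
    sessions = np.arange(1, n_sessions + 1, dtype=float)

    def _map(theta: np.ndarray) -> np.ndarray:
        a, b, r = theta
        return a + b * np.exp(-r * (sessions - 1.0))

    return _map


CUSTOM_FAMILIES: dict[str, Callable[..., Callable]] = {
    "exp_decay_learning": exp_decay_learning,
}


# ---------------------------------------------------------------------------
# Contrast matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastMatrix:
    """A full n x n contrast set; the intercept row of ones comes first.

    Sub-selecting rows yields trend-analysis model matrices, e.g. rows 1-2
    of the polynomial set for n = 4, [[1, 1, 1, 1], [-3, -1, 1, 3]],
    constrain four locations to a straight line in condition index.
    """

    kind: str
    n: int
    rows: np.ndarray

    def select(self, indices: Sequence[int]) -> np.ndarray:
        return self.rows[list(indices)]


def _polynomial_rows(n: int) -> np.ndarray:
    # Exact Gram-Schmidt over the rationals on the symmetric integer grid
    # 2j - (n - 1), then rescaling to the smallest integer representatives,
    # reproduces the classic orthogonal-polynomial contrast tables.
    x = [Fraction(2 * j - (n - 1)) for j in range(n)]
    basis: list[list[Fraction]] = []
    for d in range(n):
        v = [xi**d for xi in x]
        for b in basis:
            num = sum(vi * bi for vi, bi in zip(v, b))
            den = sum(bi * bi for bi in b)
            c = num / den
            v = [vi - c * bi for vi, bi in zip(v, b)]
        basis.append(v)
    rows = []
    for v in basis:
        lcm = math.lcm(*(f.denominator for f in v))
        ints = [int(f * lcm) for f in v]
        g = math.gcd(*(abs(i) for i in ints if i != 0))
        rows.append([i // g for i in ints])
    return np.asarray(rows, float)


def _helmert_rows(n: int) -> np.ndarray:
    rows = [np.ones(n)]
    for i in range(n - 1):
        r = np.zeros(n)
        r[i] = n - 1 - i
        r[i + 1 :] = -1.0
        rows.append(r)
    return np.vstack(rows)


def _periodic_rows(n: int) -> np.ndarray:
    rows = [np.ones(n)]
    t = np.arange(n)
    for f in range(1, n // 2 + 1):
        rows.append(np.cos(2.0 * np.pi * f * t / n))
        if 2 * f != n:  # the Nyquist sine row is identically zero
            rows.append(np.sin(2.0 * np.pi * f * t / n))
    M = np.vstack(rows[:n])
    M[np.abs(M) < 1e-12] = 0.0
    return M


def generate_contrasts(n: int, kind: str) -> ContrastMatrix:
    """Generate the full contrast set of the requested kind.

    Parameters
    ----------
    n : int
        Number of conditions (>= 2).
    kind : {"polynomial", "helmert", "periodic"}
        Contrast family. Polynomial rows beyond the intercept encode
        linear, quadratic, ... trends; Helmert rows compare each condition
        with the mean of those following it; periodic rows are sampled
        sine/cosine pairs.

    Returns
    -------
    ContrastMatrix
        n rows, intercept first. For polynomial and Helmert the
        non-intercept rows are mutually orthogonal and each sums to zero.
    """
    if n < 2:
        raise DomainError(f"contrasts require n >= 2 conditions, got {n}")
    builders = {
        "polynomial": _polynomial_rows,
        "helmert": _helmert_rows,
        "periodic": _periodic_rows,
    }
    if kind not in builders:
        raise ConfigurationError(
            f"unknown contrast kind {kind!r}; expected one of {sorted(builders)}"
        )
    return ContrastMatrix(kind=kind, n=n, rows=builders[kind](n))
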