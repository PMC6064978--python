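"""Maximum-likelihood fitting of psychometric-function models.

The likelihood of a model is the probability of reproducing the observed
response counts cell by cell: for a cell with n trials, k positive
responses and model probability psi, the contribution is
``k log psi + (n - k) log(1 - psi)``. Binomial coefficients are omitted:
they cancel in every likelihood ratio and shift the AIC of all models on
the same data by the same constant, so reported log-likelihoods are
comparable only within a dataset.

Optimization is a derivative-free Nelder-Mead simplex search with
multi-start: the first start comes from data-driven heuristics (location
from the level nearest the mid-proportion, slope from the stimulus range),
further starts jitter it. Positivity of the slope is enforced by searching
on a log scale, and free guess/lapse rates are searched on a logit scale —
but only for the ``constrained``/``unconstrained`` modes, where one search
coordinate is one native value; ``matrix`` and ``custom`` thetas live in
their own linear effect space and are searched untransformed.

The saturated model — one free probability per cell, estimated by the
observed proportion k/n — has a closed form and anchors goodness-of-fit
tests: its log-likelihood bounds that of every model making the same
independence and stability assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import expit, logit, xlogy

from .data import ConditionData, Dataset
from .exceptions import PFCompareError, SpecificationError
from .models import ModelSpec, count_free_params, expand_parameters, theta_slices
from .shapes import evaluate_sigmoid

_LL_PENALTY = 1e15


@dataclass
class FitOptions:
    """Optimizer settings.

    Attributes
    ----------
    max_iterations : int
        Simplex iteration cap per restart.
    tolerance : float
        Convergence threshold on both the log-likelihood and theta.
    n_restarts : int
        Number of starts; the first is the heuristic initialization, the
        rest jitter it. The best restart is returned regardless of
        convergence.
    init_strategy : str
        "heuristic" (default) or "spec" (custom theta_init only, no
        data-driven start).
    seed : int or None
        Seed for the jitter; None draws OS entropy.
    """

    max_iterations: int = 5000
    tolerance: float = 1e-8
    n_restarts: int = 4
    init_strategy: str = "heuristic"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise SpecificationError("tolerance must be positive")
        if self.n_restarts < 1:
            raise SpecificationError("n_restarts must be >= 1")


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    theta_hat: np.ndarray
    native_params: Optional[np.ndarray]  # (4, C); None for the saturated model
    log_likelihood: float
    k_free: int
    converged: bool
    n_restarts_used: int = 1
    warnings: list[str] = field(default_factory=list)
    cell_probs: Optional[list[np.ndarray]] = None  # saturated model only


def log_likelihood(data: Dataset, native_params, shape: str) -> float:
    """Binomial log-likelihood of native parameters on a dataset.

    ``native_params`` is a (4, C) array (rows alpha, beta, gamma, lambda).
    Returns -inf if any cell probability is numerically degenerate against
    its counts.
    """
    native = np.asarray(native_params, float)
    if native.shape != (4, data.n_conditions):
        raise SpecificationError(
            f"native parameters have shape {native.shape}; "
            f"expected (4, {data.n_conditions})"
        )
    total = 0.0
    for c, cond in enumerate(data.conditions):
        a, b, g, l = native[:, c]
        F = evaluate_sigmoid(shape, a, b, cond.levels)
        psi = g + (1.0 - g - l) * F
        if np.any(psi <= 0.0) or np.any(psi >= 1.0):
            return -np.inf
        total += float(cond.k @ np.log(psi) + (cond.n - cond.k) @ np.log1p(-psi))
    return total if np.isfinite(total) else -np.inf


# ---------------------------------------------------------------------------
# Search-space transforms
# ---------------------------------------------------------------------------

def _transform_kinds(spec: ModelSpec) -> list[str]:
    """Per-parameter transform: 'log', 'logit' or 'id' for the packed theta."""
    kinds = []
    per_native = ("constrained", "unconstrained")
    for name, con in zip(("alpha", "beta", "gamma", "lambda"), spec.constraints()):
        if con.mode not in per_native:
            kinds.append("id")
        elif name == "beta":
            kinds.append("log")
        elif name == "alpha":
            # Weibull locations must stay positive; elsewhere alpha is free.
            kinds.append("log" if spec.shape == "weibull" else "id")
        else:
            kinds.append("logit")
    return kinds


def _to_search(theta_nat: np.ndarray, kind: str) -> np.ndarray:
    if kind == "log":
        return np.log(np.maximum(theta_nat, 1e-10))
    if kind == "logit":
        return logit(np.clip(theta_nat, 1e-6, 1.0 - 1e-6))
    return np.asarray(theta_nat, float)


def _to_natural(theta_search: np.ndarray, kind: str) -> np.ndarray:
    if kind == "log":
        return np.exp(theta_search)
    if kind == "logit":
        return expit(theta_search)
    return np.asarray(theta_search, float)


def _search_to_natural(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    for s, kind in zip(theta_slices(spec), _transform_kinds(spec)):
        out[s] = _to_natural(x[s], kind)
    return out


def _natural_to_search(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    out = np.empty_like(theta)
    for s, kind in zip(theta_slices(spec), _transform_kinds(spec)):
        out[s] = _to_search(theta[s], kind)
    return out


# ---------------------------------------------------------------------------
# Initialization heuristics
# ---------------------------------------------------------------------------

def _condition_heuristics(cond: ConditionData, shape: str) -> tuple[float, float, float, float]:
    p = cond.proportions
    pmin, pmax = float(p.min()), float(p.max())
    mid = 0.5 * (pmin + pmax)
    alpha0 = float(cond.levels[np.argmin(np.abs(p - mid))])
    span = float(cond.levels.max() - cond.levels.min())
    if shape == "weibull":
        beta0 = 2.0
        if alpha0 <= 0:
            alpha0 = float(np.min(cond.levels[cond.levels > 0], initial=1.0))
    else:
        beta0 = 2.0 / span if span > 0 else 1.0
    gamma0 = float(np.clip(pmin, 0.01, 0.4))
    lambda0 = float(np.clip(1.0 - pmax, 0.01, 0.4))
    return alpha0, beta0, gamma0, lambda0


def _initial_theta(spec: ModelSpec, data: Dataset) -> np.ndarray:
    """Natural-scale packed theta start from per-condition heuristics."""
    C = spec.n_conditions
    heur = np.array(
        [_condition_heuristics(cond, spec.shape) for cond in data.conditions]
    ).T  # (4, C)
    pieces = []
    for i, con in enumerate(spec.constraints()):
        h = heur[i]
        if con.mode == "fixed":
            continue
        if con.mode == "constrained":
            pieces.append([float(np.mean(h))])
        elif con.mode == "unconstrained":
            pieces.append(h.tolist())
        elif con.mode == "matrix":
            theta0, *_ = np.linalg.lstsq(con.matrix.T, h, rcond=None)
            pieces.append(theta0.tolist())
        else:  # custom
            pieces.append(con.theta_init[con.theta_free].tolist())
    return np.concatenate(pieces) if pieces else np.empty(0)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_model(data: Dataset, spec: ModelSpec, options: Optional[FitOptions] = None) -> FitResult:
    """Maximize the binomial likelihood of a model over its free parameters.

    Multi-start Nelder-Mead on the transformed search space; the best
    restart is returned even when no restart formally converged
    (``converged`` is then False).
    """
    options = options or FitOptions()
    if spec.n_conditions != data.n_conditions:
        raise SpecificationError(
            f"model has {spec.n_conditions} conditions, data has {data.n_conditions}"
        )
    warnings = [
        f"condition {i} is degenerate (all responses identical)"
        for i in data.degenerate_conditions()
    ]
    k = count_free_params(spec)

    if k == 0:
        native = expand_parameters(spec, np.empty(0))
        return FitResult(
            theta_hat=np.empty(0),
            native_params=native,
            log_likelihood=log_likelihood(data, native, spec.shape),
            k_free=0,
            converged=True,
            n_restarts_used=0,
            warnings=warnings,
        )

    def neg_ll(x: np.ndarray) -> float:
        try:
            theta = _search_to_natural(spec, x)
            ll = log_likelihood(data, expand_parameters(spec, theta), spec.shape)
        except PFCompareError:
            return _LL_PENALTY
        return -ll if np.isfinite(ll) else _LL_PENALTY

    if options.init_strategy == "spec":
        theta0_nat = np.concatenate(
            [
                con.theta_init[con.theta_free]
                if con.mode == "custom"
                else np.zeros(con.n_free(spec.n_conditions))
                for con in spec.constraints()
            ]
        )
    else:
        theta0_nat = _initial_theta(spec, data)
    x0 = _natural_to_search(spec, theta0_nat)

    rng = np.random.default_rng(options.seed)
    best = None
    for r in range(options.n_restarts):
        start = x0 if r == 0 else x0 + rng.normal(0.0, 0.25 * (np.abs(x0) + 0.5))
        res = optimize.minimize(
            neg_ll,
            start,
            method="Nelder-Mead",
            options={
                "xatol": options.tolerance,
                "fatol": options.tolerance,
                "maxiter": options.max_iterations,
                "maxfev": 4 * options.max_iterations,
            },
        )
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = _search_to_natural(spec, np.asarray(best.x, float))
    native = expand_parameters(spec, theta_hat)
    ll = log_likelihood(data, native, spec.shape)
    if np.any(native[1] <= 0):
        warnings.append("fitted slope is non-positive in at least one condition")
    return FitResult(
        theta_hat=theta_hat,
        native_params=native,
        log_likelihood=ll,
        k_free=k,
        converged=bool(best.success),
        n_restarts_used=options.n_restarts,
        warnings=warnings,
    )


def fit_saturated(data: Dataset) -> FitResult:
    """Fit the saturated model: one free probability per cell, equal to k/n.

    The log-likelihood uses the 0 log 0 := 0 convention, so cells with
    k = 0 or k = n contribute zero. Always converged (closed form). The
    free-parameter count equals the total number of cells.
    """
    probs = [cond.proportions for cond in data.conditions]
    ll = 0.0
    for cond, p in zip(data.conditions, probs):
        ll += float(np.sum(xlogy(cond.k, p) + xlogy(cond.n - cond.k, 1.0 - p)))
    return FitResult(
        theta_hat=np.concatenate(probs),
        native_params=None,
        log_likelihood=ll,
        k_free=data.n_cells,
        converged=True,
        n_restarts_used=0,
        cell_probs=probs,
    )


# ---------------------------------------------------------------------------
# Bootstrap standard errors
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Standard errors of fitted parameters from bootstrap refits."""

    se_native: np.ndarray  # (4, C)
    se_theta: np.ndarray
    n_failed: int
    n_effective: int
    mode: str


def bootstrap_se(
    data: Dataset,
    spec: ModelSpec,
    B: int,
    mode: str = "parametric",
    options: Optional[FitOptions] = None,
    seed=None,
) -> BootstrapResult:
    """Bootstrap standard errors of the fitted parameters.

    ``parametric`` simulates B datasets from the fitted model on the
    observed design and refits each; ``nonparametric`` resamples each
    cell's count binomially from its observed proportion. Failed refits
    are dropped and counted; more than 50% failures raises an error — the
    usual cause is a model with more parameters than the data can support.
    """
    if B < 2:
        raise SpecificationError("bootstrap needs B >= 2 replicates")
    if mode not in ("parametric", "nonparametric"):
        raise SpecificationError(f"unknown bootstrap mode {mode!r}")
    options = options or FitOptions()
    base = fit_model(data, spec, options)
    if base.k_free == 0:
        zeros = np.zeros((4, data.n_conditions))
        return BootstrapResult(zeros, np.empty(0), 0, B, mode)

    rng = np.random.default_rng(seed)
    natives, thetas, n_failed = [], [], 0
    for _ in range(B):
        conds = []
        for c, cond in enumerate(data.conditions):
            if mode == "parametric":
                a, b, g, l = base.native_params[:, c]
                F = evaluate_sigmoid(spec.shape, a, b, cond.levels)
                psi = g + (1.0 - g - l) * F
            else:
                psi = cond.proportions
            k_sim = rng.binomial(cond.n, psi)
            conds.append(ConditionData(cond.levels.copy(), k_sim, cond.n.copy()))
        sim = Dataset(conds)
        try:
            refit = fit_model(sim, spec, options)
        except PFCompareError:
            n_failed += 1
            continue
        if not (refit.converged and np.isfinite(refit.log_likelihood)):
            n_failed += 1
            continue
        natives.append(refit.native_params)
        thetas.append(refit.theta_hat)

    if n_failed > B // 2:
        raise PFCompareError(
            f"{n_failed}/{B} bootstrap refits failed; the model likely has "
            "more parameters than the data can support — simplify it"
        )
    return BootstrapResult(
        se_native=np.std(np.stack(natives), axis=0, ddof=1),
        se_theta=np.std(np.stack(thetas), axis=0, ddof=1),
        n_failed=n_failed,
        n_effective=B - n_failed,
        mode=mode,
    )
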