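"""Model comparison: likelihood-ratio tests, goodness-of-fit, AIC.

Two nested models are compared via the transformed likelihood ratio

    TLR = -2 log(L_lesser / L_fuller) = -2 (LL_lesser - LL_fuller),

which, when the lesser model is true, is asymptotically chi-square
distributed with degrees of freedom equal to the difference in free
parameters. Because the asymptotics can be unreliable for small numbers of
trials, an empirical reference distribution is also available: simulate
datasets from the fitted lesser model, refit both models to each, and take
the upper-tail proportion of simulated TLRs at or beyond the observed one
as the Monte Carlo p-value.

A goodness-of-fit test is the same comparison with the saturated model as
the fuller model: it tests every assumption of the target model except
independence and stability. Its Monte Carlo variant simulates from the
fitted target model (simulating from the saturated model would reproduce
the observed proportions in expectation and is degenerate).

The AIC, -2 LL + 2 k_free, trades fit against complexity and also applies
to non-nested models; for a nested fitted pair the identity
``AIC_lesser - AIC_fuller = TLR - 2 df`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import ConditionData, Dataset
from .exceptions import DomainError, PFCompareError, SpecificationError
from .fitting import FitOptions, FitResult, fit_model, fit_saturated
from .models import ModelSpec, count_free_params
from .shapes import evaluate_sigmoid

_TLR_CLIP = 1e-6


@dataclass
class ComparisonResult:
    """Outcome of one nested-model comparison."""

    tlr: float
    df: int
    p_chi2: float
    p_mc: Optional[float] = None
    tlr_samples: Optional[np.ndarray] = None
    n_mc: int = 0
    n_failed_fits: int = 0
    fuller: Optional[FitResult] = None
    lesser: Optional[FitResult] = None
    warnings: list[str] = field(default_factory=list)


def transformed_likelihood_ratio(ll_lesser: float, ll_fuller: float) -> float:
    """TLR = -2 (LL_lesser - LL_fuller), clipped to 0 for tiny negatives.

    A negative value within 1e-6 of zero is optimizer noise and is reported
    as 0; larger negatives (also clipped) indicate a non-nested pair or an
    optimization failure — :func:`compare_models` attaches a warning.
    """
    if not (np.isfinite(ll_lesser) and np.isfinite(ll_fuller)):
        raise DomainError("both log-likelihoods must be finite")
    tlr = -2.0 * (ll_lesser - ll_fuller)
    return max(tlr, 0.0)


def chi2_p_value(tlr: float, df: int) -> float:
    """Upper-tail chi-square probability of the TLR at df degrees of freedom."""
    if df < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got {df}")
    if tlr < 0:
        raise DomainError(f"TLR must be >= 0, got {tlr}")
    return float(stats.chi2.sf(tlr, df))


def _simulate_from_native(
    data: Dataset, native: np.ndarray, shape: str, rng: np.random.Generator
) -> Dataset:
    conds = []
    for c, cond in enumerate(data.conditions):
        a, b, g, l = native[:, c]
        F = evaluate_sigmoid(shape, a, b, cond.levels)
        psi = g + (1.0 - g - l) * F
        conds.append(
            ConditionData(cond.levels.copy(), rng.binomial(cond.n, psi), cond.n.copy())
        )
    return Dataset(conds)


def _mc_p_value(
    tlr_obs: float, samples: np.ndarray, n_valid: int, plus_one: bool
) -> float:
    hits = int(np.sum(samples >= tlr_obs))
    if plus_one:
        return (hits + 1) / (n_valid + 1)
    return hits / n_valid


def compare_models(
    data: Dataset,
    fuller: ModelSpec,
    lesser: ModelSpec,
    options: Optional[FitOptions] = None,
    n_mc: int = 0,
    seed=None,
    mc_plus_one: bool = False,
) -> ComparisonResult:
    """Likelihood-ratio comparison of a fuller against a nested lesser model.

    Nesting is asserted by the caller, as in standard practice; the engine
    verifies only that the fuller model has more free parameters and warns
    when the lesser model's maximized likelihood exceeds the fuller's by
    more than numerical tolerance (a sign of non-nesting or an optimizer
    failure).

    With ``n_mc > 0``, an empirical null distribution is built by
    simulating ``n_mc`` datasets from the fitted lesser model on the
    observed design and refitting both models to each; ``p_mc`` is the
    proportion of simulated TLRs at or beyond the observed TLR (ties count
    toward the tail; ``mc_plus_one`` switches to the (x+1)/(B+1)
    convention). Failed refits are dropped and counted, never retried.
    """
    options = options or FitOptions()
    if fuller.shape != lesser.shape:
        raise SpecificationError("models must share the sigmoid shape")
    if fuller.n_conditions != lesser.n_conditions:
        raise SpecificationError("models must share the number of conditions")
    k_fuller, k_lesser = count_free_params(fuller), count_free_params(lesser)
    if k_fuller <= k_lesser:
        raise SpecificationError(
            f"fuller model must have more free parameters "
            f"({k_fuller} vs {k_lesser})"
        )

    fit_fuller = fit_model(data, fuller, options)
    fit_lesser = fit_model(data, lesser, options)
    return _finish_comparison(
        data,
        fit_fuller,
        fit_lesser,
        refit_fuller=lambda d: fit_model(d, fuller, options),
        refit_lesser=lambda d: fit_model(d, lesser, options),
        sim_native=lambda: fit_lesser.native_params,
        shape=fuller.shape,
        df=k_fuller - k_lesser,
        n_mc=n_mc,
        seed=seed,
        mc_plus_one=mc_plus_one,
    )


def goodness_of_fit(
    data: Dataset,
    model: ModelSpec,
    options: Optional[FitOptions] = None,
    n_mc: int = 0,
    seed=None,
    mc_plus_one: bool = False,
) -> ComparisonResult:
    """Goodness-of-fit test: the model against the saturated model.

    The saturated model assigns each (condition, level) cell its observed
    proportion and has one free parameter per cell, so
    ``df = n_cells - k_model``. The Monte Carlo variant simulates from the
    fitted target model.
    """
    options = options or FitOptions()
    if model.n_conditions != data.n_conditions:
        raise SpecificationError("model and data disagree on the number of conditions")
    k_model = count_free_params(model)
    if k_model >= data.n_cells:
        raise SpecificationError(
            f"model has {k_model} free parameters but the data only "
            f"{data.n_cells} cells; nothing to test against the saturated model"
        )
    fit_target = fit_model(data, model, options)
    return _finish_comparison(
        data,
        fit_saturated(data),
        fit_target,
        refit_fuller=fit_saturated,
        refit_lesser=lambda d: fit_model(d, model, options),
        sim_native=lambda: fit_target.native_params,
        shape=model.shape,
        df=data.n_cells - k_model,
        n_mc=n_mc,
        seed=seed,
        mc_plus_one=mc_plus_one,
    )


def _finish_comparison(
    data: Dataset,
    fit_fuller: FitResult,
    fit_lesser: FitResult,
    refit_fuller,
    refit_lesser,
    sim_native,
    shape: str,
    df: int,
    n_mc: int,
    seed,
    mc_plus_one: bool,
) -> ComparisonResult:
    warnings = []
    raw = -2.0 * (fit_lesser.log_likelihood - fit_fuller.log_likelihood)
    if raw < -_TLR_CLIP:
        warnings.append(
            f"lesser model's likelihood exceeds the fuller's (raw TLR {raw:.3g}); "
            "the models may not be nested or an optimization failed"
        )
    tlr = transformed_likelihood_ratio(fit_lesser.log_likelihood, fit_fuller.log_likelihood)
    result = ComparisonResult(
        tlr=tlr,
        df=df,
        p_chi2=chi2_p_value(tlr, df),
        fuller=fit_fuller,
        lesser=fit_lesser,
        warnings=warnings,
    )
    if n_mc <= 0:
        return result

    rng = np.random.default_rng(seed)
    native = sim_native()
    samples, n_failed = [], 0
    for _ in range(n_mc):
        sim = _simulate_from_native(data, native, shape, rng)
        try:
            f_full = refit_fuller(sim)
            f_less = refit_lesser(sim)
        except PFCompareError:
            n_failed += 1
            continue
        if not (np.isfinite(f_full.log_likelihood) and np.isfinite(f_less.log_likelihood)):
            n_failed += 1
            continue
        samples.append(
            transformed_likelihood_ratio(f_less.log_likelihood, f_full.log_likelihood)
        )
    samples = np.asarray(samples)
    n_valid = n_mc - n_failed
    if n_valid == 0:
        raise PFCompareError("all Monte Carlo refits failed")
    result.p_mc = _mc_p_value(tlr, samples, n_valid, mc_plus_one)
    result.tlr_samples = samples
    result.n_mc = n_mc
    result.n_failed_fits = n_failed
    return result


# ---------------------------------------------------------------------------
# Information criteria and multiplicity correction
# ---------------------------------------------------------------------------

def aic(fit: FitResult) -> float:
    """Akaike information criterion: -2 LL + 2 k_free; lower is preferred."""
    return -2.0 * fit.log_likelihood + 2.0 * fit.k_free


def aic_table(fits: dict[str, FitResult]) -> list[tuple[str, float, float]]:
    """Rank fitted models by AIC.

    Returns (name, aic, delta_aic) tuples sorted ascending by AIC; delta is
    relative to the best model.
    """
    if not fits:
        raise SpecificationError("aic_table needs at least one fit")
    scored = sorted(((name, aic(f)) for name, f in fits.items()), key=lambda t: t[1])
    best = scored[0][1]
    return [(name, a, a - best) for name, a in scored]


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni correction: multiply each p by the number of comparisons.

    ``m`` defaults to the number of p-values; results are capped at 1.
    """
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < 1:
        raise DomainError(f"number of comparisons must be >= 1, got {m}")
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in ps]
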