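# Methods

## Model

Each (condition, level) cell's positive-response count is binomial,
k ~ Bin(n, ψ(x)), with

ψ(x; α, β, γ, λ) = γ + (1 − γ − λ)·F(x; α, β).

The four base sigmoids use conventional psychophysics parameterizations in
which α is a location and β a rate:

| shape | F(x; α, β) | domain |
|---|---|---|
| logistic | 1 / (1 + e^(−β(x−α))) | all x |
| cumulative normal | Φ(β(x−α)) | all x; β = 1/σ |
| weibull | 1 − exp(−(x/α)^β) | x > 0, α > 0 |
| gumbel (log-Weibull) | 1 − exp(−10^(β(x−α))) | all x |

Two modelling assumptions are inherited by everything downstream:
**independence** (each trial depends only on its own stimulus) and
**stability** (response probabilities are constant over the session). They
are exactly what the saturated model — one free probability per cell — also
assumes, which is why a comparison against it tests *all other* assumptions
of a candidate model.

γ and λ are kept as two separate parameters; tying them (as is natural for
two-alternative tasks where a lapse can land on either response) is
expressed through the model specification, not hard-wired.

## Constraints and reparameterization

A `ModelSpec` assigns each of α, β, γ, λ one of five constraint modes; the
free-parameter count is the sum of per-constraint contributions
(0 / 1 / C / matrix rows / free custom entries). For `matrix` mode the
engine must reconstruct C native values from M effect parameters θ; it uses
**native = Mᵀθ**. Writing the effects of the natives as θ′ = M·native, the
two conventions differ by the per-row scaling M·Mᵀ (for orthogonal rows a
diagonal matrix; e.g. factor 2 for the row [1, 1] with C = 2). This choice
does not affect fitted native parameters, likelihoods, degrees of freedom
or p-values — only the numeric scale of the internal θ, which is why fit
reports present native parameters. The scaling is documented here because
the reconstruction of natives from a non-square effect matrix has no single
canonical convention.

Custom maps accept any callable θ → C natives through the API; config
files can only name registered families (currently `exp_decay_learning`:
α_s = θ₁ + θ₂·e^(−θ₃(s−1))), so data files never execute code.

Nesting of two models is asserted by the analyst, as in standard likelihood
practice; the engine verifies only k_fuller > k_lesser and warns when the
lesser model out-fits the fuller beyond 1e-6 (general structural nesting
detection is impossible for arbitrary custom maps).

Contrast sets (`polynomial`, `helmert`, `periodic`) are generated as full
n×n matrices with the intercept row first. Polynomial rows are computed by
exact Gram–Schmidt over the rationals on the symmetric integer grid
2j − (n−1) and rescaled to smallest-integer form, reproducing the classic
tables (n = 4: [1 1 1 1], [−3 −1 1 3], [1 −1 −1 1], [−1 3 −3 1]). Contrast
rows are defined up to an overall sign; the increasing-trend convention is
used (the linear row for n = 2 is therefore [−1, 1], spanning the same
model space as [1, −1]).

## Likelihood and optimization

The log-likelihood omits binomial coefficients; they cancel in every
likelihood ratio and shift all AICs on the same data equally, so reported
LLs are comparable only within a dataset. The saturated model is closed
form (p̂ = k/n, with 0·log 0 := 0).

Fitting is Nelder–Mead simplex search (scipy) with multi-start:

- **tolerance** 1e-8 on both LL and θ, at most 5000 iterations per
  restart; 4 restarts by default (first from the heuristic start, the rest
  jittered with seeded Gaussian noise of scale 0.25(|θ₀| + 0.5));
- **initialization**: per condition, α₀ is the level whose observed
  proportion is nearest the midpoint of the observed range, β₀ = 2/range
  of levels (2 for the Weibull), γ₀/λ₀ from the extreme observed
  proportions clipped to [0.01, 0.4]; matrix-mode θ₀ solves
  Mᵀθ = heuristic natives by least squares; custom-mode θ₀ is the
  user-supplied `theta_init`;
- **transforms**: in `constrained`/`unconstrained` modes β is searched on
  a log scale (positivity) and γ, λ on a logit scale; for the Weibull, α
  is also log-transformed in those modes. `matrix`/`custom` θ are effect
  parameters in their own linear space and are searched untransformed, so
  e.g. a difference-of-slopes effect may legitimately be negative. A
  fitted non-positive native slope is flagged in the result.

F is clipped to [1e-12, 1 − 1e-12] before the γ/λ transform to keep
log-likelihoods finite; optimizer excursions that violate a domain
constraint (e.g. a non-positive Weibull location) are penalized rather than
raised. The best restart is returned even when no restart formally
converged, with `converged=False`.

Degenerate conditions (all k = 0 or all k = n) do not abort a fit but are
flagged — such data cannot support a per-condition location and slope, and
bootstrap/Monte Carlo loops on overspecified models will fail often (an
error is raised when more than half of bootstrap refits fail).

## Model comparison

TLR = −2(LL_lesser − LL_fuller), clipped to zero when negative; a raw
value below −1e-6 attaches a non-nesting/optimizer warning. The asymptotic
p-value is the upper χ² tail at df = k_fuller − k_lesser. The Monte Carlo
null simulates from the **fitted lesser model** on the observed design,
refits both models per replicate, and takes
p_mc = #{TLR_sim ≥ TLR_obs}/n_valid (ties toward the tail; a
(x+1)/(B+1) variant is available via `mc_plus_one=True`). Failed refits
are dropped and counted, never retried — retrying with fresh data would
bias the null sample. Goodness of fit simulates from the fitted target
model, not the saturated model, whose simulations would reproduce the
observed proportions in expectation and make the test degenerate. The
saturated model's df counts every cell across all conditions.

## Synthetic data

`simulate_observer` draws each cell independently as
k ~ Bin(n, ψ(level)); `make_learning_fixture` builds a multi-session
experiment whose locations follow the exponential-decay curve. Defaults
are five levels at −2…2, 50 trials per level, logistic, γ = λ = 0.02 — a
realistic appearance-task design in which the five levels straddle the
location and the per-cell binomial information is moderate. What the
generator deliberately does *not* emulate: sequential dependencies,
drifting attention or criterion, stimulus-dependent lapsing, or
between-session variance beyond the modeled learning curve. Tests passing
on this generator therefore validate the *inferential machinery* under the
model's own assumptions; they do not certify robustness to violations of
independence and stability in real data.

## Validation choices and problem sizes

The statistical checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use: 1000 replicate experiments for null
calibration (95% binomial band 0.0365–0.0635 around the nominal 0.05);
10,000 Monte Carlo simulations for the empirical-null comparison, with the
KS distance to χ²₁ evaluated on the first 2000 simulated TLRs (an
identically distributed null subsample); 200 random datasets for the
nesting/saturation inequalities over the 3×3 location-by-slope model grid;
100 replicates at 400 trials/level for location/slope recovery and 50
replicates for learning-curve recovery; a 1e-3-spaced grid scan as the
optimizer oracle. Monte Carlo inner refits use a single heuristic-start
restart — the one- and two-parameter profile likelihoods in these designs
are unimodal in practice, and the outer fits keep the multi-start default.

## Known limitations

- No gradient-based or global optimizer; very flat likelihoods (tiny n,
  near-degenerate designs) may need more restarts.
- No small-sample correction to the χ² reference; for low-N experiments
  use the Monte Carlo null instead.
- Constraints cannot link different parameter classes (e.g. tying γ to λ);
  express such designs through fixed values or custom maps per parameter.
- Asymmetric lapsing (different lapse streams for the two asymptotes
  beyond the γ/λ pair) is out of scope.
- Reported log-likelihoods exclude binomial coefficients (see above).
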