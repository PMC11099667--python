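# Methods

## Model family

The package fits conditional models for a positive allometric response `y`
given a positive covariate `x`:

**Multiplicative (EMEM) protocols.**

    y = w(x, p) · exp( h(x, c) · ε ),   ε zero-mean

so that `ln y = ln w(x) + h(x) ε`. The response density follows by change
of variables; with a scale-mixture error `ε ~ Σ_k π_k N(0, s_k)`,

    f(y|x) = Σ_k π_k φ( (ln y − ln w) / (h s_k) ) / (y h s_k),

a lognormal mixture in `y`. The conditional moments have closed forms from
the per-component lognormal identities:

    E[y|x]   = w Σ_k π_k exp(h² s_k² / 2)
    Var[y|x] = w² [ Σ_k π_k exp(2 h² s_k²) − (Σ_k π_k exp(h² s_k²/2))² ].

**Additive (AEM) protocols.** `y = w(x) + ε`, `ε ~ N(0, σ(x))` with
constant `σ`, the Breusch–Pagan form `σ(x) = σ(1 + kx)` (constrained
positive over the data range), or constant `σ` with an offset mean
`β x^α + c0`. These exist for model comparison; they admit non-positive
responses.

### Systematic parts

- `wH(x) = β x^α` — Huxley's power law, through the origin for `α > 0`.
- `wBH(x) = β x^α` for `x ≤ xb`, `β xb^(α−λ) x^λ` for `x > xb` — biphasic,
  continuous at the breakpoint by construction. In log coordinates
  (`u = ln x`) this is a continuous piecewise-linear function with slopes
  `α` and `λ` meeting at `ub = ln xb`, which the fitter exploits.
- `wH + c0` — the three-parameter power law; it does not pass through the
  origin and is included only as a competitor.

### Variance scaling

`hp(x, c) = 1` for `0 < x ≤ xb` and `(xb/x)^c` for `x > xb`, with `c ≥ 0`.
This is the minimal power-law form that equals 1 at the breakpoint
(continuity) and is non-increasing beyond it, matching the observation that
log-scale spread shrinks monotonically for large traits. In log coordinates
`ln h = −c·(u − ub)₊`. The breakpoint is *shared* with the biphasic
systematic part — a single `xb` is estimated, not two. The fitted form is
recorded in every fit report so alternative scalings can be compared later.

### Error laws

A single `N(0, σ)` or a zero-mean two-component scale mixture (`NM2`) with
weights on the simplex and components ordered by increasing sd to remove
label switching. The mixture's overall sd is `sqrt(Σ π_k s_k²)`; its
kurtosis `3 Σπ_k s_k⁴ / (Σπ_k s_k²)²` exceeds 3 whenever the sds differ,
which is exactly the heavy-tail behaviour the family is meant to capture.
The component count is fixed at 2 by default (configurable in the EM
routine); no automatic selection of the component count is attempted.

## Estimation

All parameters are estimated by maximizing the exact log-likelihood
`Σ_i ln f(y_i|x_i)` on the arithmetic data scale. Log-transformed views
exist in the package purely as plotting aids and are never used as an
estimation route.

- **Parameterization.** Positive parameters (β, σ, s_k) are optimized as
  logs, the mixture weight through a logit, the scaling exponent `c ≥ 0`
  under a box bound. Gradients for all multiplicative objectives are
  analytic.
- **Breakpoint profiling.** The likelihood is continuous but not
  differentiable in `xb`, so `xb` is never handed to the smooth optimizer:
  it is profiled on a 50-point quantile grid of the covariate (default;
  quantiles 0.02–0.98), each grid point maximized over the remaining
  parameters, then refined by a bounded 1-D search between the best grid
  point's neighbours.
- **Closed-form inner fits.** For multiplicative protocols with normal
  errors and constant scaling, the inner maximization at fixed `xb` is a
  linear least-squares problem in `ln y` (design `[1, min(u, ub),
  (u−ub)₊]`) with `σ²` profiled as SSE/n. These inner fits are solved
  exactly, which makes the `(EMEM, wBH, 1, N)` profile fast and free of
  optimizer noise.
- **Cascaded initialization.** Richer families are seeded by their nested
  ones: the normal-error fit initializes the mixture fit (EM on its
  standardized log-residuals supplies the mixture start), and the
  constant-scaling fit initializes the piecewise-scaling fit at `c = 0`.
  The exact embedding of the nested optimum is always among the starting
  points, so a generalized family's maximized log-likelihood can never fall
  below its nested family's — the nesting inequalities hold by
  construction up to optimizer tolerance (1e-6 in the tests). Additional
  jittered starts (5 total by default) guard against local optima.
- **EM for the error mixture.** A zero-mean Gaussian scale mixture has the
  standard EM updates with means pinned at zero; the observed-data
  log-likelihood is monotone, iteration stops at relative change < 1e-9 or
  2000 iterations, and a collapsing component (sd below 1e-8 of the
  residual sd) triggers up to 5 perturbed restarts before flagging. This is
  written in-package because general-purpose mixture implementations do not
  support the zero-mean constraint.
- **Convergence and uncertainty.** L-BFGS-B runs with ftol 1e-12 / gtol
  1e-8 so that AIC differences of order 1 are trustworthy; the convergence
  flag and final gradient norm are reported honestly. Standard errors, when
  requested, come from the numerically differenced observed information on
  the internal scale, delta-method transformed back; for biphasic families
  they condition on the estimated breakpoint.
- **Parameter counts** (for AIC): `(EMEM,wH,1,N)` 3; `(EMEM,wBH,1,N)` 5
  (the breakpoint counts); `(EMEM,wH,1,NM2)` 5; `(EMEM,wBH,1,NM2)` 7;
  `(EMEM,wBH,hp,NM2)` 8; `(AEM,wH,N)` 3; `(AEM-BP,wH,N)` 4; `(AEM,wH+c,N)` 4.

## Synthetic-data generator

The generator emulates the eelgrass leaf study the family was built for:
10 410 pairs of leaf area (mm², covariate) and dry weight (g, response).

- **Reference configuration** (`fig1_protocol`): biphasic systematic part
  with β=1.008219e-04, α=0.3416174, λ=1.138851, xb=30.82518 and
  multiplicative `N(0, 0.1)` errors. Default `n = 10410`.
- **Covariate sampler.** The real covariate distribution is only loosely
  characterized, so the default is a lognormal(meanlog 3.5, sdlog 1.0)
  truncated to (0.5, 2000) mm² by rejection. This places the data cloud on
  both sides of `ln x ≈ 4`, i.e. roughly balances small against
  moderate-to-large leaves around the breakpoint region. It is a stand-in,
  not a claim about the field data; any callable `(rng, n) → x` can replace
  it.
- **Full-complexity configuration** (`piecewise_mixture_protocol`): the
  same systematic part with `hp` scaling (`c = 0.5`, a moderate damping
  that roughly halves the latent-error sd by x ≈ 120 mm²) and an `NM2`
  error with π=(0.7, 0.3), s=(0.05, 0.2). These mixture values give an
  overall sd ≈ 0.117 — close to the reference σ=0.1 — with a clearly
  heavy-tailed minority component (mixture kurtosis ≈ 7.4), the qualitative
  situation the mixture law exists to model. Neither the mixture parameters
  nor `c` are published numbers; they were fixed once as realistic study
  conditions and all simulation-based tests run against them.
- **What it does not emulate:** the 13-month sampling structure and its
  seawater-temperature dynamics (group labels, when requested, are assigned
  uniformly at random), measurement-device error for very small leaves, and
  any data-cleaning artefacts. Passing parameter-recovery tests on this
  generator therefore demonstrates correctness of the estimation machinery
  under the stated model, not fit quality on real eelgrass data — the
  original 10 410-pair dataset is not publicly deposited, so its published
  AIC/CCC table values are intentionally out of scope.

## Diagnostics conventions

- **Standardized residuals**: `ε̂_i = (ln y_i − ln ŵ(x_i)) / h(x_i)` for
  multiplicative fits (additive: `(y_i − ŵ)/σ̂(x_i)`); under a correct
  model these are draws from the fitted error law, and the division by `h`
  removes the piecewise variance pattern.
- **Q–Q plots** use Hazen plotting positions `(i − 0.5)/n` and numerical
  inversion of the mixture CDF (Brent's method bracketed by the widest
  component; |CDF∘quantile − id| < 1e-12). Both the latent-error scale and
  the exponentiated (lognormal-reference) scale are offered.
- **Kurtosis** is the sample fourth standardized moment (normal ⇒ 3.0,
  non-excess convention). The heavy-tail flag trips above 4.0: at the
  n ≥ 1000 sizes this package targets, that is roughly ten sampling
  standard deviations (`sqrt(24/n)`) above the normal reference, so false
  positives under normality are rare (verified ≤ 5% over repeated draws)
  while genuine scale mixtures far exceed it.
- **Prediction strips** are pointwise quantile bands for *individual*
  responses, `[ŵ e^{h q_lo}, ŵ e^{h q_hi}]`, chosen because the published
  strip constructions bound the data cloud rather than the mean's sampling
  error; a delta-method mean-confidence band is not the default. Empirical
  coverage of the 95% strip is verified to sit in 95% ± 1% under each
  multiplicative protocol at n=10 410.

## Numerical choices and degenerate inputs

- Multiplicative densities are 0 (not an error) at `y ≤ 0`; a dataset
  containing non-positive values is rejected for multiplicative *fitting*.
- Component sds are box-bounded within e^{±7} of the residual sd during
  optimization to keep the mixture likelihood bounded.
- Biphasic evaluation beyond the recorded `xmax` warns and extrapolates
  rather than failing: `xmax` is a data attribute, not a mathematical bound.
- Equal-sd mixtures collapse exactly to the single normal; ties in the
  component ordering are broken by the stable sort of the sds.
- Every stochastic routine (simulation, jittered starts, EM restarts) takes
  an explicit seed; identical configuration and seed give bit-identical
  output.

## Problem sizes used by the test suite

Parameter recovery runs 20 replicate fits at the study size n=10 410;
nesting inequalities use three n=1000 datasets; AIC model-selection sanity
runs 10 seeds at n=2000 (a scaled-down size whose selection behaviour
matches the full size in spot checks); strip coverage uses n=10 410 per
protocol; Monte-Carlo moment oracles use 10⁷ draws.

## Known limitations

- Mixtures beyond two components are supported by the EM routine but not by
  the protocol grammar; no non-normal component families (t, skew-normal)
  and no Bayesian estimation.
- Curvature standard errors for biphasic fits ignore breakpoint
  uncertainty; use the profile curve (returned with every biphasic fit) or
  across-seed spread for honest breakpoint uncertainty.
- The two published breakpoint estimates under different error laws (≈30.8
  under N, ≈44.7 under NM2 on the real data) show that the profiled
  breakpoint can move substantially with the error law; with the real data
  unavailable, exact reproduction of those values is not promised and the
  likelihood surface in that direction should be inspected via the profile
  record.
- The RAD index is a mean-level agreement measure: compensating per-group
  errors cancel by construction.
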