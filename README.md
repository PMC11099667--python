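# emem — extended multiplicative error models for allometry

Allometric data relate the size of one trait to another through Huxley's
power law `y = β x^α`. The classical multiplicative-error analysis fits that
power law with a lognormal error, `y = β x^α e^ε`, `ε ~ N(0, σ)`. On real
trait data — the motivating case is paired eelgrass (*Zostera marina*) leaf
area (mm²) and dry weight (g) measurements — that scheme often fails in
three distinct ways: the mean curve is *biphasic* (the scaling exponent
switches at a breakpoint), the latent errors are *heavy-tailed* (a normal
law underfits the extremes), and the spread is *piecewise heteroscedastic*
(log-scale variance shrinks beyond the breakpoint).

`emem` implements the extended multiplicative error model family that
addresses all three at once:

    y = w(x, p) · exp( h(x, c) · ε )

- **Systematic part** `w(x, p)`: Huxley `wH = β x^α`; biphasic
  `wBH = β x^α` for `x ≤ xb` and `β xb^(α−λ) x^λ` for `x > xb` (continuous
  at the breakpoint `xb`); or `wH + c` (power law with offset, for
  comparison only).
- **Variance scaling** `h(x, c)`: constant 1, or piecewise
  `hp(x, c) = 1` for `x ≤ xb`, `(xb/x)^c` beyond — the latent error is
  damped for large traits.
- **Error law** `ε`: a single zero-mean normal `N(0, σ)` or a zero-mean
  two-component normal scale mixture `NM2` (weights π, sds s₁ < s₂), whose
  exponential transform yields lognormal / lognormal-mixture responses.

A protocol is named by its tuple, e.g. `(EMEM, wBH, hp, NM2)`. Additive
competitors `(AEM, wH, N)`, `(AEM-BP, wH, N)` (Breusch–Pagan deviation
`σ(x) = σ(1 + kx)`) and `(AEM, wH+c, N)` are carried along the same
interfaces for model comparison.

Everything is estimated by maximum likelihood on the arithmetic scale of
the data. The breakpoint, where the likelihood is not differentiable, is
profiled on a quantile grid of `x` and refined by golden section; mixture
parameters are seeded by EM on standardized residuals. Model choice uses
AIC/ΔAIC plus Lin's concordance correlation coefficient (CCC) and the
reproducibility statistics SEE, MPE and RAD. Log-transformed views are
offered for *graph assessment only* — never for estimation.

Intended users: ecologists and biostatisticians fitting allometric proxies
(e.g. non-destructive biomass estimation) whose data violate the classical
lognormal power-law assumptions.

## Worked example

Simulate 10 410 pairs from the reference biphasic lognormal configuration
(β=1.008219e-04, α=0.3416174, λ=1.138851, xb=30.82518, σ=0.1) and refit the
same protocol family:

```python
from emem import fit
from emem.simulate import SimulationConfig, simulate_dataset

data = simulate_dataset(SimulationConfig(n=10410, seed=42))
result = fit("(EMEM, wBH, 1, N)", data)
s = result.spec_hat
print(s.systematic.beta, s.systematic.alpha, s.systematic.lam,
      s.systematic.xb, s.error.sigma, result.aic)
```

prints (seed 42):

```
beta      : 9.987077e-05
alpha     : 0.346563
lambda    : 1.142416
xb        : 31.2221
sigma     : 0.10025
AIC       : -177942.09
```

i.e. every generating parameter is recovered to within sampling error, and
the breakpoint lands on the true 30.8 mm². Ranking protocols on data drawn
from the full-complexity generating law (biphasic + piecewise scaling +
mixture errors, n=2000, seed 7):

```python
from emem.model_compare import compare
from emem.simulate import piecewise_mixture_protocol

data = simulate_dataset(
    SimulationConfig(protocol=piecewise_mixture_protocol(), n=2000, seed=7))
fits = [fit(lab, data) for lab in ("(EMEM, wH, 1, N)", "(EMEM, wBH, 1, N)",
                                   "(EMEM, wBH, 1, NM2)", "(EMEM, wBH, hp, NM2)")]
print(compare(fits, data).to_text())
```

```
               label         aic  delta_aic    ccc    see     mpe
    (EMEM, wH, 1, N) -30475.5234  4809.8801 0.8328 0.0004 64.3341
   (EMEM, wBH, 1, N) -34220.0182  1065.3853 0.9978 0.0001  8.9094
 (EMEM, wBH, 1, NM2) -35113.6973   171.7061 0.9978 0.0001  8.9247
(EMEM, wBH, hp, NM2) -35285.4035     0.0000 0.9978 0.0001  8.9087
```

AIC picks the generating family; the ΔAIC column quantifies how much each
simplification costs. The same workflows are scriptable from a shell:

```sh
emem simulate --n 10410 --seed 7 --out results/
emem fit --input results/simulated.csv --protocol "(EMEM, wBH, 1, N)" --out results/
emem compare --input results/simulated.csv --protocols all --out results/
emem diagnose --fit results/fit_EMEM_wBH_1_N.json --input results/simulated.csv --plot
```

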