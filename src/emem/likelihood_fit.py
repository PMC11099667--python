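"""Maximum-likelihood estimation for every protocol in the family.

Strategy
--------
All fits maximize the exact log-likelihood on the arithmetic scale of the
data, ``sum_i ln f(y_i | x_i)`` with ``f`` the protocol's response density.
Positive parameters (beta, sigma, component sds) are optimized on the log
scale, the mixture weight through a logit, and the breakpoint ``xb`` of the
biphasic families — where the likelihood is not differentiable — is handled
by profiling: an inner fit of the smooth parameters on a quantile grid of
``x``, followed by 1-D golden-section refinement around the best grid cell.

For multiplicative protocols with normal errors and constant scaling the
inner maximization has a closed form (the log-likelihood is, up to constants,
a least-squares criterion in ``ln y`` with a design that is linear for fixed
``xb``), which makes breakpoint profiling exact and fast.  Mixture and
piecewise-scaling protocols use quasi-Newton (L-BFGS-B) inner fits seeded by
a cascade of nested fits: the normal-error fit initializes the mixture fit
(via EM on its standardized residuals), and the constant-scaling fit
initializes the piecewise-scaling fit with ``c_exp = 0``.  Each richer family
always includes the exact embedding of its nested family's optimum among its
starting points, so the maximized log-likelihood never falls below the
nested one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp, logit

from .core_model import (
    AllometryDataset,
    ErrorDistributionSpec,
    ErrorLaw,
    ErrorStructure,
    Family,
    ProtocolSpec,
    ScalingKind,
    SystematicSpec,
    VarianceScalingSpec,
    parse_label,
    response_density,
)

__all__ = [
    "ProtocolFit",
    "FitOptions",
    "loglik",
    "fit",
    "fit_mixture_em",
    "profile_breakpoint",
    "KNOWN_LABELS",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_NEG_SENTINEL = -1e300

KNOWN_LABELS = (
    "(EMEM, wH, 1, N)",
    "(EMEM, wBH, 1, N)",
    "(EMEM, wH, 1, NM2)",
    "(EMEM, wBH, 1, NM2)",
    "(EMEM, wBH, hp, NM2)",
    "(AEM, wH, N)",
    "(AEM-BP, wH, N)",
    "(AEM, wH+c, N)",
)


@dataclass
class FitOptions:
    """Optimizer settings shared by all families."""

    n_starts: int = 5
    grid_size: int = 50
    refine: bool = True
    compute_se: bool = False
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-12
    gtol: float = 1e-8


@dataclass
class ProtocolFit:
    """Result of one maximum-likelihood fit."""

    spec_hat: ProtocolSpec
    loglik: float
    n_params: int
    converged: bool
    n_iter: int
    grad_norm: float
    profile: Optional[tuple] = None  # (xb grid, profile loglik)
    se: Optional[dict] = None
    messages: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def label(self) -> str:
        return self.spec_hat.label

    def to_dict(self) -> dict:
        from .core_model import spec_to_config

        out = {
            "label": self.label,
            "estimates": spec_to_config(self.spec_hat),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
        }
        if self.se is not None:
            out["se"] = self.se
        if self.profile is not None:
            grid, prof = self.profile
            out["profile"] = {"xb": list(map(float, grid)),
                              "loglik": list(map(float, prof))}
        return out


def loglik(protocol: ProtocolSpec, data: AllometryDataset) -> float:
    """Sum of log response densities over the observations.

    Returns ``-inf`` when any observation has zero density under the
    protocol (e.g. a non-positive response under a multiplicative law).
    """
    if protocol.error_structure is ErrorStructure.MULTIPLICATIVE:
        data.require_positive()
    dens = response_density(protocol, data.x, data.y)
    if np.any(dens <= 0.0) or not np.all(np.isfinite(dens)):
        return -np.inf
    return float(np.sum(np.log(dens)))


# ---------------------------------------------------------------------------
# zero-mean Gaussian mixture EM
# ---------------------------------------------------------------------------


def fit_mixture_em(
    residuals: np.ndarray,
    n_comp: int = 2,
    *,
    max_iter: int = 2000,
    rel_tol: float = 1e-9,
    seed: int = 0,
    init: Optional[tuple] = None,
) -> tuple[ErrorDistributionSpec, dict]:
    """EM for a zero-mean Gaussian scale mixture over (weights, sds).

    The observed-data log-likelihood is non-decreasing across iterations;
    iteration stops at relative change below ``rel_tol`` or ``max_iter``.
    A collapsing component (sd below ``1e-8 * sd(residuals)``) triggers a
    perturbed restart, at most 5 times, after which the fit is flagged.

    Returns the fitted spec and a record with keys ``loglik_path``,
    ``n_iter``, ``converged``, ``collapsed``.
    """
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or not np.all(np.isfinite(e)):
        raise ValueError("residuals must be a finite 1-d vector")
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")
    n = e.size
    sd0 = float(np.std(e))
    if sd0 == 0:
        raise ValueError("residuals have zero variance")
    floor = 1e-8 * sd0
    rng = np.random.default_rng(seed)

    def run(w, s):
        w = np.asarray(w, float).copy()
        s = np.asarray(s, float).copy()
        path = []
        prev = -np.inf
        for it in range(max_iter):
            # E-step: log responsibilities
            logp = (
                np.log(w)
                - np.log(s)
                - 0.5 * _LOG2PI
                - 0.5 * (e[:, None] / s) ** 2
            )
            ll = float(np.sum(logsumexp(logp, axis=1)))
            path.append(ll)
            gamma = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
            # M-step
            nk = gamma.sum(axis=0)
            w = nk / n
            s = np.sqrt((gamma * e[:, None] ** 2).sum(axis=0) / np.maximum(nk, 1e-300))
            if np.any(s < floor):
                return None, path, it + 1
            if ll - prev < rel_tol * (abs(prev) + 1.0) and it > 0:
                return (w, s), path, it + 1
            prev = ll
        return (w, s), path, max_iter

    if init is not None:
        w0, s0 = np.asarray(init[0], float), np.asarray(init[1], float)
    else:
        w0 = np.full(n_comp, 1.0 / n_comp)
        s0 = sd0 * np.linspace(0.5, 1.5, n_comp)
    collapsed = False
    result, path, n_iter = run(w0, s0)
    restarts = 0
    while result is None and restarts < 5:
        restarts += 1
        jw = rng.dirichlet(np.ones(n_comp) * 5.0)
        js = sd0 * np.exp(rng.normal(0.0, 0.5, size=n_comp))
        result, path, n_iter = run(jw, js)
    if result is None:
        collapsed = True
        # fall back to the single-scale solution replicated across components
        result = (np.full(n_comp, 1.0 / n_comp), np.full(n_comp, sd0))
    w, s = result
    if n_comp == 1:
        spec = ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=float(s[0]))
    else:
        spec = ErrorDistributionSpec(
            law=ErrorLaw.NORMAL_MIXTURE, weights=tuple(w), sds=tuple(s)
        )
    record = {
        "loglik_path": path,
        "n_iter": n_iter,
        "converged": not collapsed and n_iter < max_iter,
        "collapsed": collapsed,
    }
    return spec, record


# ---------------------------------------------------------------------------
# internal objectives
# ---------------------------------------------------------------------------
# Internal parameter vectors (xb excluded, handled by profiling):
#   EMEM wH  N    : [lnbeta, alpha, lnsigma]
#   EMEM wBH N    : [lnbeta, alpha, lam, lnsigma]
#   EMEM wH  NM2  : [lnbeta, alpha, t_pi, lns1, lns2]
#   EMEM wBH NM2  : [lnbeta, alpha, lam, t_pi, lns1, lns2]
#   EMEM wBH hp NM2: [lnbeta, alpha, lam, t_pi, lns1, lns2, c_exp]
#   AEM   wH  N   : [lnbeta, alpha, lnsigma]
#   AEM-BP wH N   : [lnbeta, alpha, lnsigma, k]
#   AEM  wH+c N   : [lnbeta, alpha, c0, lnsigma]


@dataclass
class _FamilyDesc:
    structure: ErrorStructure
    family: Family
    scaling: Optional[ScalingKind]
    law: ErrorLaw

    @property
    def biphasic(self) -> bool:
        return self.family is Family.BIPHASIC

    @property
    def mixture(self) -> bool:
        return self.law is ErrorLaw.NORMAL_MIXTURE

    @property
    def piecewise(self) -> bool:
        return self.scaling is ScalingKind.PIECEWISE

    @property
    def n_params(self) -> int:
        if self.structure is ErrorStructure.MULTIPLICATIVE:
            k = 2 + (2 if self.biphasic else 0)  # beta, alpha (+ lam, xb)
            k += 3 if self.mixture else 1
            k += 1 if self.piecewise else 0
            return k
        k = 3  # beta, alpha, sigma
        if self.structure is ErrorStructure.ADDITIVE_BP:
            k += 1
        if self.family is Family.HUXLEY_OFFSET:
            k += 1
        return k

    @property
    def param_names(self) -> list:
        if self.structure is ErrorStructure.MULTIPLICATIVE:
            names = ["lnbeta", "alpha"]
            if self.biphasic:
                names.append("lam")
            if self.mixture:
                names += ["t_pi", "lns1", "lns2"]
            else:
                names.append("lnsigma")
            if self.piecewise:
                names.append("c_exp")
            return names
        names = ["lnbeta", "alpha"]
        if self.family is Family.HUXLEY_OFFSET:
            names.append("c0")
        names.append("lnsigma")
        if self.structure is ErrorStructure.ADDITIVE_BP:
            names.append("k")
        return names


def _desc_from_label(label: str) -> _FamilyDesc:
    p = parse_label(label)
    return _FamilyDesc(
        structure=p["error_structure"],
        family=p["family"],
        scaling=p["scaling"],
        law=p["law"],
    )


def _mult_nll_parts(theta, desc: _FamilyDesc, u, v, ub):
    """Negative log-likelihood and gradient of a multiplicative protocol.

    With r = ln y - ln w(x) and h = h(x, c), the response density is
    sum_k pi_k phi(r / (h s_k)) / (y h s_k); the sum of -ln y terms (sum of
    v) is included so log-likelihoods are comparable across additive and
    multiplicative protocols.  The gradient is analytic on the internal
    (log/logit) scale.
    """
    n = u.size
    lnbeta, alpha = theta[0], theta[1]
    j = 2
    if desc.biphasic:
        lam = theta[j]
        j += 1
        m = np.minimum(u, ub)
        du = np.clip(u - ub, 0.0, None)
        lnw = lnbeta + alpha * m + lam * du
    else:
        m = u
        du = None
        lnw = lnbeta + alpha * u
    r = v - lnw
    if desc.piecewise:
        c = theta[-1]
        lnh = -c * du
    else:
        lnh = np.zeros_like(u)
    grad = np.zeros_like(np.asarray(theta, dtype=float))
    if desc.mixture:
        t_pi, lns1, lns2 = theta[j], theta[j + 1], theta[j + 2]
        pi1 = expit(t_pi)
        lpis = np.array([np.log(pi1 + 1e-300), np.log(1.0 - pi1 + 1e-300)])
        lns = np.array([lns1, lns2])
        z = r[:, None] * np.exp(-lnh[:, None] - lns)  # (n, 2)
        comp = lpis - lns - 0.5 * _LOG2PI - 0.5 * z**2
        lse = logsumexp(comp, axis=1)
        ll = float(np.sum(lse)) - float(np.sum(lnh)) - float(np.sum(v))
        g = np.exp(comp - lse[:, None])  # responsibilities
        t = z * np.exp(-lnh[:, None] - lns)  # d comp / d lnw
        gt = np.sum(g * t, axis=1)
        grad[0] = -np.sum(gt)
        grad[1] = -np.sum(m * gt)
        jj = 2
        if desc.biphasic:
            grad[jj] = -np.sum(du * gt)
            jj += 1
        gz2 = g * z**2
        grad[jj] = -np.sum(g[:, 0] * (1.0 - pi1) - g[:, 1] * pi1)  # t_pi
        grad[jj + 1] = -np.sum(gz2[:, 0] - g[:, 0])
        grad[jj + 2] = -np.sum(gz2[:, 1] - g[:, 1])
        if desc.piecewise:
            grad[-1] = -np.sum(du * (1.0 - gz2.sum(axis=1)))
    else:
        lnsigma = theta[j]
        sigma2 = np.exp(2.0 * lnsigma)
        eps = r * np.exp(-lnh)
        ll = (
            -0.5 * n * (_LOG2PI + 2.0 * lnsigma)
            - float(np.sum(lnh))
            - 0.5 * float(np.sum(eps**2)) / sigma2
            - float(np.sum(v))
        )
        q = eps * np.exp(-lnh) / sigma2  # d ll / d lnw
        grad[0] = -np.sum(q)
        grad[1] = -np.sum(m * q)
        jj = 2
        if desc.biphasic:
            grad[jj] = -np.sum(du * q)
            jj += 1
        grad[jj] = -(-n + float(np.sum(eps**2)) / sigma2)
        if desc.piecewise:
            grad[-1] = -np.sum(du * (1.0 - eps**2 / sigma2))
    if not np.isfinite(ll):
        return -_NEG_SENTINEL, np.zeros_like(grad)
    return -ll, grad


def _mult_nll(theta, desc: _FamilyDesc, u, v, ub):
    return _mult_nll_parts(theta, desc, u, v, ub)[0]


def _add_nll(theta, desc: _FamilyDesc, x, y):
    lnbeta, alpha = theta[0], theta[1]
    j = 2
    w = np.exp(lnbeta) * x**alpha
    if desc.family is Family.HUXLEY_OFFSET:
        w = w + theta[j]
        j += 1
    lnsigma = theta[j]
    j += 1
    sd = np.exp(lnsigma)
    if desc.structure is ErrorStructure.ADDITIVE_BP:
        k = theta[j]
        scale = 1.0 + k * x
        if np.any(scale <= 0):
            return -_NEG_SENTINEL
        sd = sd * scale
    z = (y - w) / sd
    ll = -np.sum(np.log(sd)) - 0.5 * y.size * _LOG2PI - 0.5 * np.sum(z**2)
    return -ll if np.isfinite(ll) else -_NEG_SENTINEL


# ---------------------------------------------------------------------------
# closed-form inner fit: multiplicative, normal error, constant scaling
# ---------------------------------------------------------------------------


def _ols_mult_normal(u, v, ub=None):
    """Exact ML for (EMEM, wH/wBH, 1, N) at fixed breakpoint.

    The log-likelihood is a least-squares criterion in v = ln y with design
    [1, u] (Huxley) or [1, min(u, ub), (u - ub)+] (biphasic, continuous at
    ub); sigma^2 is profiled as SSE/n.  Returns (theta, loglik) with theta on
    the internal scale.
    """
    n = u.size
    if ub is None:
        X = np.column_stack([np.ones(n), u])
    else:
        X = np.column_stack([np.ones(n), np.minimum(u, ub), np.clip(u - ub, 0.0, None)])
    coef, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    sigma2 = float(resid @ resid) / n
    sigma2 = max(sigma2, 1e-300)
    ll = -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0) - float(np.sum(v))
    if ub is None:
        theta = np.array([coef[0], coef[1], 0.5 * np.log(sigma2)])
    else:
        theta = np.array([coef[0], coef[1], coef[2], 0.5 * np.log(sigma2)])
    return theta, ll


# ---------------------------------------------------------------------------
# generic inner fit
# ---------------------------------------------------------------------------


def _bounds_for(desc: _FamilyDesc, data: AllometryDataset, sd_ref: float):
    lo_s = np.log(max(sd_ref, 1e-12)) - 7.0
    hi_s = np.log(max(sd_ref, 1e-12)) + 7.0
    bounds = []
    for name in desc.param_names:
        if name in ("lnbeta", "c0"):
            bounds.append((None, None))
        elif name in ("alpha", "lam"):
            bounds.append((-20.0, 20.0))
        elif name == "t_pi":
            bounds.append((-12.0, 12.0))
        elif name in ("lns1", "lns2", "lnsigma"):
            bounds.append((lo_s, hi_s))
        elif name == "c_exp":
            bounds.append((0.0, 20.0))
        elif name == "k":
            xmax = float(np.max(data.x))
            bounds.append((-(1.0 - 1e-8) / xmax, 1e6))
        else:  # pragma: no cover
            raise AssertionError(name)
    return bounds


def _minimize(fun, x0, bounds, options: FitOptions, jac=None):
    res = optimize.minimize(
        fun,
        np.asarray(x0, dtype=float),
        method="L-BFGS-B",
        jac=jac,
        bounds=bounds,
        options={
            "maxiter": options.maxiter,
            "ftol": options.ftol,
            "gtol": options.gtol,
        },
    )
    return res


def _inner_fit(desc, data, ub, starts, options, arrays):
    """Best local optimum over the given starting points at fixed ub."""
    u, v = arrays
    if (
        desc.structure is ErrorStructure.MULTIPLICATIVE
        and not desc.mixture
        and not desc.piecewise
    ):
        theta, ll = _ols_mult_normal(u, v, ub if desc.biphasic else None)
        return theta, ll, True, 1, 0.0
    if desc.structure is ErrorStructure.MULTIPLICATIVE:
        fun = lambda th: _mult_nll_parts(th, desc, u, v, ub)
        jac = True
        sd_ref = float(np.std(v))
    else:
        fun = lambda th: _add_nll(th, desc, data.x, data.y)
        jac = None
        sd_ref = float(np.std(data.y))
    bounds = _bounds_for(desc, data, max(sd_ref, 1e-6))
    best = None
    for x0 in starts:
        res = _minimize(fun, x0, bounds, options, jac=jac)
        if best is None or res.fun < best.fun:
            best = res
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    return (
        np.asarray(best.x),
        -float(best.fun),
        bool(best.success),
        int(best.nit),
        grad_norm,
    )


# ---------------------------------------------------------------------------
# starting points
# ---------------------------------------------------------------------------


def _huxley_ols_init(data: AllometryDataset):
    """Log–log least-squares Huxley parameters, used only to seed optimizers."""
    mask = (data.x > 0) & (data.y > 0)
    if mask.sum() < 3:
        return 0.0, 1.0, 1.0
    u = np.log(data.x[mask])
    v = np.log(data.y[mask])
    X = np.column_stack([np.ones(mask.sum()), u])
    coef, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    return float(coef[0]), float(coef[1]), float(np.std(resid) + 1e-12)


def _starts_for(desc, data, options, init_theta=None, cascade_theta=None):
    """Primary + nested-embedding + jittered starting points."""
    lnb0, a0, sd0 = _huxley_ols_init(data)
    rng = np.random.default_rng(options.seed + 1_000_003)
    base = {"lnbeta": lnb0, "alpha": a0, "lam": a0, "lnsigma": np.log(sd0),
            "t_pi": 0.0, "lns1": np.log(sd0 * 0.7), "lns2": np.log(sd0 * 1.5),
            "c_exp": 0.0, "c0": 0.0, "k": 0.0}
    if desc.structure is not ErrorStructure.MULTIPLICATIVE:
        base["lnsigma"] = np.log(max(float(np.std(data.y)), 1e-12))
    names = desc.param_names
    primary = np.array([base[nm] for nm in names])
    starts = [primary]
    if cascade_theta is not None:
        starts.insert(0, np.asarray(cascade_theta, dtype=float))
    if init_theta is not None:
        starts.insert(0, np.asarray(init_theta, dtype=float))
    while len(starts) < options.n_starts:
        jit = primary + rng.normal(0.0, 0.3, size=primary.size)
        # keep bounded params inside their ranges
        for i, nm in enumerate(names):
            if nm == "c_exp":
                jit[i] = abs(jit[i])
            if nm == "k":
                jit[i] = 0.0
        starts.append(jit)
    return starts


# ---------------------------------------------------------------------------
# spec packing
# ---------------------------------------------------------------------------


def _theta_to_spec(desc: _FamilyDesc, theta, xb, xmax) -> ProtocolSpec:
    names = desc.param_names
    d = dict(zip(names, np.asarray(theta, dtype=float)))
    if desc.biphasic:
        systematic = SystematicSpec(
            family=Family.BIPHASIC,
            beta=float(np.exp(d["lnbeta"])),
            alpha=float(d["alpha"]),
            lam=float(d["lam"]),
            xb=float(xb),
            xmax=xmax,
        )
    elif desc.family is Family.HUXLEY_OFFSET:
        systematic = SystematicSpec(
            family=Family.HUXLEY_OFFSET,
            beta=float(np.exp(d["lnbeta"])),
            alpha=float(d["alpha"]),
            c0=float(d["c0"]),
            xmax=xmax,
        )
    else:
        systematic = SystematicSpec(
            family=Family.HUXLEY,
            beta=float(np.exp(d["lnbeta"])),
            alpha=float(d["alpha"]),
            xmax=xmax,
        )
    if desc.mixture:
        pi1 = float(expit(d["t_pi"]))
        error = ErrorDistributionSpec(
            law=ErrorLaw.NORMAL_MIXTURE,
            weights=(pi1, 1.0 - pi1),
            sds=(float(np.exp(d["lns1"])), float(np.exp(d["lns2"]))),
        )
    else:
        error = ErrorDistributionSpec(
            law=ErrorLaw.NORMAL, sigma=float(np.exp(d["lnsigma"]))
        )
    if desc.piecewise:
        scaling = VarianceScalingSpec(
            kind=ScalingKind.PIECEWISE, c_exp=float(d["c_exp"]), xb=float(xb)
        )
    else:
        scaling = VarianceScalingSpec()
    return ProtocolSpec(
        error_structure=desc.structure,
        systematic=systematic,
        scaling=scaling,
        error=error,
        bp_k=float(d["k"]) if "k" in d else None,
    )


def _spec_to_theta(desc: _FamilyDesc, spec: ProtocolSpec) -> np.ndarray:
    s = spec.systematic
    d = {"lnbeta": np.log(s.beta), "alpha": s.alpha}
    if s.lam is not None:
        d["lam"] = s.lam
    if s.c0 is not None:
        d["c0"] = s.c0
    if spec.error.law is ErrorLaw.NORMAL:
        d["lnsigma"] = np.log(spec.error.sigma)
        # allow a normal spec to seed a mixture family (exact embedding)
        d["t_pi"] = 0.0
        d["lns1"] = np.log(spec.error.sigma)
        d["lns2"] = np.log(spec.error.sigma)
    else:
        w = spec.error.component_weights
        sds = spec.error.component_sds
        d["t_pi"] = float(logit(np.clip(w[0], 1e-12, 1 - 1e-12)))
        d["lns1"] = np.log(sds[0])
        d["lns2"] = np.log(sds[1])
    d["c_exp"] = spec.scaling.c_exp if spec.scaling.kind is ScalingKind.PIECEWISE else 0.0
    d["k"] = spec.bp_k if spec.bp_k is not None else 0.0
    if "lam" not in d:
        d["lam"] = s.alpha
    if "c0" not in d:
        d["c0"] = 0.0
    return np.array([d[nm] for nm in desc.param_names], dtype=float)


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def _xb_grid(data: AllometryDataset, grid_size: int, extra=()):
    qs = np.linspace(0.02, 0.98, grid_size)
    grid = np.unique(np.quantile(data.x, qs))
    xmin, xmax = float(np.min(data.x)), float(np.max(data.x))
    extra = [g for g in extra if xmin < g < xmax]
    if extra:
        grid = np.unique(np.concatenate([grid, np.asarray(extra, float)]))
    return grid


def fit(
    protocol_family: str,
    data: AllometryDataset,
    init: Optional[ProtocolSpec] = None,
    options: Optional[FitOptions] = None,
) -> ProtocolFit:
    """Maximum-likelihood fit of one protocol family.

    ``protocol_family`` is a canonical label such as ``"(EMEM, wBH, 1, N)"``.
    ``init``, when given, supplies an extra starting point (and, for biphasic
    families, an extra breakpoint candidate on the profiling grid).
    """
    options = options or FitOptions()
    desc = _desc_from_label(protocol_family)
    if desc.structure is ErrorStructure.MULTIPLICATIVE:
        data.require_positive()
    n_params = desc.n_params
    if data.n < 2 * n_params:
        raise ValueError(
            f"need at least {2 * n_params} observations to fit {protocol_family}"
        )
    xmax = float(np.max(data.x))
    u = np.log(data.x) if np.all(data.x > 0) else None
    v = np.log(data.y) if np.all(data.y > 0) else None
    arrays = (u, v)
    messages: list = []

    init_theta = _spec_to_theta(desc, init) if init is not None else None
    init_xb = init.systematic.xb if init is not None else None

    # --- cascade: fit the nested family first, for seeding and nesting ---
    cascade_theta = None
    cascade_xb = None
    if desc.structure is ErrorStructure.MULTIPLICATIVE and desc.piecewise:
        nested = fit(
            f"(EMEM, {desc.family.value}, 1, NM2)"
            if desc.mixture
            else f"(EMEM, {desc.family.value}, 1, N)",
            data,
            options=options,
        )
        cascade_theta = _spec_to_theta(desc, nested.spec_hat)
        cascade_xb = nested.spec_hat.systematic.xb
    elif desc.structure is ErrorStructure.MULTIPLICATIVE and desc.mixture:
        nested = fit(f"(EMEM, {desc.family.value}, 1, N)", data, options=options)
        cascade_xb = nested.spec_hat.systematic.xb
        # EM on the nested fit's standardized residuals seeds the mixture
        r = np.log(data.y) - np.log(
            np.maximum(
                _eval_mean(nested.spec_hat, data.x), 1e-300
            )
        )
        mix, _ = fit_mixture_em(r, n_comp=2, seed=options.seed)
        seeded = _spec_to_theta(desc, nested.spec_hat)
        names = desc.param_names
        if mix.law is ErrorLaw.NORMAL_MIXTURE:
            seeded[names.index("t_pi")] = float(
                logit(np.clip(mix.component_weights[0], 1e-12, 1 - 1e-12))
            )
            seeded[names.index("lns1")] = np.log(mix.component_sds[0])
            seeded[names.index("lns2")] = np.log(mix.component_sds[1])
        cascade_theta = _spec_to_theta(desc, nested.spec_hat)  # exact embedding
        init_theta = seeded if init_theta is None else init_theta
    elif desc.structure is ErrorStructure.ADDITIVE_BP or (
        desc.family is Family.HUXLEY_OFFSET
    ):
        nested = fit("(AEM, wH, N)", data, options=options)
        cascade_theta = _spec_to_theta(desc, nested.spec_hat)

    starts = _starts_for(desc, data, options, init_theta, cascade_theta)

    if not desc.biphasic:
        theta, ll, ok, nit, gnorm = _inner_fit(desc, data, None, starts, options, arrays)
        spec_hat = _theta_to_spec(desc, theta, None, xmax)
        se = _standard_errors(desc, data, theta, None, arrays) if options.compute_se else None
        return ProtocolFit(
            spec_hat=spec_hat,
            loglik=ll,
            n_params=n_params,
            converged=ok,
            n_iter=nit,
            grad_norm=gnorm,
            se=se,
            messages=messages,
        )

    # --- biphasic: profile the breakpoint ---
    extra = [g for g in (cascade_xb, init_xb) if g is not None]
    grid = _xb_grid(data, options.grid_size, extra)
    prof_ll = np.empty(grid.size)
    prof_theta = [None] * grid.size
    warm = list(starts)
    for i, ub_x in enumerate(grid):
        ub = float(np.log(ub_x))
        theta_i, ll_i, ok_i, _, _ = _inner_fit(desc, data, ub, warm, options, arrays)
        prof_ll[i] = ll_i
        prof_theta[i] = theta_i
        # warm-start the next grid point with the current optimum
        warm = [theta_i] + starts[:1]
    if not np.any(np.isfinite(prof_ll)):
        raise RuntimeError("all breakpoint grid fits failed")
    ibest = int(np.argmax(prof_ll))
    xb_hat = float(grid[ibest])
    theta_hat = prof_theta[ibest]
    ll_hat = float(prof_ll[ibest])

    if options.refine and 0 < ibest < grid.size - 1:
        lo, hi = float(grid[ibest - 1]), float(grid[ibest + 1])

        def neg_profile(xb_c):
            th, ll_c, *_ = _inner_fit(
                desc, data, float(np.log(xb_c)), [theta_hat], options, arrays
            )
            return -ll_c

        res = optimize.minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4 * xb_hat, "maxiter": 40},
        )
        if -res.fun >= ll_hat:
            xb_hat = float(res.x)
            theta_hat, ll_hat, ok, nit, gnorm = _inner_fit(
                desc, data, float(np.log(xb_hat)), [theta_hat], options, arrays
            )
        else:
            ok, nit, gnorm = True, 1, 0.0
    else:
        ok, nit, gnorm = True, 1, 0.0

    spec_hat = _theta_to_spec(desc, theta_hat, xb_hat, xmax)
    se = (
        _standard_errors(desc, data, theta_hat, float(np.log(xb_hat)), arrays)
        if options.compute_se
        else None
    )
    return ProtocolFit(
        spec_hat=spec_hat,
        loglik=ll_hat,
        n_params=n_params,
        converged=bool(ok),
        n_iter=int(nit),
        grad_norm=float(gnorm),
        profile=(grid, prof_ll),
        se=se,
        messages=messages,
    )


def _eval_mean(spec: ProtocolSpec, x):
    from .core_model import eval_systematic

    return eval_systematic(spec.systematic, x)


def profile_breakpoint(
    protocol_family: str,
    data: AllometryDataset,
    grid: Optional[np.ndarray] = None,
    options: Optional[FitOptions] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Profile log-likelihood of the breakpoint for a biphasic family.

    Returns ``(grid, profile_loglik, xb_hat)`` where ``xb_hat`` is the
    refined maximizer.
    """
    options = options or FitOptions()
    desc = _desc_from_label(protocol_family)
    if not desc.biphasic:
        raise ValueError("breakpoint profiling requires a biphasic family")
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        if grid.size < 3:
            raise ValueError("grid must contain at least 3 candidates")
        if np.any(grid <= np.min(data.x)) or np.any(grid >= np.max(data.x)):
            raise ValueError("grid must lie strictly inside (min(x), max(x))")
        options = FitOptions(**{**options.__dict__})
        result = _fit_with_grid(protocol_family, data, grid, options)
    else:
        result = fit(protocol_family, data, options=options)
    g, p = result.profile
    return g, p, float(result.spec_hat.systematic.xb)


def _fit_with_grid(protocol_family, data, grid, options):
    """fit() with a caller-supplied breakpoint grid."""
    desc = _desc_from_label(protocol_family)
    xmax = float(np.max(data.x))
    u, v = np.log(data.x), np.log(data.y)
    arrays = (u, v)
    starts = _starts_for(desc, data, options)
    prof_ll = np.empty(grid.size)
    prof_theta = [None] * grid.size
    warm = list(starts)
    for i, ub_x in enumerate(np.sort(grid)):
        theta_i, ll_i, *_ = _inner_fit(desc, data, float(np.log(ub_x)), warm, options, arrays)
        prof_ll[i] = ll_i
        prof_theta[i] = theta_i
        warm = [theta_i] + starts[:1]
    grid_sorted = np.sort(grid)
    ibest = int(np.argmax(prof_ll))
    xb_hat = float(grid_sorted[ibest])
    theta_hat = prof_theta[ibest]
    ll_hat = float(prof_ll[ibest])
    if options.refine and 0 < ibest < grid_sorted.size - 1:
        lo, hi = float(grid_sorted[ibest - 1]), float(grid_sorted[ibest + 1])
        res = optimize.minimize_scalar(
            lambda xb_c: -_inner_fit(desc, data, float(np.log(xb_c)), [theta_hat], options, arrays)[1],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4 * xb_hat, "maxiter": 40},
        )
        if -res.fun >= ll_hat:
            xb_hat = float(res.x)
            theta_hat, ll_hat, *_ = _inner_fit(
                desc, data, float(np.log(xb_hat)), [theta_hat], options, arrays
            )
    spec_hat = _theta_to_spec(desc, theta_hat, xb_hat, xmax)
    return ProtocolFit(
        spec_hat=spec_hat,
        loglik=ll_hat,
        n_params=desc.n_params,
        converged=True,
        n_iter=1,
        grad_norm=0.0,
        profile=(grid_sorted, prof_ll),
    )


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------


def _standard_errors(desc, data, theta, ub, arrays):
    """Observed-information standard errors on the natural scale.

    The Hessian of the negative log-likelihood is differenced numerically on
    the internal (log/logit) scale at the optimum, inverted, and mapped back
    by the delta method.  For biphasic families the breakpoint is held at its
    estimate, so these are curvature-based errors conditional on xb.
    """
    u, v = arrays
    if desc.structure is ErrorStructure.MULTIPLICATIVE:
        fun = lambda th: _mult_nll(th, desc, u, v, ub)
    else:
        fun = lambda th: _add_nll(th, desc, data.x, data.y)
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    hstep = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.empty((p, p))
    f0 = fun(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = hstep[i]
            ej = np.zeros(p); ej[j] = hstep[j]
            fpp = fun(theta + ei + ej)
            fpm = fun(theta + ei - ej)
            fmp = fun(theta - ei + ej)
            fmm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hstep[i] * hstep[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    if np.any(var <= 0):
        var = np.where(var > 0, var, np.nan)
    se_int = np.sqrt(var)
    out = {}
    for nm, th_i, se_i in zip(desc.param_names, theta, se_int):
        if nm == "lnbeta":
            out["beta"] = float(np.exp(th_i) * se_i)
        elif nm.startswith("lns"):
            key = {"lnsigma": "sigma", "lns1": "s1", "lns2": "s2"}[nm]
            out[key] = float(np.exp(th_i) * se_i)
        elif nm == "t_pi":
            pi1 = float(expit(th_i))
            out["pi1"] = float(pi1 * (1 - pi1) * se_i)
        else:
            out[nm] = float(se_i)
    return out
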