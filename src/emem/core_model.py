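"""Mathematical building blocks of the extended multiplicative error model (EMEM).

An EMEM protocol describes a positive allometric response ``y`` at covariate
``x`` through

    y = w(x, p) * exp(h(x, c) * eps),

where ``w`` is a systematic mean function (Huxley power law, its biphasic
extension, or a power law with additive offset), ``h`` is a variance-scaling
function (constant or piecewise, switching at the breakpoint of the biphasic
part), and ``eps`` is a zero-mean latent error — a single normal or a
zero-mean normal scale mixture.  Additive-error protocols (``y = w(x) + eps``)
with constant or Breusch–Pagan covariate-dependent deviation are carried
along the same interfaces for model comparison.

This module holds the specification dataclasses and evaluates means,
variances, densities and quantiles of the response under any protocol;
estimation lives in :mod:`emem.likelihood_fit`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Family",
    "ScalingKind",
    "ErrorLaw",
    "ErrorStructure",
    "AllometryDataset",
    "SystematicSpec",
    "VarianceScalingSpec",
    "ErrorDistributionSpec",
    "ProtocolSpec",
    "eval_systematic",
    "eval_scaling",
    "error_density",
    "error_cdf",
    "error_quantile",
    "response_density",
    "response_mean_var",
    "parse_label",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


class Family(str, Enum):
    """Systematic mean-function family."""

    HUXLEY = "wH"
    BIPHASIC = "wBH"
    HUXLEY_OFFSET = "wH+c"


class ScalingKind(str, Enum):
    CONSTANT = "1"
    PIECEWISE = "hp"


class ErrorLaw(str, Enum):
    NORMAL = "N"
    NORMAL_MIXTURE = "NM2"


class ErrorStructure(str, Enum):
    MULTIPLICATIVE = "EMEM"
    ADDITIVE = "AEM"
    ADDITIVE_BP = "AEM-BP"


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllometryDataset:
    """Paired trait observations: covariate ``x`` (e.g. leaf area, mm^2) and
    response ``y`` (e.g. leaf dry weight, g), optionally grouped (e.g. by
    sampling month)."""

    x: np.ndarray
    y: np.ndarray
    group: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if x.shape != y.shape:
            raise ValueError(
                f"x and y lengths differ: {x.shape[0]} vs {y.shape[0]}"
            )
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.group is not None:
            g = np.asarray(self.group)
            if g.shape[0] != x.shape[0]:
                raise ValueError("group length does not match x/y")
            object.__setattr__(self, "group", g)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def require_positive(self) -> None:
        """Multiplicative protocols are defined only for x, y > 0."""
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ValueError(
                "multiplicative protocols require strictly positive x and y"
            )


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SystematicSpec:
    """Mean-function specification w(x, p).

    HUXLEY:        w(x) = beta * x**alpha
    BIPHASIC:      w(x) = beta * x**alpha            for x <= xb
                   w(x) = beta * xb**(alpha-lam) * x**lam  for x > xb
                   (continuous at the breakpoint xb)
    HUXLEY_OFFSET: w(x) = beta * x**alpha + c0
    """

    family: Family
    beta: float
    alpha: float
    lam: Optional[float] = None
    xb: Optional[float] = None
    c0: Optional[float] = None
    xmax: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.family is Family.BIPHASIC:
            if self.lam is None or self.xb is None:
                raise ValueError("BIPHASIC requires lam and xb")
            if self.xb <= 0:
                raise ValueError("breakpoint xb must be positive")
        if self.family is Family.HUXLEY_OFFSET and self.c0 is None:
            raise ValueError("HUXLEY_OFFSET requires c0")


@dataclass(frozen=True)
class VarianceScalingSpec:
    """Variance-scaling function h(x, c).

    CONSTANT:  h(x) = 1.
    PIECEWISE: h(x) = 1 for 0 < x <= xb and (xb/x)**c_exp beyond — equal to 1
    at the breakpoint and non-increasing for x > xb when c_exp >= 0, so the
    latent-error spread shrinks for the larger-trait phase.
    """

    kind: ScalingKind = ScalingKind.CONSTANT
    c_exp: Optional[float] = None
    xb: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ScalingKind(self.kind))
        if self.kind is ScalingKind.PIECEWISE:
            if self.c_exp is None or self.xb is None:
                raise ValueError("PIECEWISE scaling requires c_exp and xb")
            if self.c_exp < 0:
                raise ValueError("c_exp must be non-negative")
            if self.xb <= 0:
                raise ValueError("scaling breakpoint must be positive")


@dataclass(frozen=True)
class ErrorDistributionSpec:
    """Zero-mean latent error law: a single normal N(0, sigma) or a
    zero-mean scale mixture sum_k pi_k N(0, s_k)."""

    law: ErrorLaw
    sigma: Optional[float] = None
    weights: Optional[tuple] = None
    sds: Optional[tuple] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "law", ErrorLaw(self.law))
        if self.law is ErrorLaw.NORMAL:
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("NORMAL requires sigma > 0")
        else:
            w = np.asarray(self.weights, dtype=float)
            s = np.asarray(self.sds, dtype=float)
            if w.shape != s.shape or w.ndim != 1:
                raise ValueError("weights and sds must be 1-d and congruent")
            if np.any(s <= 0):
                raise ValueError("component sds must be positive")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("weights must be non-negative and sum to 1")
            # order components by increasing sd to remove label switching
            order = np.argsort(s)
            object.__setattr__(self, "weights", tuple(w[order]))
            object.__setattr__(self, "sds", tuple(s[order]))

    @property
    def n_comp(self) -> int:
        return 1 if self.law is ErrorLaw.NORMAL else len(self.weights)

    @property
    def component_weights(self) -> np.ndarray:
        if self.law is ErrorLaw.NORMAL:
            return np.array([1.0])
        return np.asarray(self.weights, dtype=float)

    @property
    def component_sds(self) -> np.ndarray:
        if self.law is ErrorLaw.NORMAL:
            return np.array([self.sigma], dtype=float)
        return np.asarray(self.sds, dtype=float)

    @property
    def overall_sd(self) -> float:
        """sd of the mixture: sqrt(sum_k pi_k s_k^2); the mean is zero."""
        w, s = self.component_weights, self.component_sds
        return float(np.sqrt(np.sum(w * s**2)))


@dataclass(frozen=True)
class ProtocolSpec:
    """A full protocol 4-tuple (or additive triplet).

    ``label`` is derived from the other fields and follows the grammar
    ``(EMEM|AEM|AEM-BP, wH|wBH|wH+c, 1|hp, N|NM2)`` — additive protocols
    drop the scaling slot.
    """

    error_structure: ErrorStructure
    systematic: SystematicSpec
    error: ErrorDistributionSpec
    scaling: VarianceScalingSpec = field(default_factory=VarianceScalingSpec)
    bp_k: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "error_structure", ErrorStructure(self.error_structure)
        )
        es = self.error_structure
        if es in (ErrorStructure.ADDITIVE, ErrorStructure.ADDITIVE_BP):
            if self.error.law is not ErrorLaw.NORMAL:
                raise ValueError("additive protocols require a NORMAL error law")
            if self.scaling.kind is not ScalingKind.CONSTANT:
                raise ValueError("variance scaling applies only to EMEM protocols")
        if es is ErrorStructure.ADDITIVE_BP and self.bp_k is None:
            raise ValueError("ADDITIVE_BP requires the Breusch-Pagan slope bp_k")

    @property
    def label(self) -> str:
        fam = self.systematic.family.value
        law = self.error.law.value
        if self.error_structure is ErrorStructure.MULTIPLICATIVE:
            return f"(EMEM, {fam}, {self.scaling.kind.value}, {law})"
        return f"({self.error_structure.value}, {fam}, {law})"

    def additive_sd(self, x: np.ndarray) -> np.ndarray:
        """Deviation of the additive error at covariate x.

        Constant sigma for AEM; sigma * (1 + k*x) for the Breusch–Pagan
        variant (the linear-in-covariate deviation, kept positive over the
        data range)."""
        x = np.asarray(x, dtype=float)
        sigma = self.error.sigma
        if self.error_structure is ErrorStructure.ADDITIVE_BP:
            sd = sigma * (1.0 + self.bp_k * x)
            if np.any(sd <= 0):
                raise ValueError("Breusch-Pagan deviation non-positive on data range")
            return sd
        return np.full_like(x, sigma)


def parse_label(label: str) -> dict:
    """Parse a canonical protocol label into its structural fields.

    Returns a dict with keys ``error_structure``, ``family``, ``scaling``
    (None for additive protocols) and ``law``.  Round-trips with
    :attr:`ProtocolSpec.label`.
    """
    text = label.strip()
    if text.startswith("(") and text.endswith(")"):
        text = text[1:-1]
    parts = [p.strip() for p in text.split(",")]
    if len(parts) == 4:
        es, fam, sc, law = parts
        if es != "EMEM":
            raise ValueError(f"4-tuple labels must start with EMEM: {label!r}")
        return {
            "error_structure": ErrorStructure.MULTIPLICATIVE,
            "family": Family(fam),
            "scaling": ScalingKind(sc),
            "law": ErrorLaw(law),
        }
    if len(parts) == 3:
        es, fam, law = parts
        return {
            "error_structure": ErrorStructure(es),
            "family": Family(fam),
            "scaling": None,
            "law": ErrorLaw(law),
        }
    raise ValueError(f"cannot parse protocol label {label!r}")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def eval_systematic(spec: SystematicSpec, x) -> np.ndarray:
    """Evaluate the mean function w(x, p) elementwise.

    The biphasic branch uses the closed second-phase form
    ``beta * xb**(alpha-lam) * x**lam``, algebraically identical to the
    ``beta * f(x)**alpha * g(x)**lam`` product with f(x) = min(x, xb) and
    g(x) = max(x/xb, 1).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("covariate values must be non-negative")
    if spec.family is Family.HUXLEY:
        return spec.beta * x**spec.alpha
    if spec.family is Family.HUXLEY_OFFSET:
        return spec.beta * x**spec.alpha + spec.c0
    # biphasic
    if spec.xmax is not None and np.any(x > spec.xmax):
        warnings.warn(
            "evaluating biphasic mean beyond xmax; extrapolating second phase",
            stacklevel=2,
        )
    lower = spec.beta * x**spec.alpha
    upper = spec.beta * spec.xb ** (spec.alpha - spec.lam) * x**spec.lam
    return np.where(x <= spec.xb, lower, upper)


def eval_scaling(spec: VarianceScalingSpec, x) -> np.ndarray:
    """Evaluate h(x, c) elementwise; requires x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("variance scaling is defined for x > 0 only")
    if spec.kind is ScalingKind.CONSTANT:
        return np.ones_like(x)
    return np.where(x <= spec.xb, 1.0, (spec.xb / x) ** spec.c_exp)


def error_density(spec: ErrorDistributionSpec, e) -> np.ndarray:
    """Density of the latent error eps at e (vectorized)."""
    e = np.asarray(e, dtype=float)
    w = spec.component_weights
    s = spec.component_sds
    z = e[..., None] / s
    pdf = np.exp(-0.5 * z**2) / (_SQRT2PI * s)
    return np.sum(w * pdf, axis=-1)


def error_cdf(spec: ErrorDistributionSpec, e) -> np.ndarray:
    """CDF of the latent error eps at e (vectorized)."""
    e = np.asarray(e, dtype=float)
    w = spec.component_weights
    s = spec.component_sds
    return np.sum(w * stats.norm.cdf(e[..., None] / s), axis=-1)


def error_quantile(spec: ErrorDistributionSpec, q) -> np.ndarray:
    """Quantiles of eps.  Closed form for the normal; numerical inversion of
    the mixture CDF otherwise (monotone, |CDF(quantile(q)) - q| < 1e-12)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if spec.law is ErrorLaw.NORMAL:
        return stats.norm.ppf(q, scale=spec.sigma)
    s = spec.component_sds
    smax = float(s.max())
    out = np.empty(q.shape, dtype=float)
    flat_q = np.atleast_1d(q).ravel()
    flat_out = np.empty(flat_q.shape)
    for i, qi in enumerate(flat_q):
        # bracket: the widest component dominates the tails
        lo = stats.norm.ppf(min(qi, 1e-300), scale=smax) - 1.0
        hi = stats.norm.ppf(qi, scale=smax) + 1.0
        flat_out[i] = optimize.brentq(
            lambda e: float(error_cdf(spec, np.array(e)) - qi),
            lo,
            hi,
            xtol=1e-13,
            rtol=8.9e-16,
        )
    out = flat_out.reshape(q.shape)
    return out if q.ndim else float(out)


def response_density(protocol: ProtocolSpec, x, y) -> np.ndarray:
    """Conditional density f(y | x) of the response under the protocol.

    Multiplicative protocols: change of variables through
    ln y = ln w(x) + h(x) * eps gives

        f(y|x) = sum_k pi_k phi((ln y - ln w(x)) / (h(x) s_k)) / (y h(x) s_k)

    which is a lognormal (mixture) density in y.  The density is 0 (not an
    error) for y <= 0.  Additive protocols: N(w(x), sd(x)^2) density.
    """
    x, y = np.broadcast_arrays(
        np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    )
    w = eval_systematic(protocol.systematic, x)
    if protocol.error_structure is not ErrorStructure.MULTIPLICATIVE:
        return stats.norm.pdf(y, loc=w, scale=protocol.additive_sd(x))
    if np.any(w <= 0):
        raise ValueError("multiplicative protocols require w(x) > 0")
    h = eval_scaling(protocol.scaling, x)
    pi_k = protocol.error.component_weights
    s_k = protocol.error.component_sds
    pos = y > 0
    r = np.log(np.where(pos, y, 1.0)) - np.log(w)
    scale = np.multiply.outer(h, s_k)  # (..., k)
    z = r[..., None] / scale
    dens = np.sum(
        pi_k * np.exp(-0.5 * z**2) / (_SQRT2PI * scale), axis=-1
    ) / np.where(pos, y, 1.0)
    return np.where(pos, dens, 0.0)


def response_mean_var(protocol: ProtocolSpec, x) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of y given x.

    Multiplicative: with eps a zero-mean normal mixture and t = h(x),

        E[y|x]   = w(x) * sum_k pi_k exp(t^2 s_k^2 / 2)
        E[y^2|x] = w(x)^2 * sum_k pi_k exp(2 t^2 s_k^2)

    (lognormal moment identities applied per component).  Additive: mean
    w(x), variance sd(x)^2.
    """
    x = np.asarray(x, dtype=float)
    w = eval_systematic(protocol.systematic, x)
    if protocol.error_structure is not ErrorStructure.MULTIPLICATIVE:
        sd = protocol.additive_sd(x)
        return w, sd**2
    h = eval_scaling(protocol.scaling, x)
    pi_k = protocol.error.component_weights
    s_k = protocol.error.component_sds
    t2 = np.multiply.outer(h**2, s_k**2)  # (..., k)
    m1 = np.sum(pi_k * np.exp(0.5 * t2), axis=-1)
    m2 = np.sum(pi_k * np.exp(2.0 * t2), axis=-1)
    mean = w * m1
    var = w**2 * (m2 - m1**2)
    return mean, var


# ---------------------------------------------------------------------------
# flat-config serialization
# ---------------------------------------------------------------------------


def spec_to_config(protocol: ProtocolSpec) -> dict:
    """Flatten a protocol to a plain key-value mapping (YAML/JSON friendly)."""
    s = protocol.systematic
    cfg: dict = {
        "error_structure": protocol.error_structure.value,
        "family": s.family.value,
        "beta": s.beta,
        "alpha": s.alpha,
    }
    for key in ("lam", "xb", "c0", "xmax"):
        val = getattr(s, key)
        if val is not None:
            cfg[key] = val
    cfg["scaling.kind"] = protocol.scaling.kind.value
    if protocol.scaling.kind is ScalingKind.PIECEWISE:
        cfg["scaling.c_exp"] = protocol.scaling.c_exp
    cfg["error.law"] = protocol.error.law.value
    if protocol.error.law is ErrorLaw.NORMAL:
        cfg["error.sigma"] = protocol.error.sigma
    else:
        cfg["error.weights"] = list(protocol.error.weights)
        cfg["error.sds"] = list(protocol.error.sds)
    if protocol.bp_k is not None:
        cfg["bp_k"] = protocol.bp_k
    return cfg


def spec_from_config(cfg: dict) -> ProtocolSpec:
    """Inverse of :func:`spec_to_config`."""
    systematic = SystematicSpec(
        family=Family(cfg["family"]),
        beta=float(cfg["beta"]),
        alpha=float(cfg["alpha"]),
        lam=cfg.get("lam"),
        xb=cfg.get("xb"),
        c0=cfg.get("c0"),
        xmax=cfg.get("xmax"),
    )
    kind = ScalingKind(cfg.get("scaling.kind", "1"))
    if kind is ScalingKind.PIECEWISE:
        scaling = VarianceScalingSpec(
            kind=kind, c_exp=float(cfg["scaling.c_exp"]), xb=float(cfg["xb"])
        )
    else:
        scaling = VarianceScalingSpec()
    law = ErrorLaw(cfg["error.law"])
    if law is ErrorLaw.NORMAL:
        error = ErrorDistributionSpec(law=law, sigma=float(cfg["error.sigma"]))
    else:
        error = ErrorDistributionSpec(
            law=law,
            weights=tuple(cfg["error.weights"]),
            sds=tuple(cfg["error.sds"]),
        )
    return ProtocolSpec(
        error_structure=ErrorStructure(cfg["error_structure"]),
        systematic=systematic,
        scaling=scaling,
        error=error,
        bp_k=cfg.get("bp_k"),
    )
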