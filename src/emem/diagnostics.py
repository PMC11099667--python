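"""Residual, Q–Q, kurtosis and prediction-strip diagnostics.

These reproduce the graphical model-criticism toolkit used alongside the
EMEM family: standardized latent-error residuals, Q–Q plots against normal
or normal-mixture references (and their exponential, lognormal-type
counterparts), a heavy-tail kurtosis check, and pointwise prediction strips
around the fitted mean response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_model import (
    AllometryDataset,
    ErrorDistributionSpec,
    ErrorStructure,
    eval_scaling,
    eval_systematic,
    error_quantile,
)
from .likelihood_fit import ProtocolFit

__all__ = [
    "DiagnosticReport",
    "standardized_residuals",
    "qq_against",
    "kurtosis_check",
    "mean_response_strip",
    "diagnostic_report",
    "plot_report",
]

# Sample kurtosis above this flags heavy tails (normal reference is 3; at the
# sample sizes this package targets, n >= 1000, the threshold sits far above
# normal sampling noise).
HEAVY_TAIL_KURTOSIS = 4.0


@dataclass
class DiagnosticReport:
    residuals: np.ndarray
    qq_pairs: np.ndarray  # (n, 2): theoretical, empirical
    kurtosis: float
    heavy_tails_flag: bool
    strip: tuple  # (x grid, lower, upper)

    def to_dict(self) -> dict:
        grid, lo, hi = self.strip
        return {
            "kurtosis": self.kurtosis,
            "heavy_tails_flag": self.heavy_tails_flag,
            "qq_theoretical": self.qq_pairs[:, 0].tolist(),
            "qq_empirical": self.qq_pairs[:, 1].tolist(),
            "strip_x": list(map(float, grid)),
            "strip_lower": list(map(float, lo)),
            "strip_upper": list(map(float, hi)),
        }


def standardized_residuals(fit: ProtocolFit, data: AllometryDataset) -> np.ndarray:
    """Latent-error residuals on the scale of the fitted error law.

    Multiplicative protocols: eps_i = (ln y_i - ln w(x_i)) / h(x_i), which is
    distributed as the fitted error law when the model is correct — the
    division by h removes any piecewise heteroscedastic pattern.  Additive
    protocols: (y_i - w(x_i)) / sd(x_i).
    """
    if not fit.converged:
        raise ValueError("residuals require a converged fit")
    spec = fit.spec_hat
    w = eval_systematic(spec.systematic, data.x)
    if spec.error_structure is ErrorStructure.MULTIPLICATIVE:
        data.require_positive()
        h = eval_scaling(spec.scaling, data.x)
        return (np.log(data.y) - np.log(w)) / h
    return (data.y - w) / spec.additive_sd(data.x)


def qq_against(
    error_spec: ErrorDistributionSpec,
    residuals: np.ndarray,
    scale: str = "eps",
) -> np.ndarray:
    """Quantile–quantile pairs of residuals against a reference error law.

    Plotting positions are (i - 0.5)/n.  ``scale="eps"`` compares on the
    latent-error scale (normal / normal-mixture reference); ``scale="exp"``
    exponentiates both axes, giving the lognormal / lognormal-mixture
    comparison used for multiplicative responses.
    """
    e = np.sort(np.asarray(residuals, dtype=float))
    n = e.size
    if n < 10:
        raise ValueError("need at least 10 residuals for a Q-Q construction")
    if not np.all(np.isfinite(e)):
        raise ValueError("residuals must be finite")
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = error_quantile(error_spec, probs)
    if scale == "exp":
        return np.column_stack([np.exp(theo), np.exp(e)])
    if scale != "eps":
        raise ValueError("scale must be 'eps' or 'exp'")
    return np.column_stack([theo, e])


def kurtosis_check(residuals: np.ndarray) -> tuple[float, bool]:
    """Sample kurtosis (fourth standardized moment, normal => 3.0) and a
    heavy-tail flag at the package threshold."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 4:
        raise ValueError("kurtosis needs at least 4 observations")
    centered = e - e.mean()
    m2 = np.mean(centered**2)
    if m2 == 0:
        raise ValueError("residuals have zero variance")
    kurt = float(np.mean(centered**4) / m2**2)
    return kurt, kurt > HEAVY_TAIL_KURTOSIS


def mean_response_strip(
    fit: ProtocolFit,
    x_grid: np.ndarray,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise prediction strip for individual responses.

    Multiplicative protocols:
        [w(x) * exp(h(x) q_lo), w(x) * exp(h(x) q_hi)]
    with q_lo, q_hi the (1-level)/2 and (1+level)/2 quantiles of the fitted
    latent error law — so the strip inherits the piecewise heteroscedastic
    narrowing beyond the breakpoint.  Additive protocols: w(x) ± z * sd(x).
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    if not fit.converged:
        raise ValueError("strip requires a converged fit")
    spec = fit.spec_hat
    x_grid = np.asarray(x_grid, dtype=float)
    w = eval_systematic(spec.systematic, x_grid)
    q = np.array([(1 - level) / 2, (1 + level) / 2])
    if spec.error_structure is ErrorStructure.MULTIPLICATIVE:
        h = eval_scaling(spec.scaling, x_grid)
        q_lo, q_hi = error_quantile(spec.error, q)
        return x_grid, w * np.exp(h * q_lo), w * np.exp(h * q_hi)
    # additive: quantiles of eps scale with the covariate-dependent deviation
    z_lo, z_hi = error_quantile(spec.error, q) / spec.error.sigma
    sd = spec.additive_sd(x_grid)
    return x_grid, w + sd * z_lo, w + sd * z_hi


def diagnostic_report(
    fit: ProtocolFit,
    data: AllometryDataset,
    level: float = 0.95,
    grid_size: int = 200,
) -> DiagnosticReport:
    """Bundle residuals, Q–Q pairs, kurtosis and the prediction strip."""
    eps = standardized_residuals(fit, data)
    qq = qq_against(fit.spec_hat.error, eps)
    kurt, flag = kurtosis_check(eps)
    grid = np.linspace(float(np.min(data.x)), float(np.max(data.x)), grid_size)
    grid = grid[grid > 0]
    strip = mean_response_strip(fit, grid, level=level)
    return DiagnosticReport(
        residuals=eps, qq_pairs=qq, kurtosis=kurt,
        heavy_tails_flag=flag, strip=strip,
    )


def plot_report(
    report: DiagnosticReport,
    data: AllometryDataset,
    fit: ProtocolFit,
    path: Optional[str] = None,
):
    """Four-panel figure: spread + strip, residual plot, Q-Q, log-scale view."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    grid, lo, hi = report.strip
    w = eval_systematic(fit.spec_hat.systematic, grid)
    ax = axes[0, 0]
    ax.scatter(data.x, data.y, s=2, alpha=0.3)
    ax.plot(grid, w, "r-", lw=1.5)
    ax.plot(grid, lo, "r--", lw=1)
    ax.plot(grid, hi, "r--", lw=1)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"spread about {fit.label}")
    ax = axes[0, 1]
    pred = eval_systematic(fit.spec_hat.systematic, data.x)
    ax.scatter(pred, report.residuals, s=2, alpha=0.3)
    ax.axhline(0.0, color="r", lw=1)
    ax.set_xlabel("fitted mean response")
    ax.set_ylabel("standardized residual")
    ax.set_title("residual plot")
    ax = axes[1, 0]
    ax.scatter(report.qq_pairs[:, 0], report.qq_pairs[:, 1], s=2)
    lim = [report.qq_pairs.min(), report.qq_pairs.max()]
    ax.plot(lim, lim, "r-", lw=1)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("empirical quantile")
    ax.set_title(f"Q-Q (kurtosis={report.kurtosis:.2f})")
    ax = axes[1, 1]
    ax.scatter(np.log(data.x), np.log(data.y), s=2, alpha=0.3)
    ax.plot(np.log(grid), np.log(w), "r-", lw=1.5)
    ax.set_xlabel("ln x")
    ax.set_ylabel("ln y")
    ax.set_title("log-scale view (graph assessment only)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
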