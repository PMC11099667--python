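"""AIC and concordance-based comparison of fitted protocols.

Builds the ranked comparison table (label, AIC, ΔAIC, CCC) together with the
reproducibility statistics SEE (standard error of estimate), MPE (mean
prediction error, percent) and RAD (relative absolute deviation of grouped
means).  Predictions everywhere are the model mean response μ(y|x) —
including the lognormal-type exp(h²s²/2) correction for multiplicative
protocols — not the bare systematic part.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import AllometryDataset, response_mean_var
from .likelihood_fit import ProtocolFit

__all__ = [
    "ComparisonTable",
    "aic_delta",
    "ccc",
    "predictive_stats",
    "rad_index",
    "compare",
]


@dataclass
class ComparisonTable:
    """Rows ranked by descending AIC (worst model first, best last)."""

    rows: pd.DataFrame
    best_label: str

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_text(self) -> str:
        cols = [c for c in ("label", "aic", "delta_aic", "ccc", "see", "mpe", "rad")
                if c in self.rows.columns]
        return self.rows[cols].to_string(
            index=False,
            float_format=lambda f: f"{f:.4f}",
        )


def aic_delta(fits: Sequence[ProtocolFit]) -> ComparisonTable:
    """AIC and ΔAIC (versus the minimum) for a set of fits on one dataset."""
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    aics = np.array([f.aic for f in fits], dtype=float)
    delta = aics - aics.min()
    rows = pd.DataFrame(
        {
            "label": [f.label for f in fits],
            "aic": aics,
            "delta_aic": delta,
            "n_params": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
        }
    ).sort_values("aic", ascending=False, kind="mergesort").reset_index(drop=True)
    best = rows.loc[rows["aic"].idxmin(), "label"]
    return ComparisonTable(rows=rows, best_label=str(best))


def ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 cov(o, p) / (var(o) + var(p) + (mean(o) - mean(p))^2)

    with population (1/n) moment denominators, penalizing both location and
    scale departures from the 45-degree line; -1 <= rho_c <= 1.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-d and congruent")
    if o.size < 2:
        raise ValueError("need at least two pairs")
    vo = np.var(o)
    vp = np.var(p)
    if vo == 0 and vp == 0:
        raise ValueError("both vectors are constant")
    cov = np.mean((o - o.mean()) * (p - p.mean()))
    return float(2.0 * cov / (vo + vp + (o.mean() - p.mean()) ** 2))


def predictive_stats(fit: ProtocolFit, data: AllometryDataset) -> tuple[float, float]:
    """(SEE, MPE): standard error of estimate and mean prediction error.

    SEE = sqrt(sum (y_i - yhat_i)^2 / (n - q)) with q the number of fitted
    parameters; MPE = 100 * SEE / mean(y) (percent).  Predictions yhat are
    the model mean response.
    """
    if not fit.converged:
        raise ValueError("predictive statistics require a converged fit")
    q = fit.n_params
    if data.n <= q:
        raise ValueError("more parameters than observations")
    yhat, _ = response_mean_var(fit.spec_hat, data.x)
    see = float(np.sqrt(np.sum((data.y - yhat) ** 2) / (data.n - q)))
    mpe = float(100.0 * see / np.mean(data.y))
    return see, mpe


def rad_index(observed_group_means, predicted_group_means) -> float:
    """Relative absolute deviation of overall means of per-group means.

    RAD = |mean_g(obs_g) - mean_g(pred_g)| / mean_g(obs_g).  This is a
    mean-level agreement index: compensating per-group errors cancel.
    """
    o = np.asarray(observed_group_means, dtype=float)
    p = np.asarray(predicted_group_means, dtype=float)
    if o.shape != p.shape or o.size < 1:
        raise ValueError("group mean vectors must be congruent and non-empty")
    mo = o.mean()
    if mo == 0:
        raise ValueError("overall observed mean is zero")
    return float(abs(mo - p.mean()) / mo)


def _group_means(values: np.ndarray, group: np.ndarray) -> np.ndarray:
    df = pd.DataFrame({"g": group, "v": values})
    return df.groupby("g", sort=True)["v"].mean().to_numpy()


def compare(
    fits: Sequence[ProtocolFit],
    data: AllometryDataset,
    grouped_ccc: bool = False,
) -> ComparisonTable:
    """Full comparison table: AIC, ΔAIC, CCC, SEE, MPE and (when the dataset
    carries group labels) RAD.

    ``grouped_ccc=True`` computes CCC on per-group means instead of raw
    pairs.
    """
    table = aic_delta(fits)
    by_label = {f.label: f for f in fits}
    cccs, sees, mpes, rads = [], [], [], []
    for label in table.rows["label"]:
        f = by_label[label]
        yhat, _ = response_mean_var(f.spec_hat, data.x)
        if grouped_ccc:
            if data.group is None:
                raise ValueError("grouped CCC requires group labels")
            cccs.append(ccc(_group_means(data.y, data.group),
                            _group_means(yhat, data.group)))
        else:
            cccs.append(ccc(data.y, yhat))
        see, mpe = predictive_stats(f, data)
        sees.append(see)
        mpes.append(mpe)
        if data.group is not None:
            rads.append(rad_index(_group_means(data.y, data.group),
                                  _group_means(yhat, data.group)))
    table.rows["ccc"] = cccs
    table.rows["see"] = sees
    table.rows["mpe"] = mpes
    if data.group is not None:
        table.rows["rad"] = rads
    return table
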