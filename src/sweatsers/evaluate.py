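"""Regression metrics, Bland-Altman agreement, and box summaries.

Small, exactly specified statistics used to score the quantifier:
coefficient of determination and RMSE on held-out predictions,
Bland-Altman bias with 95% limits of agreement for method comparison, and
per-true-level quartile summaries (median / quartiles / 1.5 IQR whiskers,
linear "type 7" quantile interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _paired(pred, true) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return p, t


def r_squared(pred, true) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot about mean(true)."""
    p, t = _paired(pred, true)
    if len(t) < 2:
        raise ValueError("need at least 2 points for R^2")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("true values are constant; R^2 undefined")
    ss_res = float(np.sum((p - t) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(pred, true) -> float:
    """Root-mean-square error, in the labels' physical units."""
    p, t = _paired(pred, true)
    if len(t) == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def bland_altman(pred, true) -> dict:
    """Agreement analysis of paired measurements.

    Differences d = pred - true; bias = mean(d); 95% limits of agreement
    = bias +/- 1.96 * sd(d).
    """
    p, t = _paired(pred, true)
    if len(t) < 3:
        raise ValueError("need at least 3 pairs for Bland-Altman")
    d = p - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd": sd,
        "differences": d,
        "means": (p + t) / 2.0,
    }


def box_summary(pred, true_levels) -> pd.DataFrame:
    """Per-true-level box statistics of the predictions.

    One row per distinct level: median, quartiles (linear interpolation),
    whisker bounds at Q1 - 1.5 IQR and Q3 + 1.5 IQR, and the outliers
    beyond them.
    """
    p, t = _paired(pred, true_levels)
    if len(t) == 0:
        raise ValueError("empty input")
    rows = []
    for level in np.unique(t):
        vals = p[t == level]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        rows.append(
            {
                "level": float(level),
                "n": int(len(vals)),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(lo),
                "whisker_high": float(hi),
                "outliers": vals[(vals < lo) | (vals > hi)].tolist(),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Per-metabolite evaluation bundle from cross-validation output."""

    cv_metrics: pd.DataFrame  # rows: repeat x metabolite, columns r2 / rmse
    bland_altman: dict[str, dict] = field(default_factory=dict)
    box_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Min / mean / max R^2 and mean RMSE per metabolite."""
        g = self.cv_metrics.groupby("metabolite")
        out = g.agg(
            r2_min=("r2", "min"),
            r2_mean=("r2", "mean"),
            r2_max=("r2", "max"),
            rmse_mean=("rmse", "mean"),
            rmse_sd=("rmse", "std"),
        )
        return out.reset_index()

    def to_json_dict(self) -> dict:
        payload = {"summary": self.summary().to_dict(orient="records")}
        payload["bland_altman"] = {
            m: {k: v for k, v in ba.items() if np.isscalar(v)}
            for m, ba in self.bland_altman.items()
        }
        return payload


def report(
    cv_metrics: pd.DataFrame,
    predictions: dict[str, np.ndarray] | None = None,
    truths: dict[str, np.ndarray] | None = None,
) -> EvalReport:
    """Assemble an :class:`EvalReport`, adding agreement and box summaries
    when per-metabolite prediction/truth vectors are supplied."""
    rep = EvalReport(cv_metrics=cv_metrics)
    if predictions and truths:
        for m, pred in predictions.items():
            true = truths[m]
            rep.bland_altman[m] = bland_altman(pred, true)
            rep.box_summaries[m] = box_summary(pred, true)
    return rep


def plot_bland_altman(ba: dict, ax=None, title: str = ""):
    """Scatter of differences vs means with bias and limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba["means"], ba["differences"], s=8, alpha=0.6)
    for y, style in ((ba["bias"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(y, linestyle=style, color="crimson")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (pred - true)")
    if title:
        ax.set_title(title)
    return ax
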