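"""Accuracy metrics and agreement analysis against measured GFR.

All metrics are computed on the 1.73 m^2-normalized scale.  The comparison
report has one row per estimation equation (13) plus a ``decision_tree``
row for the selector dispatch, mirroring a per-method RMSE/MAE/Bland-Altman
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import cart
from .cohort import record_covariate_row
from .equations import (
    CANDIDATE_EQUATIONS,
    EquationId,
    MissingInputError,
    estimate_egfr,
)

__all__ = [
    "rmse",
    "mae",
    "BlandAltman",
    "bland_altman",
    "summary_stats",
    "comparison_report",
    "bland_altman_pairs",
    "plot_deviation_box",
    "plot_bland_altman",
]

DISPATCH_METHOD = "decision_tree"


def _pair(predicted, actual) -> tuple:
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return p, a


def rmse(predicted, actual) -> float:
    """Root mean square error, sqrt(mean((predicted - actual)^2))."""
    p, a = _pair(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def mae(predicted, actual) -> float:
    """Mean absolute error."""
    p, a = _pair(predicted, actual)
    return float(np.mean(np.abs(p - a)))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(predicted, actual, *, loa_multiplier: float = 1.96) -> BlandAltman:
    """Bland-Altman agreement summary of predicted vs actual.

    Differences are predicted - actual; the bias is their mean and the
    limits of agreement are bias +/- ``loa_multiplier`` * sample SD (ddof 1).
    ``means`` holds the per-pair average of the two methods for plotting.
    """
    p, a = _pair(predicted, actual)
    if p.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = p - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        means=(p + a) / 2.0,
        diffs=d,
    )


def summary_stats(values) -> tuple:
    """(mean, P25, P75) with percentiles by linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return float(np.mean(v)), float(np.percentile(v, 25)), float(np.percentile(v, 75))


# ---------------------------------------------------------------------------
# per-method report
# ---------------------------------------------------------------------------

def _method_estimates(labeled, subset: str, cg_numerator: str) -> pd.DataFrame:
    """Long table (method, patient_id, egfr, sgfr_norm) for the 13 equations
    plus the selector dispatch on the requested split."""
    rows = []
    for rec, pred_eq in labeled.iter_records(subset):
        sgfr_norm = rec.sgfr_norm
        if sgfr_norm is None:
            continue
        for eq in EquationId:
            try:
                v = estimate_egfr(eq, rec, cg_numerator=cg_numerator).value
            except MissingInputError:
                continue
            rows.append((eq.value, rec.patient_id, v, sgfr_norm))
        dispatched = estimate_egfr(pred_eq, rec, cg_numerator=cg_numerator).value
        rows.append((DISPATCH_METHOD, rec.patient_id, dispatched, sgfr_norm))
    return pd.DataFrame(rows, columns=["method", "patient_id", "egfr", "sgfr_norm"])


def comparison_report(
    labeled,
    tree: Optional[cart.TreeNode] = None,
    *,
    subset: str = "test",
    loa_multiplier: float = 1.96,
    cg_numerator: str = "weight",
) -> pd.DataFrame:
    """Per-method accuracy table on one split of a labeled cohort.

    Parameters
    ----------
    labeled:
        A :class:`~egfr_selector.pipeline.LabeledCohort`.
    tree:
        Fitted selector; when given, dispatch predictions come from it,
        otherwise the cohort must already carry predictions.
    subset:
        ``"test"`` (default), ``"train"`` or ``"total"``.

    Returns
    -------
    DataFrame with columns method, rmse, mae, bias, loa_low, loa_high,
    mean, p25, p75, n -- 14 rows (13 equations + ``decision_tree``).
    """
    if tree is not None:
        labeled = labeled.with_predictions(tree)
    long = _method_estimates(labeled, subset, cg_numerator)
    if long.empty:
        raise ValueError(f"no evaluable rows in subset {subset!r}")
    out = []
    methods = [eq.value for eq in EquationId] + [DISPATCH_METHOD]
    for method in methods:
        sub = long[long["method"] == method]
        if sub.empty:
            continue
        ba = bland_altman(sub["egfr"], sub["sgfr_norm"], loa_multiplier=loa_multiplier)
        mean, p25, p75 = summary_stats(sub["egfr"])
        out.append(
            {
                "method": method,
                "rmse": rmse(sub["egfr"], sub["sgfr_norm"]),
                "mae": mae(sub["egfr"], sub["sgfr_norm"]),
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "mean": mean,
                "p25": p25,
                "p75": p75,
                "n": len(sub),
            }
        )
    return pd.DataFrame(out)


def bland_altman_pairs(
    labeled,
    tree: Optional[cart.TreeNode] = None,
    *,
    subset: str = "test",
    cg_numerator: str = "weight",
) -> pd.DataFrame:
    """Per-pair (mean, difference) data for Bland-Altman plotting, long
    format over all 14 methods."""
    if tree is not None:
        labeled = labeled.with_predictions(tree)
    long = _method_estimates(labeled, subset, cg_numerator)
    long["mean_pair"] = (long["egfr"] + long["sgfr_norm"]) / 2.0
    long["diff"] = long["egfr"] - long["sgfr_norm"]
    return long[["method", "patient_id", "mean_pair", "diff"]]


# ---------------------------------------------------------------------------
# optional plotting (matplotlib)
# ---------------------------------------------------------------------------

def plot_deviation_box(report_pairs: pd.DataFrame, path) -> None:
    """Box plot of eGFR - sGFR per method (Fig 3 analogue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(dict.fromkeys(report_pairs["method"]))
    data = [report_pairs.loc[report_pairs["method"] == m, "diff"] for m in methods]
    fig, ax = plt.subplots(figsize=(max(8, len(methods)), 5))
    ax.boxplot(data, tick_labels=methods)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("eGFR - sGFR (mL/min/1.73 m$^2$)")
    ax.tick_params(axis="x", rotation=75)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(pairs: pd.DataFrame, method: str, path, *, loa_multiplier=1.96) -> None:
    """Bland-Altman scatter with bias and limit lines for one method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = pairs[pairs["method"] == method]
    if sub.empty:
        raise ValueError(f"no pairs for method {method!r}")
    d = sub["diff"].to_numpy()
    bias = d.mean()
    sd = d.std(ddof=1)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(sub["mean_pair"], d, s=12, alpha=0.6)
    for y, style in ((bias, "-"), (bias - loa_multiplier * sd, "--"), (bias + loa_multiplier * sd, "--")):
        ax.axhline(y, color="crimson", ls=style, lw=1)
    ax.set_xlabel("mean of eGFR and sGFR (mL/min/1.73 m$^2$)")
    ax.set_ylabel("eGFR - sGFR")
    ax.set_title(method)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
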