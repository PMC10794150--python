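"""Reporting: spindle plots, enrichment-activity regression, score exports.

The spindle plot is the standard visual summary of a selection round: every
AND-surviving variant is a point, with the dense core of unselected library
members near the origin and the selective tail reaching up and to the right.
Axes default to x = ln(selectivity) and y = ln(enrichment + 2), the same
transform used when regressing variant activity against enrichment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, EmptyResultError
from .scoring import SCORE_COLUMNS


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares fit of y on x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS fit of ``y`` on ``x`` with the standard slope t-test p-value.

    Constant ``x`` is a degenerate fit and raises.  Constant ``y`` (zero total
    sum of squares) is reported as slope 0, r-squared 0 with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise DegenerateFitError("linear_fit needs two equal-length vectors with n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant x: slope is undefined")
    if np.ptp(y) == 0:
        warnings.warn("constant y: zero total sum of squares, reporting r_squared = 0",
                      stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                p_value=float("nan"), n=len(x))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def enrichment_activity_fit(scores: pd.DataFrame, activity: dict[str, float]) -> RegressionResult:
    """Regress measured activity (y) on ln(enrichment + 2) (x) for known variants."""
    rows = scores[scores["variant"].isin(activity)]
    if len(rows) < 3:
        raise DegenerateFitError("need activity values for at least 3 scored variants")
    return linear_fit(rows["ln_score"], [activity[v] for v in rows["variant"]])


def spindle_plot(
    scores: pd.DataFrame,
    path: str | Path,
    highlight: Sequence[str] | None = None,
    x_column: str = "selectivity",
    y_column: str = "enrichment",
    log_x: bool = True,
    title: str | None = None,
) -> Path:
    """Scatter all retained variants; highlighted variants drawn in red.

    Default axes: x = ln(selectivity), y = ln(enrichment + 2).  Highlight keys
    absent from the table are skipped with a warning.  Writes SVG (or any
    format matplotlib infers from the suffix) and returns the path.
    """
    if scores.empty:
        raise EmptyResultError("cannot plot an empty score table")
    x = np.log(scores[x_column].to_numpy(dtype=float)) if log_x \
        else scores[x_column].to_numpy(dtype=float)
    y = np.log(scores[y_column].to_numpy(dtype=float) + 2.0)
    x_label = f"ln({x_column})" if log_x else x_column
    y_label = f"ln({y_column} + 2)"

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=8, c="0.4", alpha=0.6, linewidths=0, label="library variants")
    if highlight:
        wanted = set(highlight)
        missing = wanted - set(scores["variant"])
        if missing:
            warnings.warn(f"highlight keys not in score table, skipped: {sorted(missing)}",
                          stacklevel=2)
        mask = scores["variant"].isin(wanted).to_numpy()
        if mask.any():
            ax.scatter(x[mask], y[mask], s=18, c="crimson", linewidths=0, label="highlighted")
            ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    ax.set_title(title or "spindle plot")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def export_scores(scores: pd.DataFrame, path: str | Path) -> Path:
    """Write a score table as CSV with a stable column order.

    Numeric fields round-trip at full precision through
    :func:`read_scores`.
    """
    cols = [c for c in SCORE_COLUMNS if c in scores.columns]
    cols += [c for c in scores.columns if c not in cols]
    path = Path(path)
    scores[cols].to_csv(path, index=False)
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a score table written by :func:`export_scores`."""
    # keep_default_na: amino-acid keys like "NA" must stay strings
    return pd.read_csv(path, dtype={"variant": str}, float_precision="round_trip",
                       keep_default_na=False, na_values=[""])


def write_run_summary(path: str | Path, **sections) -> Path:
    """Serialise a run summary (seeds, sizes, per-stage record counts) as JSON."""
    path = Path(path)

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    path.write_text(json.dumps(sections, indent=2, default=default) + "\n")
    return path
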