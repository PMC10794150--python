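"""qPCR quantification of pulldown recovery.

A standard curve is fitted by ordinary least squares of Cq against
log10(template copies) over a serial dilution (typically five fivefold
steps).  Amplification efficiency follows the standard relation

    efficiency = 10 ** (-1 / slope) - 1

so a perfectly efficient assay (template doubling per cycle) has slope
-1/log10(2) = -3.321928 and efficiency 1.0.  Unknown samples are quantified
by averaging their replicate Cq values (arithmetic mean of Cq, the dominant
qPCR convention) and inverting the curve.  Pulldown recovery is reported as
percent of input, 100 * (molecules after pulldown / molecules in input).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidCurveError


@dataclass(frozen=True)
class StandardCurve:
    """A fitted qPCR standard curve: Cq = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction (1.0 = 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Cq against log10(copies).

    ``points`` are (copies, Cq) pairs; at least two distinct positive copy
    numbers are required and the fitted slope must be negative (more template
    cannot raise Cq).
    """
    pts = list(points)
    if any(c <= 0 for c, _ in pts):
        raise InvalidCurveError("copy numbers must be positive")
    copies = np.array([c for c, _ in pts], dtype=float)
    cq = np.array([q for _, q in pts], dtype=float)
    if len(np.unique(copies)) < 2:
        raise InvalidCurveError("need at least 2 distinct copy numbers to fit a curve")
    fit = stats.linregress(np.log10(copies), cq)
    if fit.slope >= 0:
        raise InvalidCurveError(f"fitted slope {fit.slope:.4g} is not negative; bad standards?")
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def copies_from_cq(curve: StandardCurve, cq_values: Sequence[float]) -> float:
    """Estimate template copies from replicate Cq values.

    Replicates are combined by the arithmetic mean of Cq before inverting
    ``copies = 10 ** ((Cq - intercept) / slope)``.
    """
    cq = np.asarray(list(cq_values), dtype=float)
    if cq.size == 0:
        raise InvalidCurveError("no Cq values given")
    return float(10.0 ** ((cq.mean() - curve.intercept) / curve.slope))


def percent_input(after_pulldown: float, input_molecules: float) -> float:
    """Pulldown recovery: 100 * (molecules after pulldown / molecules in input)."""
    if input_molecules <= 0:
        raise ValueError("input molecule count must be positive")
    if after_pulldown < 0:
        raise ValueError("molecule counts cannot be negative")
    return 100.0 * after_pulldown / input_molecules


def fold_difference(a: float, b: float) -> float:
    """Fold recovery of ``a`` over ``b`` (e.g. +monomer over -monomer)."""
    if b <= 0:
        raise ValueError("denominator molecule count must be positive")
    return a / b


def serial_dilution(start_copies: float, fold: float = 5.0, steps: int = 5) -> list[float]:
    """Copy numbers of a serial dilution (``steps`` points, ``fold`` per step)."""
    if start_copies <= 0 or fold <= 1 or steps < 2:
        raise InvalidCurveError("dilution needs positive start, fold > 1 and >= 2 steps")
    return [start_copies / fold**k for k in range(steps)]


def quantify_table(table: pd.DataFrame) -> dict:
    """Quantify a tidy qPCR table.

    Expected columns: ``sample_id``, ``role`` ("standard" or "unknown"),
    ``copies`` (standards only) and ``cq``.  Unknown samples may appear on
    multiple rows (qPCR replicates); their Cq values are averaged.  Returns a
    dict with the curve parameters and per-sample copy estimates.
    """
    required = {"sample_id", "role", "cq"}
    if not required <= set(table.columns):
        raise InvalidCurveError(f"qPCR table must have columns {sorted(required)}")
    standards = table[table["role"] == "standard"]
    if standards.empty:
        raise InvalidCurveError("no standard rows in qPCR table")
    curve = fit_standard_curve(list(zip(standards["copies"].astype(float), standards["cq"].astype(float))))
    samples = {}
    for sid, grp in table[table["role"] != "standard"].groupby("sample_id"):
        samples[str(sid)] = copies_from_cq(curve, grp["cq"].astype(float).tolist())
    return {
        "curve": {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "efficiency": curve.efficiency,
        },
        "samples": samples,
    }


def quantify_file(path: str | Path) -> dict:
    """Run :func:`quantify_table` on a TSV file."""
    return quantify_table(pd.read_csv(path, sep="\t"))
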