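"""Enrichment, selectivity and dispersion scoring of a selection round.

The statistics operate on per-sample variant *frequencies* (count divided by
the sample's total count).  Replicate tables are combined in two steps:

* **AND over positive replicates** — only variants observed in every positive
  replicate are retained; a variant missing from any positive replicate is
  dropped.
* **OR into negative and input replicates** — highly enriched variants may be
  absent from the negative and input (naive) samples yet still be of
  interest, so each retained variant missing from such a replicate receives a
  placeholder of 0.95 counts, i.e. frequency ``0.95 / total`` where ``total``
  is that replicate's observed count total (the placeholder is not added to
  the total, which would perturb every other frequency).

Per retained variant, with mean frequencies over replicates:

* enrichment          ``E  = mean positive frequency / mean input frequency``
* negative enrichment ``E- = mean negative frequency / mean input frequency``
* selectivity         ``S  = mean positive frequency / mean negative frequency``
  (identically ``E / E-``; the input frequency cancels)
* dispersion error    ``D  = sd(positive frequencies) / mean(positive
  frequencies)`` — the coefficient of variation across positive replicates,
  with the sample (n-1) standard deviation.

Hits satisfy ``E >= 5``, ``S >= 10`` (inclusive) and ``D <=`` a configurable
ceiling, and are ranked by selectivity.  ``ln(E + 2)`` is the transform used
when regressing enrichment against downstream activity measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyResultError, EmptySampleError, SampleSheetError
from .variant_model import CountTable, SampleSpec, contains_stop, validate_specs

#: Pseudo-count assigned when a negative or input replicate lacks a variant.
DEFAULT_PLACEHOLDER_COUNTS = 0.95
DEFAULT_ENRICHMENT_MIN = 5.0
DEFAULT_SELECTIVITY_MIN = 10.0
DEFAULT_DISPERSION_MAX = 1.0

SCORE_COLUMNS = [
    "variant",
    "mean_pos_freq",
    "mean_neg_freq",
    "mean_input_freq",
    "enrichment",
    "neg_enrichment",
    "selectivity",
    "dispersion",
    "ln_score",
    "contains_stop",
    "n_placeholder_neg",
    "n_placeholder_input",
    "dispersion_defined",
]


@dataclass
class FrequencyTable:
    """Per-sample variant frequencies with the sample totals retained."""

    freqs: dict[str, dict[str, float]]
    totals: dict[str, int]


@dataclass
class VariantMatrix:
    """Replicate-aligned frequencies for the AND-surviving variants."""

    variants: list[str]
    pos_samples: list[str]
    neg_samples: list[str]
    input_samples: list[str]
    pos: np.ndarray            # (n_variants, n_pos)
    neg: np.ndarray            # (n_variants, n_neg)
    inp: np.ndarray            # (n_variants, n_input)
    neg_placeholder: np.ndarray    # bool, same shape as neg
    input_placeholder: np.ndarray  # bool, same shape as inp
    placeholder_counts: float = DEFAULT_PLACEHOLDER_COUNTS


def frequencies(counts: CountTable) -> FrequencyTable:
    """Convert counts to per-sample frequencies (count / sample total)."""
    freqs: dict[str, dict[str, float]] = {}
    totals: dict[str, int] = {}
    for sample_id, variant_counts in counts.counts.items():
        total = sum(variant_counts.values())
        if total <= 0:
            raise EmptySampleError(f"sample {sample_id!r} has zero total counts")
        totals[sample_id] = total
        freqs[sample_id] = {v: c / total for v, c in variant_counts.items()}
    return FrequencyTable(freqs=freqs, totals=totals)


def assemble_variant_matrix(
    freqs: FrequencyTable,
    specs: list[SampleSpec],
    placeholder_counts: float = DEFAULT_PLACEHOLDER_COUNTS,
) -> VariantMatrix:
    """Apply the AND/OR replicate merge and placeholder fill.

    Variants absent from any positive replicate are dropped; each retained
    variant missing from a negative or input replicate gets frequency
    ``placeholder_counts / total`` for that replicate's observed total.
    """
    validate_specs(specs)
    by_cond: dict[str, list[SampleSpec]] = {"positive": [], "negative": [], "input": []}
    for s in specs:
        if s.sample_id not in freqs.freqs:
            raise SampleSheetError(f"sample {s.sample_id!r} has no frequency data")
        by_cond[s.condition].append(s)
    for cond, members in by_cond.items():
        if not members:
            raise SampleSheetError(f"no {cond!r} sample declared")
        members.sort(key=lambda s: s.replicate)

    pos_ids = [s.sample_id for s in by_cond["positive"]]
    neg_ids = [s.sample_id for s in by_cond["negative"]]
    in_ids = [s.sample_id for s in by_cond["input"]]

    retained = set(freqs.freqs[pos_ids[0]])
    for sid in pos_ids[1:]:
        retained &= set(freqs.freqs[sid])
    if not retained:
        raise EmptyResultError(
            "no variant is present in every positive replicate "
            "(failed selection or mislabelled samples?)"
        )
    variants = sorted(retained)

    def fill(sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        mat = np.empty((len(variants), len(sample_ids)))
        placeholder = np.zeros_like(mat, dtype=bool)
        for j, sid in enumerate(sample_ids):
            f = freqs.freqs[sid]
            ph = placeholder_counts / freqs.totals[sid]
            for i, v in enumerate(variants):
                if v in f:
                    mat[i, j] = f[v]
                else:
                    mat[i, j] = ph
                    placeholder[i, j] = True
        return mat, placeholder

    pos, _ = fill(pos_ids)  # never placeholder-filled by construction
    neg, neg_ph = fill(neg_ids)
    inp, in_ph = fill(in_ids)
    return VariantMatrix(
        variants=variants,
        pos_samples=pos_ids,
        neg_samples=neg_ids,
        input_samples=in_ids,
        pos=pos,
        neg=neg,
        inp=inp,
        neg_placeholder=neg_ph,
        input_placeholder=in_ph,
        placeholder_counts=placeholder_counts,
    )


def ln_enrichment(enrichment):
    """The ``ln(E + 2)`` transform used against activity measurements."""
    return np.log(np.asarray(enrichment, dtype=float) + 2.0)


def compute_scores(matrix: VariantMatrix) -> pd.DataFrame:
    """Score every retained variant; returns a tidy score table.

    With a single positive replicate the dispersion error is undefined; it is
    reported as 0 with ``dispersion_defined=False`` and a warning.
    """
    if not matrix.variants:
        raise EmptyResultError("empty variant matrix")
    mean_pos = matrix.pos.mean(axis=1)
    mean_neg = matrix.neg.mean(axis=1)
    mean_inp = matrix.inp.mean(axis=1)
    enrichment = mean_pos / mean_inp
    neg_enrichment = mean_neg / mean_inp
    selectivity = mean_pos / mean_neg
    n_pos = matrix.pos.shape[1]
    if n_pos >= 2:
        dispersion = matrix.pos.std(axis=1, ddof=1) / mean_pos
        defined = True
    else:
        warnings.warn(
            "single positive replicate: dispersion error undefined, reported as 0",
            stacklevel=2,
        )
        dispersion = np.zeros_like(mean_pos)
        defined = False
    return pd.DataFrame(
        {
            "variant": matrix.variants,
            "mean_pos_freq": mean_pos,
            "mean_neg_freq": mean_neg,
            "mean_input_freq": mean_inp,
            "enrichment": enrichment,
            "neg_enrichment": neg_enrichment,
            "selectivity": selectivity,
            "dispersion": dispersion,
            "ln_score": ln_enrichment(enrichment),
            "contains_stop": [contains_stop(v) for v in matrix.variants],
            "n_placeholder_neg": matrix.neg_placeholder.sum(axis=1),
            "n_placeholder_input": matrix.input_placeholder.sum(axis=1),
            "dispersion_defined": defined,
        },
        columns=SCORE_COLUMNS,
    )


def call_hits(
    scores: pd.DataFrame,
    enrichment_min: float = DEFAULT_ENRICHMENT_MIN,
    selectivity_min: float = DEFAULT_SELECTIVITY_MIN,
    dispersion_max: float = DEFAULT_DISPERSION_MAX,
    exclude_stops: bool = True,
) -> pd.DataFrame:
    """Filter and rank hits.

    Inclusive thresholds: a variant with exactly ``E = enrichment_min`` and
    ``S = selectivity_min`` is a hit.  The dispersion ceiling is ignored when
    dispersion is undefined (single positive replicate).  Hits are ranked by
    selectivity, ties broken by enrichment, then lexically by variant key.
    """
    if enrichment_min <= 0 or selectivity_min <= 0 or dispersion_max <= 0:
        raise ValueError("hit thresholds must be positive")
    mask = (scores["enrichment"] >= enrichment_min) & (scores["selectivity"] >= selectivity_min)
    if "dispersion_defined" in scores:
        mask &= ~scores["dispersion_defined"].astype(bool) | (scores["dispersion"] <= dispersion_max)
    else:
        mask &= scores["dispersion"] <= dispersion_max
    if exclude_stops:
        mask &= ~scores["contains_stop"].astype(bool)
    hits = scores.loc[mask].sort_values(
        ["selectivity", "enrichment", "variant"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return hits.reset_index(drop=True)


def annotate_hits(scores: pd.DataFrame, **thresholds) -> pd.DataFrame:
    """Return a copy of the score table with a boolean ``hit`` column."""
    hits = call_hits(scores, **thresholds)
    out = scores.copy()
    out["hit"] = out["variant"].isin(set(hits["variant"]))
    return out


def score_counts(
    counts: CountTable,
    specs: list[SampleSpec],
    placeholder_counts: float = DEFAULT_PLACEHOLDER_COUNTS,
) -> pd.DataFrame:
    """Counts -> frequencies -> AND/OR merge -> score table, in one call."""
    return compute_scores(assemble_variant_matrix(frequencies(counts), specs, placeholder_counts))
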