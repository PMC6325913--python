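"""Ensemble-prediction triage of candidate genes.

Implements the selection funnel applied to a genes × models matrix of raw
function-prediction scores for a target process (here, long-term memory):

1. per-model quantization of raw scores into five-level Q values
   (0 = negative prediction; positive scores binned into quartiles
   0.25 / 0.5 / 0.75 / 1.0 within each model),
2. per-gene aggregation (mean Q, sd Q, model coverage),
3. three-class categorization — "likely positive" (mean Q >= 0.5, covered by
   >= 7 models), "likely negative" (mean Q exactly 0, agreed by >= 7 models)
   and "variable" (mean Q in [0.1, 0.25], sd above the 90% quantile,
   >= 7 models) — everything else uncategorized,
4. exclusion of essential genes and genes already annotated to the target
   term, and
5. seeded stratified random selection of screening candidates per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CategoryThresholds",
    "CategoryAssignment",
    "to_quantile_bins",
    "aggregate_quantiles",
    "categorize",
    "apply_exclusions",
    "select_candidates",
    "Q_LEVELS",
]

logger = logging.getLogger(__name__)

#: The five admissible quantized prediction values.
Q_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)

#: Order in which classes are sampled by select_candidates (fixed for
#: reproducibility of the seeded draw).
_CLASS_ORDER = ("positive", "negative", "variable")


@dataclass(frozen=True)
class CategoryThresholds:
    """Thresholds of the three-class categorization.

    ``sd_quantile_level`` sets the dispersion cutoff for the variable class
    (the realized cutoff is that quantile of sd_Q over genes meeting
    ``min_coverage``). ``population_sd`` switches aggregation elsewhere to
    the population (ddof=0) standard deviation; the default is the sample
    (ddof=1) standard deviation.
    """

    positive_min_mean: float = 0.5
    negative_mean: float = 0.0
    variable_mean_low: float = 0.1
    variable_mean_high: float = 0.25
    sd_quantile_level: float = 0.9
    min_coverage: int = 7

    def __post_init__(self) -> None:
        ok = (
            0
            <= self.negative_mean
            < self.variable_mean_low
            <= self.variable_mean_high
            < self.positive_min_mean
            <= 1
        )
        if not ok:
            raise ValueError(
                "thresholds must satisfy 0 <= negative_mean < variable_mean_low "
                "<= variable_mean_high < positive_min_mean <= 1"
            )
        if not 0 < self.sd_quantile_level < 1:
            raise ValueError("sd_quantile_level must lie in (0, 1)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass(frozen=True)
class CategoryAssignment:
    """Result of categorization: one label per gene plus the realized sd cutoff.

    ``labels`` maps every input gene to exactly one of
    {"positive", "negative", "variable", "uncategorized"}; ``sd_cutoff`` is
    the realized dispersion cutoff used for the variable class; ``excluded``
    flags genes relabeled by :func:`apply_exclusions`.
    """

    labels: pd.Series
    sd_cutoff: float
    excluded: frozenset[str] = field(default_factory=frozenset)

    def genes_in(self, label: str) -> list[str]:
        """Gene ids carrying ``label``, in input order."""
        return list(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in
                ("positive", "negative", "variable", "uncategorized")}


def _validate_scores(raw: pd.DataFrame) -> None:
    vals = raw.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if finite.any() and ((vals[finite] < 0) | (vals[finite] > 1)).any():
        bad = vals[finite][(vals[finite] < 0) | (vals[finite] > 1)][0]
        raise ValueError(f"raw scores must lie in [0, 1]; found {bad}")


def to_quantile_bins(raw: pd.DataFrame) -> pd.DataFrame:
    """Quantize raw prediction scores into five-level Q values, per model.

    Within each model (column), scores equal to 0 — negative predictions —
    map to Q = 0. Strictly positive scores are ranked among that model's
    strictly positive covered scores and assigned a quartile bin
    (lowest quarter -> 0.25, ..., top quarter -> 1.0). Ties receive the bin
    of their average rank. The coverage mask (NaN pattern) is preserved.

    Only the rank order of a model's positive scores matters, so any
    strictly increasing transform of a column's positive scores leaves its
    Q column unchanged.
    """
    _validate_scores(raw)
    out = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    for model in raw.columns:
        col = raw[model].to_numpy(dtype=float)
        covered = np.isfinite(col)
        zero = covered & (col == 0)
        pos = covered & (col > 0)
        q = np.full(col.shape, np.nan)
        q[zero] = 0.0
        n_pos = int(pos.sum())
        if n_pos:
            ranks = stats.rankdata(col[pos])  # average ranks for ties
            q[pos] = np.ceil(4.0 * ranks / n_pos) / 4.0
        out[model] = q
    return out


def aggregate_quantiles(qm: pd.DataFrame, population_sd: bool = False) -> pd.DataFrame:
    """Aggregate a quantized matrix into per-gene (mean_Q, sd_Q, coverage).

    Mean and standard deviation are computed over covering models only; the
    standard deviation uses divisor coverage-1 (sample sd; ``population_sd``
    switches to divisor coverage) and is defined as 0 when coverage is 1.
    Genes covered by no model are omitted (and logged).
    """
    coverage = qm.notna().sum(axis=1)
    dropped = list(qm.index[coverage == 0])
    if dropped:
        logger.info("omitting %d gene(s) with zero model coverage: %s", len(dropped), dropped)
    mean_q = qm.mean(axis=1)
    sd_q = qm.std(axis=1, ddof=0 if population_sd else 1).fillna(0.0)
    out = pd.DataFrame({"mean_Q": mean_q, "sd_Q": sd_q, "coverage": coverage})
    out = out[coverage >= 1]
    out["coverage"] = out["coverage"].astype(int)
    return out


def categorize(aggs: pd.DataFrame, th: CategoryThresholds | None = None) -> CategoryAssignment:
    """Assign each gene one of the three candidate classes (or uncategorized).

    The dispersion cutoff is the ``th.sd_quantile_level`` quantile (linear
    interpolation) of sd_Q over genes meeting ``th.min_coverage``. With the
    default thresholds the three classes are disjoint by construction
    (their mean-Q windows do not overlap); the positive > negative >
    variable precedence is applied for safety under custom thresholds.
    """
    if th is None:
        th = CategoryThresholds()
    if len(aggs) == 0:
        raise ValueError("empty aggregate table")
    eligible = aggs["coverage"] >= th.min_coverage
    if not eligible.any():
        raise ValueError(
            f"no gene meets min_coverage={th.min_coverage}; sd cutoff undefined"
        )
    sd_cutoff = float(np.quantile(aggs.loc[eligible, "sd_Q"], th.sd_quantile_level))

    labels = pd.Series("uncategorized", index=aggs.index, dtype=object)
    mean_q, sd_q = aggs["mean_Q"], aggs["sd_Q"]
    is_positive = eligible & (mean_q >= th.positive_min_mean)
    is_negative = eligible & (mean_q == th.negative_mean) & ~is_positive
    is_variable = (
        eligible
        & (mean_q >= th.variable_mean_low)
        & (mean_q <= th.variable_mean_high)
        & (sd_q > sd_cutoff)
        & ~is_positive
        & ~is_negative
    )
    labels[is_positive] = "positive"
    labels[is_negative] = "negative"
    labels[is_variable] = "variable"
    labels.index.name = "gene"
    return CategoryAssignment(labels=labels, sd_cutoff=sd_cutoff)


def apply_exclusions(
    assignment: CategoryAssignment,
    essential: Iterable[str] = (),
    already_annotated: Iterable[str] = (),
) -> CategoryAssignment:
    """Relabel essential or already-annotated genes as uncategorized.

    Genes in either set become ineligible for selection; all other labels
    are unchanged. Idempotent: a gene in both sets is excluded once.
    """
    drop = (set(essential) | set(already_annotated)) & set(assignment.labels.index)
    labels = assignment.labels.copy()
    labels[list(drop)] = "uncategorized"
    return CategoryAssignment(
        labels=labels,
        sd_cutoff=assignment.sd_cutoff,
        excluded=assignment.excluded | frozenset(drop),
    )


def select_candidates(
    assignment: CategoryAssignment,
    n_per_class: Mapping[str, int],
    seed: int | None = None,
) -> pd.DataFrame:
    """Randomly select screening candidates, stratified by class.

    Uniform sampling without replacement within each class using a seeded
    RNG; deterministic under a fixed seed. Classes are drawn in the fixed
    order positive, negative, variable.

    Returns a DataFrame with columns ``gene`` and ``label``, classes
    concatenated in draw order, genes within a class in draw order.
    """
    unknown = set(n_per_class) - set(_CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown class label(s) in n_per_class: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    for label in _CLASS_ORDER:
        want = int(n_per_class.get(label, 0))
        if want == 0:
            continue
        pool = assignment.genes_in(label)
        if want > len(pool):
            raise ValueError(
                f"requested {want} {label} candidates but only {len(pool)} eligible"
            )
        picked = rng.choice(np.array(pool, dtype=object), size=want, replace=False)
        rows.extend((str(g), label) for g in picked)
    return pd.DataFrame(rows, columns=["gene", "label"])
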