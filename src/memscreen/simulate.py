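"""Synthetic data generators for the triage and screen stages.

Two generators are provided:

* :func:`simulate_scores` builds a genes × models raw prediction-score matrix
  with planted class structure (likely-positive / likely-negative / variable /
  background genes), so the quantile-binning and categorization stage can be
  exercised against known ground truth.

* :func:`simulate_screen` builds a vial-level egg-count table following the
  oviposition-depression screen design: two conditions (wasp-exposed vs
  unexposed), two 24 h scoring periods (acute: 0-24 h of cohabitation;
  memory: 24-48 h after wasp removal), and a fixed number of biological
  replicate vials per condition. Counts are negative binomial around a
  baseline mean, with multiplicative effects when a line carries a true
  depression (or increased-oviposition) response.

:func:`reference_ground_truth` returns the packaged 29-gene screen outcome
table (plus wild-type-behaving control lines) used throughout the test-suite
and the pipeline's simulation fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenDesign",
    "GroundTruthPhenotype",
    "simulate_scores",
    "simulate_screen",
    "reference_ground_truth",
    "reference_metadata",
    "PLANTED_CLASSES",
]

#: Valid planted-class labels for simulate_scores.
PLANTED_CLASSES = ("positive", "negative", "variable", "background")

ACUTE_PHENOTYPES = ("depress", "none", "increase")
MEMORY_PHENOTYPES = ("depress", "none")


@dataclass(frozen=True)
class ScreenDesign:
    """Design parameters of the oviposition-depression screen.

    Defaults mirror the assay design: vials of 10 females (and 5 males),
    12 biological replicate vials per condition, and two 24 h scoring
    periods. ``baseline_mean`` is the expected egg count per vial per 24 h
    period for unexposed flies; ``dispersion`` is the negative-binomial size
    parameter (``math.inf`` recovers a Poisson). ``depress_effect`` and
    ``increase_effect`` multiply the exposed-condition mean when the line
    carries a true depression / increased-oviposition response.
    """

    n_replicates: int = 12
    females_per_vial: int = 10
    baseline_mean: float = 40.0
    dispersion: float = 10.0
    depress_effect: float = 0.5
    increase_effect: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (needed for testing)")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if not 0 < self.depress_effect < 1:
            raise ValueError("depress_effect must lie in (0, 1)")
        if self.increase_effect <= 1:
            raise ValueError("increase_effect must be > 1")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0 (math.inf for Poisson)")


@dataclass(frozen=True)
class GroundTruthPhenotype:
    """True per-line behavioral phenotype used to drive the simulator.

    ``acute`` is the line's true response during wasp cohabitation
    (``depress`` = oviposition depression, ``increase`` = elevated
    oviposition, ``none`` = no response); ``memory`` is the true response in
    the post-removal period (``depress`` or ``none``). ``prior_paradigm``
    flags genes already implicated in this fly-wasp memory paradigm (used to
    count novel hits); ``is_control`` flags non-gene control lines excluded
    from screen tallies.
    """

    line_id: str
    acute: str
    memory: str
    prior_paradigm: bool = False
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.acute not in ACUTE_PHENOTYPES:
            raise ValueError(f"acute must be one of {ACUTE_PHENOTYPES}, got {self.acute!r}")
        if self.memory not in MEMORY_PHENOTYPES:
            raise ValueError(f"memory must be one of {MEMORY_PHENOTYPES}, got {self.memory!r}")


# Per-class raw-score mixtures. Chosen so that, after per-model quantile
# binning, planted positives sit in the top bins across models, negatives
# quantize to Q=0 in every covering model, and variables have low mean /
# high spread (a couple of isolated high scores among zeros).
_POSITIVE_RANGE = (0.70, 1.00)
_VARIABLE_RANGE = (0.70, 1.00)
_VARIABLE_HIGH_FRACTION = 0.2  # fraction of models scoring a variable gene high
_BACKGROUND_RANGE = (0.02, 0.50)
_BACKGROUND_NONZERO_PROB = 0.50


def simulate_scores(
    n_genes: int,
    n_models: int,
    planted: Mapping[str, str] | None = None,
    coverage_prob: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a genes × models raw prediction-score matrix.

    Parameters
    ----------
    n_genes, n_models
        Matrix dimensions. ``n_genes`` may be 0 (empty matrix); ``n_models``
        must be >= 1.
    planted
        Mapping gene id -> planted class, one of ``PLANTED_CLASSES``. Must
        cover exactly ``n_genes`` genes. If None, ``n_genes`` background
        genes named ``g0001``... are generated.
    coverage_prob
        Independent per-cell probability that a model covers a gene;
        uncovered cells are NaN.
    seed
        RNG seed; identical seeds reproduce identical matrices.

    Returns
    -------
    pandas.DataFrame
        Rows = genes, columns = model ids (``m01``...), values = raw scores
        in [0, 1], NaN where not covered.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not 0 < coverage_prob <= 1:
        raise ValueError("coverage_prob must lie in (0, 1]")
    if planted is None:
        planted = {f"g{i + 1:04d}": "background" for i in range(n_genes)}
    if len(planted) != n_genes:
        raise ValueError(f"planted covers {len(planted)} genes, expected {n_genes}")
    for gene, label in planted.items():
        if label not in PLANTED_CLASSES:
            raise ValueError(f"unknown planted label {label!r} for gene {gene!r}")

    rng = np.random.default_rng(seed)
    models = [f"m{j + 1:02d}" for j in range(n_models)]
    genes = list(planted)
    scores = np.zeros((n_genes, n_models))
    for i, gene in enumerate(genes):
        label = planted[gene]
        if label == "positive":
            scores[i] = rng.uniform(*_POSITIVE_RANGE, size=n_models)
        elif label == "negative":
            scores[i] = 0.0
        elif label == "variable":
            # a fixed small number of dissenting high-scoring models among
            # zeros: low mean Q, high spread, by construction
            n_high = max(1, round(_VARIABLE_HIGH_FRACTION * n_models))
            high = rng.choice(n_models, size=n_high, replace=False)
            scores[i, high] = rng.uniform(*_VARIABLE_RANGE, size=n_high)
        else:  # background
            nonzero = rng.random(n_models) < _BACKGROUND_NONZERO_PROB
            vals = rng.uniform(*_BACKGROUND_RANGE, size=n_models)
            scores[i] = np.where(nonzero, vals, 0.0)
    covered = rng.random((n_genes, n_models)) < coverage_prob
    scores = np.where(covered, scores, np.nan)
    return pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=models)


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    """Draw n egg counts with the given mean; NB with size=dispersion, Poisson at inf."""
    if math.isinf(dispersion):
        return rng.poisson(mean, size=n)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def _period_factor(phenotype: str, design: ScreenDesign) -> float:
    if phenotype == "depress":
        return design.depress_effect
    if phenotype == "increase":
        return design.increase_effect
    return 1.0


def simulate_screen(
    truth: Sequence[GroundTruthPhenotype],
    design: ScreenDesign | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a vial-level egg-count table for the two-period screen.

    For every line, condition and period, ``design.n_replicates`` negative-
    binomial counts are drawn. Unexposed vials have mean ``baseline_mean``
    in both periods; exposed vials have the baseline mean multiplied by
    ``depress_effect`` / ``increase_effect`` / 1 according to the line's
    true phenotype for that period.

    Parameters
    ----------
    truth
        Non-empty sequence of :class:`GroundTruthPhenotype`, unique line ids.
    design
        Screen design; defaults to :class:`ScreenDesign` defaults.
    seed
        Overrides ``design.seed`` when given.

    Returns
    -------
    pandas.DataFrame
        Columns ``line_id, condition, period, replicate, egg_count`` with
        conditions ``exposed``/``unexposed`` and periods ``acute``/``memory``.
    """
    if len(truth) == 0:
        raise ValueError("truth must be non-empty")
    ids = [t.line_id for t in truth]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate line_id(s): {dupes}")
    if design is None:
        design = ScreenDesign()
    rng = np.random.default_rng(design.seed if seed is None else seed)

    rows: list[tuple[str, str, str, int, int]] = []
    for line in truth:
        for period, phenotype in (("acute", line.acute), ("memory", line.memory)):
            for condition in ("exposed", "unexposed"):
                mean = design.baseline_mean
                if condition == "exposed":
                    mean *= _period_factor(phenotype, design)
                counts = _draw_counts(rng, mean, design.dispersion, design.n_replicates)
                rows.extend(
                    (line.line_id, condition, period, r + 1, int(c))
                    for r, c in enumerate(counts)
                )
    return pd.DataFrame(
        rows, columns=["line_id", "condition", "period", "replicate", "egg_count"]
    )


# The packaged 29-gene screen outcome. acute/memory give the line's TRUE
# response: "depress" where the published call was Y, "none" where it was N;
# ft and knrl showed a significant oviposition increase during exposure and
# are planted as acute="increase". rut was previously implicated in this
# fly-wasp paradigm.
_REFERENCE_GENES: list[tuple[str, str, str, bool]] = [
    # (gene, acute, memory, prior_paradigm)
    ("ft", "increase", "none", False),
    ("knrl", "increase", "none", False),
    ("TkR86C", "none", "none", False),
    ("sens", "depress", "none", False),
    ("rut", "depress", "none", True),
    ("sna", "depress", "none", False),
    ("5-HT7", "depress", "none", False),
    ("Rnp4F", "depress", "none", False),
    ("Nrk", "depress", "none", False),
    ("Cad87A", "depress", "none", False),
    ("Dop1R1", "depress", "none", False),
    ("Octbeta1R", "depress", "none", False),
    ("Mob4", "depress", "none", False),
    ("mnb", "depress", "none", False),
    ("Dop1R2", "depress", "none", False),
    ("sbr", "depress", "depress", False),
    ("shf", "depress", "depress", False),
    ("GluRIA", "depress", "depress", False),
    ("wdn", "depress", "depress", False),
    ("Snap25", "depress", "depress", False),
    ("sdk", "depress", "depress", False),
    ("CG17119", "depress", "depress", False),
    ("CG18812", "depress", "depress", False),
    ("Oaz", "depress", "depress", False),
    ("Trpm", "depress", "depress", False),
    ("p38c", "depress", "depress", False),
    ("CG12744", "depress", "depress", False),
    ("CG5815", "depress", "depress", False),
    ("Capr", "depress", "depress", False),
]

#: Control lines (wild type, driver-only outcrosses, white-RNAi) behave
#: wild-type: depression in both periods.
_REFERENCE_CONTROLS = [
    "CS",
    "white-RNAi-MB247",
    "MB247-driver",
    "white-RNAi-MB48571",
    "MB48571-driver",
]


def reference_ground_truth(include_controls: bool = True) -> list[GroundTruthPhenotype]:
    """The packaged 29-gene screen ground truth (plus control lines).

    Returns the per-line true phenotypes of the RNAi screen: 3 lines without
    a true acute depression (ft and knrl with increased oviposition, TkR86C
    with none), 12 lines with acute depression but no memory retention, and
    14 lines behaving wild-type, plus (optionally) 5 wild-type-behaving
    control lines flagged ``is_control``.
    """
    truth = [
        GroundTruthPhenotype(g, acute, memory, prior_paradigm=prior)
        for g, acute, memory, prior in _REFERENCE_GENES
    ]
    if include_controls:
        truth.extend(
            GroundTruthPhenotype(c, "depress", "depress", is_control=True)
            for c in _REFERENCE_CONTROLS
        )
    return truth


def reference_metadata() -> pd.DataFrame:
    """Gene metadata for the packaged screen: prior_paradigm flags, one row per gene."""
    truth = reference_ground_truth(include_controls=False)
    return pd.DataFrame(
        {"gene": [t.line_id for t in truth], "prior_paradigm": [t.prior_paradigm for t in truth]}
    ).set_index("gene")
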