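"""Phenotype calling for the oviposition-depression RNAi screen.

The assay: vials of flies are scored for eggs laid per 24 h period under two
conditions (wasp-exposed vs unexposed) and two periods (acute = 0-24 h of
cohabitation; memory = 24-48 h after wasp removal). A line shows an *acute
response* when exposed vials lay significantly fewer eggs than unexposed
vials during the acute period, and a *memory response* when the depression
persists in the memory period. Significance is Welch's two-tailed t-test on
raw per-vial counts at alpha = 0.05; a significant *increase* in oviposition
is scored as response absent (N) but retained via a direction flag.

Screen classes:

* ``acute_required`` — acute call N: the gene is needed to mount the response
  at all, so its role in memory cannot be teased apart;
* ``memory_required`` — acute Y, memory N: the long-term-memory hits;
* ``wildtype_response`` — Y/Y, behaves like wild type.

The statsmodels-style surface is :class:`OvipositionScreen` (model built
from a vial-level count table) whose :meth:`~OvipositionScreen.fit` returns
a :class:`ScreenResults` carrying per-line calls, normalized responses,
p-values, the class tally and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "NormalizedResponse",
    "PhenotypeCall",
    "ScreenSummary",
    "welch_t_test",
    "normalize_oviposition",
    "call_phenotype",
    "classify_screen",
    "OvipositionScreen",
    "ScreenResults",
]

CLASS_LABELS = ("acute_required", "memory_required", "wildtype_response")


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test: statistic, Welch-Satterthwaite df, two-tailed p."""

    t: float
    df: float
    p: float


@dataclass(frozen=True)
class NormalizedResponse:
    """Mean exposed eggs as a percentage of mean unexposed eggs, with SEM.

    ``sem`` is the standard error of the per-replicate normalized values
    100 * exposed_i / mean(unexposed) over the exposed replicates.
    """

    line_id: str
    period: str
    percent: float
    sem: float


@dataclass(frozen=True)
class PhenotypeCall:
    """Directional binary acute/memory call for one line.

    A period's call is Y exactly when the Welch p-value is below ``alpha``
    AND the exposed mean is lower than the unexposed mean; significant
    increases are recorded in the direction field but called N.
    """

    line_id: str
    acute: str  # "Y" | "N"
    memory: str
    direction_acute: str  # "decrease" | "increase" | "none"
    direction_memory: str
    p_acute: float
    p_memory: float
    alpha: float


@dataclass(frozen=True)
class ScreenSummary:
    """Class tally over tested genes (controls excluded).

    ``n_novel_memory`` counts memory-required genes not flagged
    prior-paradigm. The three class counts partition ``n_tested``.
    """

    n_tested: int
    n_acute_required: int
    n_memory_required: int
    n_wildtype: int
    n_novel_memory: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        total = self.n_acute_required + self.n_memory_required + self.n_wildtype
        if total != self.n_tested:
            raise AssertionError(
                f"class counts {total} do not partition n_tested={self.n_tested}"
            )


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's two-tailed t-test for unequal-variance samples.

    t = (mean x - mean y) / sqrt(s2x/nx + s2y/ny), with degrees of freedom
    by the Welch-Satterthwaite approximation and p the two-tailed tail mass
    of Student's t. Degenerate inputs: if both sample variances are zero the
    test statistic is 0 (p = 1) for equal means and +/-inf (p = 0)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0)
        return WelchResult(t=math.copysign(math.inf, mx - my), df=float(nx + ny - 2), p=0.0)
    t = (mx - my) / math.sqrt(se2)
    # Welch-Satterthwaite, written with the variance fractions a+b=1 so the
    # ratio cannot underflow for near-constant samples
    a = (vx / nx) / se2
    b = (vy / ny) / se2
    df = 1.0 / (a * a / (nx - 1) + b * b / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def _stratum(table: pd.DataFrame, line_id: str, condition: str, period: str) -> np.ndarray:
    mask = (
        (table["line_id"] == line_id)
        & (table["condition"] == condition)
        & (table["period"] == period)
    )
    counts = table.loc[mask, "egg_count"].to_numpy(dtype=float)
    if counts.size == 0:
        raise ValueError(f"missing stratum: line={line_id!r} condition={condition!r} period={period!r}")
    return counts


def normalize_oviposition(table: pd.DataFrame, line_id: str, period: str) -> NormalizedResponse:
    """Percentage of eggs laid by exposed flies normalized to unexposed flies.

    percent = 100 * mean(exposed) / mean(unexposed); sem is the standard
    error of {100 * exposed_i / mean(unexposed)} over exposed replicates.
    """
    exposed = _stratum(table, line_id, "exposed", period)
    unexposed = _stratum(table, line_id, "unexposed", period)
    mu_u = unexposed.mean()
    if mu_u == 0:
        raise ValueError(f"unexposed mean is zero for line={line_id!r} period={period!r}; normalization undefined")
    scaled = 100.0 * exposed / mu_u
    sem = float(scaled.std(ddof=1) / math.sqrt(len(scaled))) if len(scaled) > 1 else 0.0
    return NormalizedResponse(line_id=line_id, period=period, percent=float(scaled.mean()), sem=sem)


def _direction(exposed: np.ndarray, unexposed: np.ndarray) -> str:
    if exposed.mean() < unexposed.mean():
        return "decrease"
    if exposed.mean() > unexposed.mean():
        return "increase"
    return "none"


def call_phenotype(table: pd.DataFrame, line_id: str, alpha: float = 0.05) -> PhenotypeCall:
    """Directional binary acute/memory call for one line.

    Per period, Welch's two-tailed test compares exposed vs unexposed raw
    per-vial counts; the call is Y only when p < alpha and the exposed mean
    is below the unexposed mean (response = oviposition depression).
    """
    results: dict[str, tuple[str, str, float]] = {}
    for period in ("acute", "memory"):
        exposed = _stratum(table, line_id, "exposed", period)
        unexposed = _stratum(table, line_id, "unexposed", period)
        welch = welch_t_test(exposed, unexposed)
        direction = _direction(exposed, unexposed)
        call = "Y" if (welch.p < alpha and direction == "decrease") else "N"
        results[period] = (call, direction, welch.p)
    return PhenotypeCall(
        line_id=line_id,
        acute=results["acute"][0],
        memory=results["memory"][0],
        direction_acute=results["acute"][1],
        direction_memory=results["memory"][1],
        p_acute=results["acute"][2],
        p_memory=results["memory"][2],
        alpha=alpha,
    )


def _classify_call(call: PhenotypeCall) -> str:
    if call.acute == "N":
        return "acute_required"
    if call.memory == "N":
        return "memory_required"
    return "wildtype_response"


def classify_screen(
    calls: Iterable[PhenotypeCall],
    metadata: Mapping[str, bool] | None = None,
    controls: Iterable[str] = (),
) -> ScreenSummary:
    """Tally the screen: acute-required / memory-required / wild-type genes.

    Control lines are excluded from the gene counts (their calls are kept in
    the per-line table, flagged). ``metadata`` maps gene -> prior-paradigm
    flag and must cover every non-control gene; memory-required genes
    without the flag count as novel memory genes.
    """
    controls = set(controls)
    metadata = dict(metadata or {})
    rows = []
    n = {lab: 0 for lab in CLASS_LABELS}
    n_novel = 0
    n_tested = 0
    for call in calls:
        is_control = call.line_id in controls
        cls = _classify_call(call)
        prior = False
        if not is_control:
            if call.line_id not in metadata:
                raise ValueError(f"metadata missing for tested gene {call.line_id!r}")
            prior = bool(metadata[call.line_id])
            n_tested += 1
            n[cls] += 1
            if cls == "memory_required" and not prior:
                n_novel += 1
        rows.append(
            {
                "line_id": call.line_id,
                "acute_call": call.acute,
                "memory_call": call.memory,
                "direction_acute": call.direction_acute,
                "direction_memory": call.direction_memory,
                "p_acute": call.p_acute,
                "p_memory": call.p_memory,
                "class": cls,
                "prior_paradigm": prior,
                "is_control": is_control,
            }
        )
    return ScreenSummary(
        n_tested=n_tested,
        n_acute_required=n["acute_required"],
        n_memory_required=n["memory_required"],
        n_wildtype=n["wildtype_response"],
        n_novel_memory=n_novel,
        table=pd.DataFrame(rows),
    )


class OvipositionScreen:
    """Model for a vial-level egg-count screen.

    Parameters
    ----------
    counts
        DataFrame with columns ``line_id, condition, period, replicate,
        egg_count`` (conditions ``exposed``/``unexposed``, periods
        ``acute``/``memory``).
    metadata
        Mapping gene -> prior-paradigm flag (or a DataFrame with a
        ``prior_paradigm`` column indexed by gene). Must cover every
        non-control line.
    controls
        Line ids excluded from the gene tallies.

    Examples
    --------
    >>> from memscreen import simulate_screen, reference_ground_truth
    >>> counts = simulate_screen(reference_ground_truth(), seed=7)
    >>> res = OvipositionScreen.from_ground_truth(counts).fit(alpha=0.05)
    >>> res.summary_counts.n_tested
    29
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        metadata: Mapping[str, bool] | pd.DataFrame | None = None,
        controls: Iterable[str] = (),
    ) -> None:
        required = {"line_id", "condition", "period", "replicate", "egg_count"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"counts table missing column(s): {sorted(missing)}")
        if (counts["egg_count"] < 0).any():
            raise ValueError("egg counts must be non-negative")
        if isinstance(metadata, pd.DataFrame):
            metadata = metadata["prior_paradigm"].to_dict()
        self.counts = counts.reset_index(drop=True)
        self.metadata = dict(metadata or {})
        self.controls = set(controls)
        self.lines = list(dict.fromkeys(self.counts["line_id"]))

    @classmethod
    def from_ground_truth(cls, counts: pd.DataFrame) -> "OvipositionScreen":
        """Build a screen model for counts simulated from the packaged truth,
        wiring in the packaged metadata and control set."""
        from .simulate import _REFERENCE_CONTROLS, reference_metadata

        meta = reference_metadata()["prior_paradigm"].to_dict()
        return cls(counts, metadata=meta, controls=_REFERENCE_CONTROLS)

    def fit(self, alpha: float = 0.05) -> "ScreenResults":
        """Run per-line Welch tests, directional calls and the class tally."""
        calls = [call_phenotype(self.counts, line, alpha=alpha) for line in self.lines]
        summary = classify_screen(calls, metadata=self.metadata, controls=self.controls)
        percents = {
            (line, period): normalize_oviposition(self.counts, line, period)
            for line in self.lines
            for period in ("acute", "memory")
        }
        return ScreenResults(model=self, alpha=alpha, calls=calls,
                             summary_counts=summary, normalized=percents)


class ScreenResults:
    """Fitted screen: per-line calls, normalized responses, class tally."""

    def __init__(
        self,
        model: OvipositionScreen,
        alpha: float,
        calls: list[PhenotypeCall],
        summary_counts: ScreenSummary,
        normalized: Mapping[tuple[str, str], NormalizedResponse],
    ) -> None:
        self.model = model
        self.alpha = alpha
        self.calls = calls
        self.summary_counts = summary_counts
        self.normalized = normalized

    @property
    def table(self) -> pd.DataFrame:
        """Per-line table: normalized percents, SEMs, p-values, calls, class."""
        base = self.summary_counts.table.set_index("line_id")
        for period in ("acute", "memory"):
            base[f"percent_{period}"] = [self.normalized[(l, period)].percent for l in base.index]
            base[f"sem_{period}"] = [self.normalized[(l, period)].sem for l in base.index]
        cols = [
            "percent_acute", "sem_acute", "p_acute", "direction_acute", "acute_call",
            "percent_memory", "sem_memory", "p_memory", "direction_memory", "memory_call",
            "class", "prior_paradigm", "is_control",
        ]
        return base[cols].reset_index()

    def hits(self, cls: str) -> list[str]:
        """Non-control gene ids in the given screen class."""
        t = self.summary_counts.table
        sel = (t["class"] == cls) & ~t["is_control"]
        return list(t.loc[sel, "line_id"])

    def summary(self) -> str:
        """Human-readable screen summary."""
        s = self.summary_counts
        lines = [
            "Oviposition-depression screen summary",
            "=" * 48,
            f"alpha (Welch two-tailed)   : {self.alpha}",
            f"genes tested               : {s.n_tested}",
            f"acute-response required    : {s.n_acute_required}",
            f"memory-response required   : {s.n_memory_required}",
            f"wild-type response         : {s.n_wildtype}",
            f"novel memory genes         : {s.n_novel_memory}",
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
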