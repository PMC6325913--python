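"""End-to-end pipeline driver: triage -> screen -> network enrichment.

A :class:`PipelineConfig` (loadable from YAML) names the inputs; any input
left unset falls back to the packaged synthetic fixtures, so a config with
only a seed and an output directory runs the whole chain on simulated data:

1. **select** — read (or simulate) the score matrix, quantize, aggregate,
   categorize, apply exclusions, and draw the stratified candidate sets;
2. **screen** — read (or simulate from the packaged ground truth) the
   vial-level egg counts and fit the oviposition screen;
3. **network** — query the functional network separately with the
   acute-required and memory-required hit sets at the stringent and lenient
   confidence tiers, and run term enrichment on each retained gene set.

Every stochastic stage consumes a seed derived deterministically from the
global seed and the stage name; re-running an identical config + seed
reproduces byte-identical stage outputs (the manifest isolates timestamps).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .fixtures import toy_acute_network, toy_annotations, toy_memory_network
from .network import connectivity_report, enrich_terms, threshold_subnetwork
from .screen import OvipositionScreen
from .simulate import (
    ScreenDesign,
    reference_ground_truth,
    reference_metadata,
    simulate_scores,
    simulate_screen,
    _REFERENCE_CONTROLS,
)
from .triage import (
    CategoryThresholds,
    aggregate_quantiles,
    apply_exclusions,
    categorize,
    select_candidates,
    to_quantile_bins,
)

__version__ = "0.1.0"

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]

_STAGES = ("simulate_scores", "select", "simulate_screen", "screen", "network")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed and stage name."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Path fields left as None fall back to packaged synthetic fixtures
    (simulated scores, the packaged screen ground truth, the toy networks
    and annotations).
    """

    seed: int = 0
    out_dir: str = "results"
    scores: str | None = None
    essential: str | None = None
    annotated: str | None = None
    counts: str | None = None
    metadata: str | None = None
    acute_edges: str | None = None
    memory_edges: str | None = None
    annotations: str | None = None
    alpha: float = 0.05
    min_conf: float = 0.85
    min_conf_weak: float = 0.4
    n_positive: int = 5
    n_negative: int = 9
    n_variable: int = 15
    design: ScreenDesign = field(default_factory=ScreenDesign)
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        design = ScreenDesign(**raw.pop("design", {}))
        thresholds = CategoryThresholds(**raw.pop("thresholds", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(design=design, thresholds=thresholds, **raw)

    def content_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one pipeline run: version, config hash, seed, row counts."""

    version: str
    config_hash: str
    seed: int
    stage_rows: dict[str, int]
    sd_cutoff: float
    started: str
    finished: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


def _write_result_tsv(df: pd.DataFrame, path: Path, seed: int, stage: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed={seed} stage={stage}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline; returns the run manifest (also written to disk)."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_rows: dict[str, int] = {}

    # --- triage -------------------------------------------------------------
    if config.scores is not None:
        scores = msio.read_score_matrix(config.scores)
    else:
        planted = _default_planted()
        scores = simulate_scores(
            len(planted), 10, planted, coverage_prob=0.95,
            seed=stage_seed(config.seed, "simulate_scores"),
        )
        msio.write_score_matrix(scores, out / "scores.tsv")
    essential = msio.read_gene_list(config.essential) if config.essential else []
    annotated = msio.read_gene_list(config.annotated) if config.annotated else []

    aggs = aggregate_quantiles(to_quantile_bins(scores))
    assignment = apply_exclusions(categorize(aggs, config.thresholds), essential, annotated)
    selection = select_candidates(
        assignment,
        {"positive": config.n_positive, "negative": config.n_negative,
         "variable": config.n_variable},
        seed=stage_seed(config.seed, "select"),
    )
    table = aggs.copy()
    table["label"] = assignment.labels
    table["selected"] = table.index.isin(selection["gene"])
    _write_result_tsv(table.reset_index(), out / "assignments.tsv", config.seed, "select")
    _write_result_tsv(selection, out / "candidates.tsv", config.seed, "select")
    stage_rows["select"] = len(selection)

    # --- screen -------------------------------------------------------------
    if config.counts is not None:
        counts = msio.read_egg_counts(config.counts)
    else:
        counts = simulate_screen(
            reference_ground_truth(), config.design,
            seed=stage_seed(config.seed, "simulate_screen"),
        )
        msio.write_egg_counts(counts, out / "counts.csv")
    stage_rows["counts"] = len(counts)

    if config.metadata is not None:
        meta = msio.read_gene_metadata(config.metadata)["prior_paradigm"].to_dict()
        controls = sorted(set(counts["line_id"]) - set(meta))
    else:
        meta = reference_metadata()["prior_paradigm"].to_dict()
        controls = list(_REFERENCE_CONTROLS)

    results = OvipositionScreen(counts, metadata=meta, controls=controls).fit(config.alpha)
    _write_result_tsv(results.table, out / "screen_results.tsv", config.seed, "screen")
    s = results.summary_counts
    summary_df = pd.DataFrame(
        [
            ("n_tested", s.n_tested),
            ("n_acute_required", s.n_acute_required),
            ("n_memory_required", s.n_memory_required),
            ("n_wildtype", s.n_wildtype),
            ("n_novel_memory", s.n_novel_memory),
        ],
        columns=["quantity", "count"],
    )
    _write_result_tsv(summary_df, out / "screen_summary.tsv", config.seed, "screen")
    stage_rows["screen"] = s.n_tested

    # --- network ------------------------------------------------------------
    nets = {
        "acute": msio.read_edge_list(config.acute_edges) if config.acute_edges else toy_acute_network(),
        "memory": msio.read_edge_list(config.memory_edges) if config.memory_edges else toy_memory_network(),
    }
    ann = msio.read_annotations(config.annotations) if config.annotations else toy_annotations()
    hit_sets = {
        "acute": results.hits("acute_required"),
        "memory": results.hits("memory_required"),
    }
    for which, hits in hit_sets.items():
        if not hits:
            continue
        sub = threshold_subnetwork(nets[which], hits, config.min_conf_weak)
        edges = pd.DataFrame(sub.edge_list(), columns=["gene_a", "gene_b", "confidence", "tier"])
        edges = edges[edges["confidence"] >= config.min_conf_weak]
        _write_result_tsv(edges, out / f"network_{which}_edges.tsv", config.seed, "network")
        report = connectivity_report(threshold_subnetwork(nets[which], hits, config.min_conf))
        _write_result_tsv(report, out / f"network_{which}_connectivity.tsv", config.seed, "network")
        enrichment = enrich_terms(sub.nodes, ann, fdr=True)
        _write_result_tsv(enrichment, out / f"enrichment_{which}.tsv", config.seed, "network")
        stage_rows[f"network_{which}"] = len(edges)

    manifest = RunManifest(
        version=__version__,
        config_hash=config.content_hash(),
        seed=config.seed,
        stage_rows=stage_rows,
        sd_cutoff=assignment.sd_cutoff,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    return manifest


def _default_planted(n_positive: int = 20, n_negative: int = 20,
                     n_variable: int = 20, n_background: int = 140) -> dict[str, str]:
    """Default planted-class layout used when no score matrix is supplied."""
    planted: dict[str, str] = {}
    for label, count in (("positive", n_positive), ("negative", n_negative),
                         ("variable", n_variable), ("background", n_background)):
        for i in range(count):
            planted[f"{label[:3]}{i + 1:04d}"] = label
    return planted
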