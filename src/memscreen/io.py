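"""Readers and writers for the pipeline's table dialects.

All files are UTF-8 text with a mandatory header line. Dialects:

* score matrix — TSV, first column ``gene``, one column per model id; an
  empty cell means the model does not cover the gene;
* egg counts — CSV with header ``line_id,condition,period,replicate,
  egg_count``; conditions ``exposed``/``unexposed``, periods
  ``acute``/``memory``;
* edge list — TSV ``gene_a\tgene_b\tconfidence`` with confidence in (0, 1];
* annotations — TSV ``gene\tterm``, one pair per line;
* gene metadata — TSV ``gene\tessential\tannotated_target\tprior_paradigm``
  with 0/1 flags;
* gene lists — one gene id per line, ``#`` comments allowed.

Malformed rows are rejected with their line number. ``write(read(write(x)))``
is byte-stable for every dialect.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .network import AnnotationMap, FunctionalNetwork

__all__ = [
    "FormatError",
    "read_score_matrix", "write_score_matrix",
    "read_egg_counts", "write_egg_counts",
    "read_edge_list", "write_edge_list",
    "read_annotations", "write_annotations",
    "read_gene_metadata", "write_gene_metadata",
    "read_gene_list", "write_gene_list",
]

CONDITIONS = ("exposed", "unexposed")
PERIODS = ("acute", "memory")


class FormatError(ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, path: str | Path, line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.splitlines()


# -- score matrix ------------------------------------------------------------

def read_score_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × models score TSV; empty cells become NaN (not covered)."""
    lines = _read_lines(path)
    if not lines:
        raise FormatError(path, 1, "empty file (expected a header)")
    header = lines[0].split("\t")
    if header[0] != "gene" or len(header) < 2:
        raise FormatError(path, 1, "expected header 'gene<TAB>model...'")
    models = header[1:]
    genes, rows = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(path, i, f"expected {len(header)} columns, found {len(parts)}")
        genes.append(parts[0])
        row = []
        for j, cell in enumerate(parts[1:]):
            if cell == "":
                row.append(np.nan)
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(path, i, f"non-numeric score {cell!r} in column {models[j]!r}") from None
            if not 0 <= v <= 1:
                raise FormatError(path, i, f"score {v} outside [0, 1] in column {models[j]!r}")
            row.append(v)
        rows.append(row)
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise FormatError(path, 1, f"duplicate gene id(s): {dupes}")
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=models)


def _fmt_score(v: float) -> str:
    return "" if not np.isfinite(v) else format(float(v), ".10g")


def write_score_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    lines = ["\t".join(["gene", *map(str, matrix.columns)])]
    for gene, row in matrix.iterrows():
        lines.append("\t".join([str(gene), *(_fmt_score(v) for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- egg counts --------------------------------------------------------------

def read_egg_counts(path: str | Path) -> pd.DataFrame:
    """Read a vial-level egg-count CSV."""
    lines = _read_lines(path)
    expected = "line_id,condition,period,replicate,egg_count"
    if not lines or lines[0] != expected:
        raise FormatError(path, 1, f"expected header {expected!r}")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 5:
            raise FormatError(path, i, f"expected 5 columns, found {len(parts)}")
        line_id, condition, period, replicate, count = parts
        if condition not in CONDITIONS:
            raise FormatError(path, i, f"condition must be one of {CONDITIONS}, got {condition!r}")
        if period not in PERIODS:
            raise FormatError(path, i, f"period must be one of {PERIODS}, got {period!r}")
        try:
            rep = int(replicate)
            n = int(count)
        except ValueError:
            raise FormatError(path, i, "replicate and egg_count must be integers") from None
        if n < 0:
            raise FormatError(path, i, f"egg_count must be >= 0, got {n}")
        rows.append((line_id, condition, period, rep, n))
    return pd.DataFrame(rows, columns=["line_id", "condition", "period", "replicate", "egg_count"])


def write_egg_counts(table: pd.DataFrame, path: str | Path) -> None:
    lines = ["line_id,condition,period,replicate,egg_count"]
    for r in table.itertuples(index=False):
        lines.append(f"{r.line_id},{r.condition},{r.period},{int(r.replicate)},{int(r.egg_count)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- edge list ---------------------------------------------------------------

def read_edge_list(path: str | Path) -> FunctionalNetwork:
    """Read a weighted edge TSV into a FunctionalNetwork."""
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != ["gene_a", "gene_b", "confidence"]:
        raise FormatError(path, 1, "expected header 'gene_a<TAB>gene_b<TAB>confidence'")
    net = FunctionalNetwork()
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(path, i, f"expected 3 columns, found {len(parts)}")
        a, b, conf_s = parts
        try:
            conf = float(conf_s)
        except ValueError:
            raise FormatError(path, i, f"non-numeric confidence {conf_s!r}") from None
        try:
            net.add_edge(a, b, conf)
        except ValueError as exc:
            raise FormatError(path, i, str(exc)) from None
    return net


def write_edge_list(net: FunctionalNetwork, path: str | Path) -> None:
    lines = ["gene_a\tgene_b\tconfidence"]
    for a, b, conf in net.edge_list():
        lines.append(f"{a}\t{b}\t{format(conf, '.10g')}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- annotations -------------------------------------------------------------

def read_annotations(path: str | Path, background_size: int | None = None) -> AnnotationMap:
    """Read a two-column gene -> term TSV into an AnnotationMap."""
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != ["gene", "term"]:
        raise FormatError(path, 1, "expected header 'gene<TAB>term'")
    pairs = []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(path, i, "expected 'gene<TAB>term' with non-empty fields")
        pairs.append((parts[0], parts[1]))
    return AnnotationMap.from_pairs(pairs, background_size=background_size)


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    lines = ["gene\tterm"]
    for gene in sorted(ann.terms):
        for term in sorted(ann.terms[gene]):
            lines.append(f"{gene}\t{term}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- gene metadata -----------------------------------------------------------

_META_HEADER = ["gene", "essential", "annotated_target", "prior_paradigm"]


def read_gene_metadata(path: str | Path) -> pd.DataFrame:
    """Read gene flags: essentiality, prior target-term annotation, prior paradigm."""
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != _META_HEADER:
        raise FormatError(path, 1, f"expected header {chr(9).join(_META_HEADER)!r}")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(path, i, f"expected 4 columns, found {len(parts)}")
        gene, *flags = parts
        if any(f not in ("0", "1") for f in flags):
            raise FormatError(path, i, "flags must be 0 or 1")
        rows.append((gene, *(f == "1" for f in flags)))
    out = pd.DataFrame(rows, columns=_META_HEADER)
    return out.set_index("gene")


def write_gene_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    lines = ["\t".join(_META_HEADER)]
    for gene, row in meta.iterrows():
        flags = "\t".join("1" if bool(row[c]) else "0" for c in _META_HEADER[1:])
        lines.append(f"{gene}\t{flags}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- gene lists --------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line text file; blank lines and # comments skipped."""
    out = []
    for line in _read_lines(path):
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
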