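"""Confidence-thresholded functional-network queries and term enrichment.

Operates on user-supplied weighted gene networks (edge lists with a
per-edge relationship confidence in (0, 1]) and gene -> term annotation
maps, mimicking the query workflow of integrative functional-relationship
webservers: extract the subnetwork around a set of query genes at a minimum
confidence (a stringent 0.85 tier and a lenient 0.4 tier are conventional),
report per-query connectivity, and test the retained gene set for term
over-representation with the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats

__all__ = [
    "FunctionalNetwork",
    "AnnotationMap",
    "SubnetworkResult",
    "threshold_subnetwork",
    "connectivity_report",
    "enrich_terms",
    "STRONG_CONFIDENCE",
    "WEAK_CONFIDENCE",
]

logger = logging.getLogger(__name__)

#: Conventional stringent / lenient relationship-confidence tiers.
STRONG_CONFIDENCE = 0.85
WEAK_CONFIDENCE = 0.4


class FunctionalNetwork:
    """Weighted gene network: unordered gene pairs with confidence in (0, 1].

    Backed by a :class:`networkx.Graph` with a ``confidence`` attribute per
    edge. No self-loops; at most one edge per pair (a duplicated pair with a
    conflicting confidence is rejected).
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()) -> None:
        self.graph = nx.Graph()
        for a, b, conf in edges:
            self.add_edge(a, b, conf)

    def add_edge(self, a: str, b: str, confidence: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r} not allowed")
        if not 0 < confidence <= 1:
            raise ValueError(f"confidence must lie in (0, 1]; got {confidence} for ({a}, {b})")
        if self.graph.has_edge(a, b):
            existing = self.graph.edges[a, b]["confidence"]
            if existing != confidence:
                raise ValueError(
                    f"conflicting confidences for pair ({a}, {b}): {existing} vs {confidence}"
                )
            return
        self.graph.add_edge(a, b, confidence=float(confidence))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Edges as sorted (gene_a, gene_b, confidence) with gene_a < gene_b."""
        out = [
            (min(a, b), max(a, b), d["confidence"])
            for a, b, d in self.graph.edges(data=True)
        ]
        return sorted(out)

    def __len__(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class AnnotationMap:
    """Gene -> term annotations over a background of annotatable genes.

    ``background_size`` defaults to the number of annotated genes; it can be
    set larger when the annotatable universe exceeds the annotation file.
    """

    terms: Mapping[str, frozenset[str]]
    background_size: int | None = None

    def __post_init__(self) -> None:
        for gene, ts in self.terms.items():
            if not ts:
                raise ValueError(f"gene {gene!r} listed with an empty term set")
        n = len(self.terms) if self.background_size is None else self.background_size
        if n < len(self.terms):
            raise ValueError("background_size smaller than the number of annotated genes")
        object.__setattr__(self, "background_size", n)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   background_size: int | None = None) -> "AnnotationMap":
        terms: dict[str, set[str]] = {}
        for gene, term in pairs:
            terms.setdefault(gene, set()).add(term)
        return cls({g: frozenset(t) for g, t in terms.items()}, background_size)

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.terms.items() if term in ts}


@dataclass(frozen=True)
class SubnetworkResult:
    """Thresholded subnetwork around a query set.

    ``graph`` holds the retained nodes/edges (every retained edge has
    confidence >= ``min_conf``; edges carry a ``tier`` attribute, "strong"
    for >= 0.85 else "weak"). ``isolated_queries`` lists query genes present
    in the network but with no retained incident edge; ``unknown_queries``
    lists query genes absent from the network (reported, not fatal).
    """

    graph: nx.Graph
    query: frozenset[str]
    min_conf: float
    isolated_queries: tuple[str, ...]
    unknown_queries: tuple[str, ...]

    @property
    def query_connected(self) -> dict[str, bool]:
        isolated = set(self.isolated_queries) | set(self.unknown_queries)
        return {q: q not in isolated for q in sorted(self.query)}

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_list(self) -> list[tuple[str, str, float, str]]:
        out = [
            (min(a, b), max(a, b), d["confidence"], d["tier"])
            for a, b, d in self.graph.edges(data=True)
        ]
        return sorted(out)


def threshold_subnetwork(
    net: FunctionalNetwork,
    query: Iterable[str],
    min_conf: float,
    include_neighbors: bool = True,
) -> SubnetworkResult:
    """Extract the subnetwork around ``query`` at a minimum edge confidence.

    Edges below ``min_conf`` are dropped. Retained nodes are the query genes
    plus, when ``include_neighbors``, their direct neighbors through
    retained edges (one hop). Retained edges are those meeting the threshold
    with both endpoints retained. Query genes with no retained incident edge
    are flagged isolated; query genes absent from the network are listed as
    unknown.

    Raising ``min_conf`` never adds nodes or edges (monotonicity).
    """
    query = set(query)
    if not query:
        raise ValueError("query must be non-empty")
    if not 0 < min_conf <= 1:
        raise ValueError("min_conf must lie in (0, 1]")
    unknown = tuple(sorted(query - net.nodes))
    if unknown:
        logger.info("query gene(s) absent from network: %s", list(unknown))
    present = query & net.nodes

    strong = nx.Graph(
        (a, b, d)
        for a, b, d in net.graph.edges(data=True)
        if d["confidence"] >= min_conf
    )
    retained_nodes = set(present)
    if include_neighbors:
        for q in present:
            if q in strong:
                retained_nodes.update(strong.neighbors(q))

    sub = nx.Graph()
    sub.add_nodes_from(retained_nodes)
    for a, b, d in strong.edges(data=True):
        if a in retained_nodes and b in retained_nodes:
            tier = "strong" if d["confidence"] >= STRONG_CONFIDENCE else "weak"
            sub.add_edge(a, b, confidence=d["confidence"], tier=tier)
    isolated = tuple(sorted(q for q in present if sub.degree(q) == 0))
    return SubnetworkResult(
        graph=sub,
        query=frozenset(query),
        min_conf=min_conf,
        isolated_queries=isolated,
        unknown_queries=unknown,
    )


def connectivity_report(sub: SubnetworkResult, query: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-query connectivity within the retained subnetwork.

    Returns a DataFrame (gene, connected, degree, neighbors) sorted by
    degree descending, ties by gene id.
    """
    query = set(query) if query is not None else set(sub.query)
    rows = []
    for gene in query:
        if gene in sub.graph:
            degree = sub.graph.degree(gene)
            neighbors = sorted(sub.graph.neighbors(gene))
        else:
            degree, neighbors = 0, []
        rows.append(
            {"gene": gene, "connected": degree > 0, "degree": int(degree),
             "neighbors": ",".join(neighbors)}
        )
    out = pd.DataFrame(rows, columns=["gene", "connected", "degree", "neighbors"])
    return out.sort_values(["degree", "gene"], ascending=[False, True]).reset_index(drop=True)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): the over-representation p."""
    if K > N or n > N:
        raise ValueError(f"inconsistent annotation universe: K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    network_genes: Iterable[str],
    ann: AnnotationMap,
    fdr: bool = False,
) -> pd.DataFrame:
    """Hypergeometric term over-representation for a gene set.

    For each term annotating at least one of the n annotated network genes:
    k = annotated network genes with the term, K = background genes with the
    term, N = background size; p is the hypergeometric upper tail
    P(X >= k). ``percent`` is 100*k/n at full precision (round for
    reports). Rows are sorted ascending by p, ties by term id; with
    ``fdr=True`` a Benjamini-Hochberg ``q`` column is appended.

    Network genes missing from the annotation universe are dropped (logged).
    """
    genes = set(network_genes)
    annotated = genes & set(ann.terms)
    dropped = sorted(genes - annotated)
    if dropped:
        logger.info("dropping %d unannotated network gene(s): %s", len(dropped), dropped)
    n = len(annotated)
    N = ann.background_size
    if n > N:
        raise ValueError(f"network gene count n={n} exceeds background N={N}")
    term_counts: dict[str, int] = {}
    for g in annotated:
        for t in ann.terms[g]:
            term_counts[t] = term_counts.get(t, 0) + 1
    rows = []
    for term, k in term_counts.items():
        K = len(ann.genes_with(term))
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "percent": 100.0 * k / n,
                "K": K,
                "N": N,
                "p": hypergeom_upper_tail(k, N, K, n),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "k", "n", "percent", "K", "N", "p"])
    out = out.sort_values(["p", "term"]).reset_index(drop=True)
    if fdr and len(out):
        m = len(out)
        q = out["p"].to_numpy() * m / (pd.RangeIndex(1, m + 1).to_numpy())
        # enforce monotonicity from the largest p down
        for i in range(m - 2, -1, -1):
            q[i] = min(q[i], q[i + 1])
        out["q"] = q.clip(max=1.0)
    return out
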