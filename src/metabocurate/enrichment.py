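"""Topology-aware pathway over-representation analysis.

Importance of a compound within a pathway is its relative betweenness
centrality: raw betweenness divided by the pathway's maximum (pathways
without topology, or whose graph has no intermediary at all, fall back to
uniform importance 1/K).  The pathway impact of a hit set is the summed
importance of the hits over the summed importance of all members; the
over-representation p-value is the upper tail of the hypergeometric
distribution, and the enrichment ratio is observed over expected hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .differential import bh_fdr
from .model import Pathway, PathwayLibrary, ValidationError


def relative_betweenness(graph: nx.Graph) -> dict[str, float]:
    """Betweenness centrality normalised by the graph's maximum.

    If no node has positive betweenness (complete graphs, tiny graphs),
    every node gets the uniform fallback 1/|V|.
    """
    n = graph.number_of_nodes()
    if n == 0:
        return {}
    bc = nx.betweenness_centrality(graph, normalized=True)
    top = max(bc.values())
    if top <= 0:
        return {v: 1.0 / n for v in graph.nodes}
    return {v: b / top for v, b in bc.items()}


def pathway_importance(pathway: Pathway) -> dict[str, float]:
    """Per-member importance; uniform 1/K when the pathway has no topology."""
    members = sorted(pathway.members)
    if pathway.graph is None:
        k = len(members)
        return {m: 1.0 / k for m in members} if k else {}
    rb = relative_betweenness(pathway.graph)
    # members absent from the topology contribute zero importance
    return {m: rb.get(m, 0.0) for m in members}


def pathway_impact(hits, pathway: Pathway) -> float:
    """Summed importance of hit members over summed importance of all members."""
    imp = pathway_importance(pathway)
    denom = sum(imp.values())
    if denom == 0:
        return 0.0
    hits = set(hits)
    return sum(v for m, v in imp.items() if m in hits) / denom


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail over-representation p: P(X >= k), X ~ Hypergeom(N, K, n)."""
    if K > N or n > N:
        raise ValidationError("pathway size and input size cannot exceed the universe")
    if k > min(K, n) or k < 0:
        raise ValidationError(f"impossible hit count k={k} for K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_ratio(k: int, K: int, n: int, N: int) -> float:
    """Observed hits over expected hits K*n/N under random sampling."""
    expected = K * n / N
    if expected == 0:
        return 0.0
    return k / expected


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    k: int  # hits
    K: int  # pathway size
    n: int  # mapped input size
    N: int  # universe size
    impact: float
    p: float
    enrichment_ratio: float
    q: float
    minus_log10_p: float
    hit_members: frozenset[str]
    n_unmapped_input: int = 0


def enrich_all(
    input_compounds, library: PathwayLibrary, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Per-pathway impact + hypergeometric test, BH-adjusted across pathways.

    The universe is the library's compound union; input compounds outside
    the universe are dropped (and reflected in n).  Zero-overlap pathways
    are kept with p = 1 so the FDR correction sees the full family.
    """
    universe = library.universe
    n_dropped = len(set(input_compounds)) - len(set(input_compounds) & universe)
    mapped = set(input_compounds) & universe
    if not mapped:
        raise ValidationError("no mapped compounds: input does not intersect the library universe")
    N, n = len(universe), len(mapped)

    ordered = sorted(library.pathways)
    pvals, partial = [], []
    for pid in ordered:
        pw = library.pathways[pid]
        hits = frozenset(mapped & pw.members)
        k, K = len(hits), len(pw.members)
        p = hypergeom_p(k, K, n, N)
        pvals.append(p)
        partial.append((pw, hits, k, K, p))

    qvals = bh_fdr(pvals)
    results = []
    for (pw, hits, k, K, p), q in zip(partial, qvals):
        results.append(
            EnrichmentResult(
                pathway_id=pw.pathway_id,
                name=pw.name,
                k=k,
                K=K,
                n=n,
                N=N,
                impact=pathway_impact(hits, pw),
                p=p,
                enrichment_ratio=enrichment_ratio(k, K, n, N),
                q=float(q),
                minus_log10_p=-math.log10(p) if p > 0 else math.inf,
                hit_members=hits,
                n_unmapped_input=n_dropped,
            )
        )
    results.sort(key=lambda r: (r.p, -r.impact, r.pathway_id))
    return results
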