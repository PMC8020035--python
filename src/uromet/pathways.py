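"""Pathway over-representation and topology-impact analysis.

Significantly altered compounds are screened against a library of pathway
graphs (compound nodes, reaction-adjacency edges):

* over-representation — the exact hypergeometric upper tail of the hit
  count given the pathway size, the number of significant compounds mapped
  to the background, and the background size;
* topology impact — the sum of relative betweenness centralities of the
  matched nodes, normalized by the pathway's total centrality, so that a
  hit on a bottleneck node weighs more than one on a leaf.

The library is a static JSON fixture (live pathway databases are neither
versionable nor testable); :func:`default_pathway_library` builds a small
synthetic library shaped like human urine metabolism, including purine- and
tyrosine-metabolism-like pathways.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "PathwayGraph",
    "PathwayLibrary",
    "PathwayResult",
    "hypergeometric_ora",
    "relative_betweenness_impact",
    "pathway_screen",
    "default_pathway_library",
]


@dataclass
class PathwayGraph:
    """One pathway: compound nodes plus undirected reaction adjacency."""

    id: str
    name: str
    nodes: list
    edges: list = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"{self.id}: edge ({a}, {b}) references a missing node")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class PathwayLibrary:
    pathways: list
    background: list

    def __post_init__(self) -> None:
        bg = set(self.background)
        for p in self.pathways:
            missing = set(p.nodes) - bg
            if missing:
                raise ValueError(f"{p.id}: nodes outside the background: {sorted(missing)}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "background": list(self.background),
                    "pathways": [
                        {"id": p.id, "name": p.name, "nodes": list(p.nodes),
                         "edges": [list(e) for e in p.edges]}
                        for p in self.pathways
                    ],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "PathwayLibrary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pathways=[
                PathwayGraph(p["id"], p["name"], p["nodes"],
                             [tuple(e) for e in p.get("edges", [])])
                for p in d["pathways"]
            ],
            background=list(d["background"]),
        )


@dataclass(frozen=True)
class PathwayResult:
    pathway_id: str
    name: str
    hits: int
    size: int
    background: int
    p: float
    impact: float
    matched: tuple


def hypergeometric_ora(hits_in_pathway: int, pathway_size: int,
                       total_hits: int, background: int) -> float:
    """Exact hypergeometric upper tail P(X >= k).

    k hits observed in a pathway of K compounds when n significant
    compounds are drawn from a background of N.
    """
    k, K, n, N = hits_in_pathway, pathway_size, total_hits, background
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError("inconsistent hypergeometric counts")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def relative_betweenness_impact(pathway: PathwayGraph, matched) -> float:
    """Topology impact: matched betweenness / total pathway betweenness.

    Betweenness centrality is computed on the pathway's undirected graph;
    pathways whose centralities are all zero (stars of leaves, edgeless
    sets) fall back to degree centrality, and a pathway with zero total
    centrality under both measures has impact 0.
    """
    matched = list(matched)
    node_set = set(pathway.nodes)
    absent = [m for m in matched if m not in node_set]
    if absent:
        raise ValueError(f"matched compounds not in pathway {pathway.id}: {absent}")
    g = pathway.graph()
    cent = nx.betweenness_centrality(g, normalized=True)
    total = sum(cent.values())
    if total == 0.0:
        cent = dict(g.degree())
        total = sum(cent.values())
        if total == 0.0:
            return 0.0
    return float(sum(cent[m] for m in matched) / total)


def pathway_screen(significant_compounds, library: PathwayLibrary,
                   alpha: float = 0.05, holm: bool = False):
    """One ORA + impact result per pathway, sorted by ascending p.

    Significant compounds missing from the background are dropped with a
    warning (an identifier-mapping miss, not an error). With ``holm=True``
    the p-values are Holm-adjusted before the sort; the default reports raw
    p-values.
    """
    background = list(dict.fromkeys(library.background))
    if not background:
        raise ValueError("background must be nonempty")
    bg = set(background)
    sig = list(dict.fromkeys(significant_compounds))
    unmapped = [c for c in sig if c not in bg]
    if unmapped:
        warnings.warn(f"dropping compounds absent from the background: {unmapped}",
                      stacklevel=2)
    sig = [c for c in sig if c in bg]

    results = []
    for p in library.pathways:
        matched = tuple(c for c in p.nodes if c in sig)
        pval = hypergeometric_ora(len(matched), len(p.nodes), len(sig), len(bg))
        impact = relative_betweenness_impact(p, matched) if matched else 0.0
        results.append(
            PathwayResult(
                pathway_id=p.id, name=p.name, hits=len(matched),
                size=len(p.nodes), background=len(bg), p=pval,
                impact=impact, matched=matched,
            )
        )
    if holm:
        order = np.argsort([r.p for r in results])
        m = len(results)
        adj, prev = {}, 0.0
        for rank, i in enumerate(order):
            prev = max(prev, min(1.0, (m - rank) * results[i].p))
            adj[i] = prev
        results = [
            PathwayResult(r.pathway_id, r.name, r.hits, r.size, r.background,
                          adj[i], r.impact, r.matched)
            for i, r in enumerate(results)
        ]
    results.sort(key=lambda r: (r.p, -r.impact, r.pathway_id))
    return results


def default_pathway_library() -> PathwayLibrary:
    """Synthetic pathway library fixture (~10 small human-urine-like pathways).

    The graphs are toys: node sets reuse the compound identifiers of the
    bundled peak library plus padding compounds, and the "purine
    metabolism"-like pathway is deliberately enriched in the default planted
    biomarkers so that end-to-end recovery is testable. Identifiers prefixed
    ``C9`` are synthetic placeholders.
    """
    chain = lambda nodes: [(nodes[i], nodes[i + 1]) for i in range(len(nodes) - 1)]
    pathways = [
        PathwayGraph(
            "pw01", "purine metabolism (synthetic)",
            ["C07481", "C90001", "C00262", "C00385", "C00366", "C00212"],
            chain(["C00212", "C00262", "C00385", "C00366"])
            + [("C00385", "C07481"), ("C07481", "C90001")],
        ),
        PathwayGraph(
            "pw02", "tyrosine metabolism (synthetic)",
            ["C00082", "C03758", "C90002", "C00355", "C01161"],
            chain(["C00082", "C00355", "C03758", "C90002"]) + [("C03758", "C01161")],
        ),
        PathwayGraph(
            "pw03", "branched-chain amino acid degradation (synthetic)",
            ["C00183", "C00123", "C00407", "C00233"],
            chain(["C00183", "C00233", "C00123", "C00407"]),
        ),
        PathwayGraph(
            "pw04", "glycolysis / pyruvate (synthetic)",
            ["C00186", "C00022", "C00033", "C00041"],
            chain(["C00186", "C00022", "C00033", "C00041"]),
        ),
        PathwayGraph(
            "pw05", "glycine, serine and threonine (synthetic)",
            ["C00037", "C00065", "C00188", "C00213"],
            chain(["C00037", "C00065", "C00188", "C00213"]),
        ),
        PathwayGraph(
            "pw06", "taurine and hypotaurine (synthetic)",
            ["C00245", "C00519", "C00606"],
            chain(["C00519", "C00245", "C00606"]),
        ),
        PathwayGraph(
            "pw07", "arginine and creatine (synthetic)",
            ["C00791", "C02565", "C00300", "C00062"],
            chain(["C00062", "C00300", "C00791", "C02565"]),
        ),
        PathwayGraph(
            "pw08", "TCA cycle (synthetic)",
            ["C00158", "C00042", "C00122", "C00149"],
            chain(["C00158", "C00042", "C00122", "C00149"]) + [("C00149", "C00158")],
        ),
        PathwayGraph(
            "pw09", "benzoate / hippurate conjugation (synthetic)",
            ["C01586", "C00180", "C00037"],
            chain(["C00180", "C01586", "C00037"]),
        ),
        PathwayGraph(
            "pw10", "one-carbon pool (synthetic)",
            ["C00058", "C00101", "C00143"],
            chain(["C00058", "C00101", "C00143"]),
        ),
    ]
    background = sorted(
        {n for p in pathways for n in p.nodes}
        | {"C00543", "C90050", "C90051", "C90052", "C90053", "C90054"}
    )
    return PathwayLibrary(pathways=pathways, background=background)
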