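"""Signaling-flow criticality and centrality measures.

Essentiality follows the removal-reachability definition: a protein is
essential in a tissue when deleting it disconnects at least one ligand ->
transcription-factor pair that was connected in the intact tissue graph.
Rather than deleting nodes one by one, ``essential_nodes`` computes, for each
ligand L, the dominator tree of the flowgraph rooted at L: a node v lies on
*every* path from L to T exactly when v dominates T, so the strict dominators
of T (excluding the endpoints) are precisely the nodes whose removal breaks
the pair. The two formulations are equivalent; the dominator form costs one
linear-time pass per ligand instead of one reachability sweep per node.

Bowtieness is a signaling-specific betweenness variant: the fraction of all
ligand -> TF shortest paths that pass through a node as an intermediate. The
default pools path counts into a single denominator across all reachable
pairs; per-pair averaging is available behind a flag. Shortest-path counts
use exact integer arithmetic (unweighted hop counts), so results are
tie-free and deterministic.
"""

from __future__ import annotations

import math
import statistics
from collections import deque
from typing import Iterable, Mapping

import networkx as nx

from .errors import UsageError
from .model import EssentialityResult, TissueNetwork, Variant
from .paralogs import ParalogGroup, ParalogGroupSet


# ---------------------------------------------------------------------------
# reachability and essentiality


def reachable_pairs(
    graph: nx.DiGraph,
    ligands: Iterable[str],
    tfs: Iterable[str],
) -> frozenset[tuple[str, str]]:
    """All ordered (ligand, TF) pairs joined by a directed path of length >= 1.

    A protein flagged as both ligand and TF never pairs with itself.
    """
    tfs = {t for t in tfs if t in graph}
    pairs = set()
    for ligand in ligands:
        if ligand not in graph:
            continue
        reached = nx.descendants(graph, ligand)
        pairs.update((ligand, t) for t in reached & tfs if t != ligand)
    return frozenset(pairs)


def essential_nodes(
    graph: nx.DiGraph,
    ligands: Iterable[str],
    tfs: Iterable[str],
    tissue: str = "",
    variant: Variant = Variant.ANNOTATED_ONLY,
) -> EssentialityResult:
    """Nodes whose removal disconnects a reachable ligand -> TF pair."""
    tfs = {t for t in tfs if t in graph}
    broken: dict[str, set[tuple[str, str]]] = {}
    for ligand in sorted(set(ligands)):
        if ligand not in graph:
            continue
        idom = nx.immediate_dominators(graph, ligand)
        for tf in tfs:
            if tf == ligand or tf not in idom:
                continue
            node = idom[tf]
            while node != ligand:
                if node != tf:
                    broken.setdefault(node, set()).add((ligand, tf))
                node = idom[node]
    return EssentialityResult(
        tissue=tissue,
        variant=Variant(variant),
        broken_pairs={v: frozenset(ps) for v, ps in broken.items()},
    )


def essential_in_tissue(tissue_network: TissueNetwork) -> EssentialityResult:
    return essential_nodes(
        tissue_network.graph,
        tissue_network.ligands,
        tissue_network.tfs,
        tissue=tissue_network.tissue,
        variant=tissue_network.variant,
    )


def critical_in_flow(tissue_results: Iterable[EssentialityResult]) -> frozenset[str]:
    """Proteins essential in at least one tissue (union over tissues)."""
    results = list(tissue_results)
    if not results:
        raise UsageError("no tissue essentiality results (no eligible tissues?)")
    out: set[str] = set()
    for result in results:
        out |= result.essential
    return frozenset(out)


# ---------------------------------------------------------------------------
# centralities


def degree(graph: nx.DiGraph, v: str) -> int:
    """Number of distinct neighbors of ``v``, ignoring edge direction."""
    if v not in graph:
        raise KeyError(f"node {v!r} not in graph")
    return len(set(graph.predecessors(v)) | set(graph.successors(v)))


def betweenness(graph: nx.DiGraph) -> dict[str, float]:
    """Directed shortest-path betweenness, endpoints excluded, unnormalized."""
    return nx.betweenness_centrality(graph, normalized=False)


def closeness(graph: nx.DiGraph, v: str) -> float:
    """Reciprocal mean undirected distance to the nodes reachable from ``v``.

    Isolated nodes (and a single-node graph) score 0 by convention.
    """
    if v not in graph:
        raise KeyError(f"node {v!r} not in graph")
    undirected = graph.to_undirected()
    return nx.closeness_centrality(undirected, u=v, wf_improved=False)


def closeness_all(graph: nx.DiGraph) -> dict[str, float]:
    undirected = graph.to_undirected()
    return {
        v: nx.closeness_centrality(undirected, u=v, wf_improved=False)
        for v in graph
    }


def _bfs_path_counts(
    graph: nx.DiGraph, source: str, reverse: bool = False
) -> tuple[dict[str, int], dict[str, int]]:
    """Hop distances and exact shortest-path counts from ``source``."""
    adjacency = graph.pred if reverse else graph.succ
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adjacency[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def bowtieness(
    graph: nx.DiGraph,
    ligands: Iterable[str],
    tfs: Iterable[str],
    per_pair: bool = False,
) -> dict[str, float]:
    """Fraction of ligand -> TF shortest paths through each node.

    Pooled by default: one global numerator and denominator over all reachable
    pairs. With ``per_pair=True`` the per-pair fractions are averaged instead.
    Endpoints of a pair accrue nothing from that pair. Returns 0 for every
    node when no pair is reachable.
    """
    ligand_set = sorted({l for l in ligands if l in graph})
    tf_set = sorted({t for t in tfs if t in graph})
    forward = {l: _bfs_path_counts(graph, l) for l in ligand_set}
    backward = {t: _bfs_path_counts(graph, t, reverse=True) for t in tf_set}

    numerator: dict[str, int] = {v: 0 for v in graph}
    per_pair_sum: dict[str, float] = {v: 0.0 for v in graph}
    total_paths = 0
    n_pairs = 0
    for ligand in ligand_set:
        dist_f, sigma_f = forward[ligand]
        for tf in tf_set:
            if tf == ligand or tf not in dist_f:
                continue
            d = dist_f[tf]
            paths = sigma_f[tf]
            total_paths += paths
            n_pairs += 1
            dist_b, sigma_b = backward[tf]
            for v, dv in dist_f.items():
                if v == ligand or v == tf:
                    continue
                db = dist_b.get(v)
                if db is not None and dv + db == d:
                    through = sigma_f[v] * sigma_b[v]
                    numerator[v] += through
                    if per_pair:
                        per_pair_sum[v] += through / paths

    if n_pairs == 0:
        return {v: 0.0 for v in graph}
    if per_pair:
        return {v: per_pair_sum[v] / n_pairs for v in graph}
    return {v: numerator[v] / total_paths for v in graph}


def centrality_table(
    graph: nx.DiGraph, ligands: Iterable[str], tfs: Iterable[str]
) -> dict[str, dict[str, float]]:
    """All four per-protein measures keyed by metric name."""
    return {
        "degree": {v: float(degree(graph, v)) for v in graph},
        "betweenness": betweenness(graph),
        "closeness": closeness_all(graph),
        "bowtieness": bowtieness(graph, ligands, tfs),
    }


def group_dispersion(
    groups: ParalogGroupSet | Iterable[ParalogGroup],
    metric_values: Mapping[str, float],
) -> dict[str, float]:
    """Sample standard deviation of a metric within each paralog group.

    Only members present in ``metric_values`` (i.e. in the graph) contribute;
    groups with fewer than two present members are omitted.
    """
    if isinstance(groups, ParalogGroupSet):
        groups = groups.groups.values()
    out: dict[str, float] = {}
    for group in groups:
        values = [metric_values[m] for m in group.members if m in metric_values]
        if len(values) >= 2:
            out[group.group_id] = statistics.stdev(values)
    return out
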