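"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive: exhaustive simple-path enumeration,
exhaustive shortest-path enumeration, full enumeration of rank assignments
and urn draws. These stay independent of the code paths they check.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import networkx as nx
import numpy as np


def random_flow_dag(seed: int, max_nodes: int = 12) -> tuple[nx.DiGraph, set, set]:
    """A small random layered DAG with >=1 ligand and >=1 TF."""
    rng = np.random.default_rng(seed)
    n_lig = int(rng.integers(1, 3))
    n_tf = int(rng.integers(1, 3))
    n_layers = int(rng.integers(1, 4))
    budget = max_nodes - n_lig - n_tf
    sizes = []
    for k in range(n_layers):
        size = int(rng.integers(1, max(2, budget // (n_layers - k) + 1)))
        sizes.append(size)
        budget -= size
    ligands = {f"L{i}" for i in range(n_lig)}
    tfs = {f"T{i}" for i in range(n_tf)}
    layers = [sorted(ligands)] + [
        [f"M{k}_{j}" for j in range(s)] for k, s in enumerate(sizes)
    ] + [sorted(tfs)]
    g = nx.DiGraph()
    for layer in layers:
        g.add_nodes_from(layer)
    for a, layer_a in enumerate(layers[:-1]):
        for u in layer_a:
            for b in range(a + 1, len(layers)):
                prob = 0.6 if b == a + 1 else 0.15
                for w in layers[b]:
                    if rng.random() < prob:
                        g.add_edge(u, w)
    return g, ligands, tfs


def essential_oracle(
    graph: nx.DiGraph, ligands, tfs
) -> dict[str, set[tuple[str, str]]]:
    """Broken (ligand, TF) pairs per node by exhaustive simple-path listing.

    A node breaks a pair exactly when it is interior to every simple path of
    that pair.
    """
    broken: dict[str, set] = defaultdict(set)
    for ligand in ligands:
        if ligand not in graph:
            continue
        for tf in tfs:
            if tf == ligand or tf not in graph:
                continue
            paths = list(nx.all_simple_paths(graph, ligand, tf))
            if not paths:
                continue
            always_interior = set(paths[0][1:-1])
            for path in paths[1:]:
                always_interior &= set(path[1:-1])
            for node in always_interior:
                broken[node].add((ligand, tf))
    return dict(broken)


def betweenness_oracle(graph: nx.DiGraph) -> dict[str, float]:
    """Directed betweenness by enumerating every shortest path."""
    out = {v: 0.0 for v in graph}
    for s in graph:
        for t in graph:
            if s == t or not nx.has_path(graph, s, t):
                continue
            paths = list(nx.all_shortest_paths(graph, s, t))
            for v in graph:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                if through:
                    out[v] += through / len(paths)
    return out


def bowtieness_oracle(
    graph: nx.DiGraph, ligands, tfs, per_pair: bool = False
) -> dict[str, float]:
    """Pooled ligand->TF shortest-path fraction by exhaustive enumeration."""
    numer = {v: 0 for v in graph}
    frac = {v: 0.0 for v in graph}
    total = 0
    n_pairs = 0
    for ligand in ligands:
        for tf in tfs:
            if ligand == tf or ligand not in graph or tf not in graph:
                continue
            if not nx.has_path(graph, ligand, tf):
                continue
            paths = list(nx.all_shortest_paths(graph, ligand, tf))
            total += len(paths)
            n_pairs += 1
            for v in graph:
                if v in (ligand, tf):
                    continue
                through = sum(1 for p in paths if v in p)
                numer[v] += through
                frac[v] += through / len(paths)
    if n_pairs == 0:
        return {v: 0.0 for v in graph}
    if per_pair:
        return {v: frac[v] / n_pairs for v in graph}
    return {v: numer[v] / total for v in graph}


def wilcoxon_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all rank assignments."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    observed = sum(ranks[v] for v in x)
    n = len(pooled)
    stats = [
        sum(combo) for combo in itertools.combinations(range(1, n + 1), len(x))
    ]
    mean = len(x) * (n + 1) / 2
    dev = abs(observed - mean)
    extreme = sum(1 for s in stats if abs(s - mean) >= dev - 1e-12)
    return min(1.0, extreme / len(stats))


def hypergeom_oracle(n_background: int, n_hits: int, n_target: int, overlap: int) -> float:
    """Upper-tail urn probability P(X >= overlap) by direct summation."""
    total = math.comb(n_background, n_target)
    acc = 0
    for k in range(overlap, min(n_hits, n_target) + 1):
        acc += math.comb(n_hits, k) * math.comb(n_background - n_hits, n_target - k)
    return acc / total


def merge_assignment_oracle(candidates, d_tol: float = 0.0) -> dict[str, str]:
    """Protein -> winning group id by explicit comparison over candidates."""
    per_protein: dict[str, list] = defaultdict(list)
    for group in candidates:
        for member in group.members:
            per_protein[member].append(group)
    winners = {}
    for protein, groups in per_protein.items():
        best_d = max(g.D for g in groups)
        tied = [g for g in groups if g.D >= best_d - d_tol]
        best_n = max(g.n for g in tied)
        tied = [g for g in tied if g.n == best_n]
        winners[protein] = min(g.group_id for g in tied)
    return winners
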