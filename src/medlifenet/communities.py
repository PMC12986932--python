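"""Map-equation community detection on the validated network.

The map equation scores a partition of a network by the expected
description length, in bits, of a random walk encoded with a two-level
codebook: one index codebook for jumps between modules and one codebook per
module for within-module steps and exits. Good partitions trap the walk
inside modules, so module exits are rare and the per-step description is
short. For an undirected, unweighted graph the walk's stationary
probability of a node is its degree over twice the edge count, and the
two-level codelength is

    L(M) = plogp(q) - 2 * sum_i plogp(q_i)
           - sum_a plogp(p_a) + sum_i plogp(q_i + sum_{a in i} p_a)

with plogp(x) = x log2 x, q_i the probability of exiting module i (cut
edges over 2E) and q their sum.

Communities are found by a seeded, multi-restart greedy search (single-node
moves to neighbouring modules followed by module merges, iterated to a
fixed point), run on the positive-edge subgraph of the validated network:
negative edges mark dissociation and carry no co-occurrence flow. Isolated
nodes become singleton modules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .svn import ValidatedNetwork

__all__ = ["ModulePartition", "map_equation", "detect_communities", "exhaustive_minimum"]


@dataclass(frozen=True)
class ModulePartition:
    """Node → module assignment with the achieved codelength in bits."""

    assignment: dict[str, int]
    n_modules: int
    codelength: float

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.assignment.items()), columns=["node", "module"]
        ).to_csv(path, sep="\t", index=False)

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, lab in self.assignment.items():
            out.setdefault(lab, []).append(node)
        return out


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0.0 else 0.0


def map_equation(partition: dict, graph: nx.Graph) -> float:
    """Two-level map-equation codelength (bits) of a partition of ``graph``.

    ``partition`` maps every node to a module label. The graph is treated as
    undirected and unweighted. With a single module the index codebook
    vanishes and the codelength equals the entropy of the stationary visit
    distribution.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        raise ValueError("graph has no edges; the random walk is undefined")
    missing = [v for v in graph.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition misses nodes: {missing}")

    two_e = 2.0 * graph.number_of_edges()
    p_node = {v: graph.degree(v) / two_e for v in graph.nodes}

    cut = {}     # module -> number of edges leaving it
    p_mod = {}   # module -> stationary mass inside
    for v in graph.nodes:
        p_mod[partition[v]] = p_mod.get(partition[v], 0.0) + p_node[v]
        cut.setdefault(partition[v], 0)
    for u, v in graph.edges:
        if partition[u] != partition[v]:
            cut[partition[u]] += 1
            cut[partition[v]] += 1

    q_mod = {i: cut[i] / two_e for i in cut}
    q = sum(q_mod.values())
    length = _plogp(q)
    length -= 2.0 * sum(_plogp(qi) for qi in q_mod.values())
    length -= sum(_plogp(p) for p in p_node.values())
    length += sum(_plogp(q_mod[i] + p_mod[i]) for i in q_mod)
    return length


def _greedy_once(graph: nx.Graph, rng: np.random.Generator) -> dict:
    """One restart: node moves to neighbouring modules, then module merges,
    repeated until neither improves the codelength."""
    nodes = list(graph.nodes)
    part = {v: i for i, v in enumerate(nodes)}
    best_len = map_equation(part, graph)

    improved = True
    while improved:
        improved = False
        order = list(nodes)
        rng.shuffle(order)
        for v in order:
            current = part[v]
            candidates = {part[u] for u in graph.neighbors(v)} - {current}
            for cand in candidates:
                part[v] = cand
                new_len = map_equation(part, graph)
                if new_len < best_len - 1e-12:
                    best_len = new_len
                    current = cand
                    improved = True
                else:
                    part[v] = current
        # merge phase: try fusing every pair of connected modules
        labels = sorted(set(part.values()))
        module_adj = set()
        for u, v in graph.edges:
            if part[u] != part[v]:
                module_adj.add(frozenset((part[u], part[v])))
        for pair in module_adj:
            i, j = tuple(pair)
            trial = {v: (i if lab == j else lab) for v, lab in part.items()}
            new_len = map_equation(trial, graph)
            if new_len < best_len - 1e-12:
                part = trial
                best_len = new_len
                improved = True
    return part


def _relabel(assignment: dict, node_order: list) -> tuple[dict, int]:
    """Contiguous labels from 1, ordered by first appearance in node_order."""
    mapping: dict = {}
    out = {}
    for v in node_order:
        lab = assignment[v]
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[v] = mapping[lab]
    return out, len(mapping)


def detect_communities(
    net: ValidatedNetwork | nx.Graph,
    seed: int = 0,
    n_restarts: int = 10,
) -> ModulePartition:
    """Partition the validated network's positive-edge subgraph into modules.

    Runs the greedy map-equation search ``n_restarts`` times with a seeded
    generator and keeps the best partition; with no positive edges every
    node becomes its own singleton module (codelength 0 by convention). The
    returned codelength never exceeds that of the one-module partition.
    """
    if isinstance(net, ValidatedNetwork):
        graph = net.positive_subgraph()
    else:
        graph = nx.Graph(net)
    node_order = list(graph.nodes)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")

    active = graph.subgraph([v for v in graph.nodes if graph.degree(v) > 0])
    if active.number_of_edges() == 0:
        warnings.warn("no positive edges; returning all-singleton partition")
        assignment = {v: i + 1 for i, v in enumerate(node_order)}
        return ModulePartition(assignment, len(node_order), 0.0)

    rng = np.random.default_rng(seed)
    best, best_len = None, math.inf
    for _ in range(n_restarts):
        part = _greedy_once(active, rng)
        length = map_equation(part, active)
        if length < best_len:
            best, best_len = part, length

    one_module = {v: 0 for v in active.nodes}
    one_len = map_equation(one_module, active)
    if one_len < best_len:
        best, best_len = one_module, one_len

    # isolated nodes join as singleton modules (no flow, no codelength cost)
    full = dict(best)
    next_label = max(full.values()) + 1
    for v in node_order:
        if v not in full:
            full[v] = next_label
            next_label += 1
    assignment, n_modules = _relabel(full, node_order)
    return ModulePartition(assignment, n_modules, best_len)


def _set_partitions(items: list):
    """All partitions of ``items`` into non-empty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_minimum(graph: nx.Graph) -> tuple[dict, float]:
    """Globally optimal two-level partition by brute force (small graphs).

    Intended for validation on graphs of at most ~10 nodes; the search
    enumerates every set partition.
    """
    nodes = list(graph.nodes)
    best, best_len = None, math.inf
    for blocks in _set_partitions(nodes):
        part = {v: i for i, block in enumerate(blocks) for v in block}
        length = map_equation(part, graph)
        if length < best_len:
            best, best_len = part, length
    return best, best_len
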