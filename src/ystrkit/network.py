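"""Median-joining networks over preprocessed Y-STR haplotypes.

Construction follows the classic scheme: repeatedly build a minimum
spanning network (all tied / epsilon-near links that join distinct
components in a Kruskal pass), propose quasi-medians from node triplets
that share at least two network links, and admit the cheapest medians
whenever they shorten the network; finally, median nodes of degree <= 1
are pruned.  Distances are stepwise by default — repeat counts are
ordered, so a 15 -> 17 change costs two mutational steps — with the
missing-data code 99 treated categorically (one step against any typed
allele, zero against another 99).

Input preprocessing mirrors standard network practice for Y-STRs: the
multi-copy DYS385 is dropped (copies cannot be assigned to a/b),
intermediate alleles are rounded to the nearest repeat, null alleles are
recoded 99, and identical vectors are merged with summed multiplicity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import HaplotypeTable

__all__ = [
    "NetworkInput",
    "Network",
    "preprocess_network_input",
    "weighted_distance",
    "quasi_median",
    "median_joining",
]

NULL_STATE = 99


@dataclass
class NetworkInput:
    """Merged haplotype vectors ready for network construction."""

    loci: tuple[str, ...]
    vectors: list[tuple[int, ...]]
    multiplicities: list[int]
    weights: np.ndarray
    sample_ids: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.multiplicities):
            raise ValueError("multiplicities must be >= 1")
        if len(set(self.vectors)) != len(self.vectors):
            raise ValueError("vectors must be distinct after merging")
        if len(self.weights) != len(self.loci):
            raise ValueError("one weight per locus required")
        if np.any(self.weights <= 0):
            raise ValueError("locus weights must be positive")


def preprocess_network_input(
    table: HaplotypeTable,
    weights: Mapping[str, float] | float = 10.0,
    loci: Sequence[str] | None = None,
) -> NetworkInput:
    """Convert a haplotype table into integer network input.

    Multi-copy loci (DYS385) are removed; intermediate alleles are rounded
    to the nearest repeat (half away from zero); null alleles become the
    code 99; identical vectors merge with summed multiplicity.  *weights*
    is a per-locus mapping or a single uniform value (default 10, the
    conventional network weight).
    """
    if loci is None:
        loci = list(table.panel.single_copy_names())
    else:
        loci = [l for l in loci if not table.panel.locus(l).multi_copy]
    if isinstance(weights, Mapping):
        w = np.array([float(weights.get(l, 10.0)) for l in loci])
    else:
        w = np.full(len(loci), float(weights))
    merged: dict[tuple[int, ...], list[str]] = {}
    for sample in table.sample_ids:
        vec = []
        for locus in loci:
            r = table.call(sample, locus).rounded_repeats()
            vec.append(NULL_STATE if r is None else r)
        merged.setdefault(tuple(vec), []).append(sample)
    vectors = sorted(merged)  # deterministic lexicographic node order
    return NetworkInput(
        loci=tuple(loci),
        vectors=vectors,
        multiplicities=[len(merged[v]) for v in vectors],
        weights=w,
        sample_ids=[merged[v] for v in vectors],
    )


def weighted_distance(
    u: Sequence[int], v: Sequence[int], weights: Sequence[float]
) -> float:
    """Weighted stepwise distance: sum_l w_l * |u_l - v_l|, with 99
    (missing) counting one step against any typed state and zero against
    another 99."""
    if len(u) != len(v):
        raise ValueError("state vectors differ in length")
    total = 0.0
    for a, b, w in zip(u, v, weights):
        if a == NULL_STATE and b == NULL_STATE:
            continue
        if a == NULL_STATE or b == NULL_STATE:
            total += w
        else:
            total += w * abs(a - b)
    return total


def _mismatch_distance(u, v, weights) -> float:
    total = 0.0
    for a, b, w in zip(u, v, weights):
        if a != b:
            total += w
    return total


def quasi_median(u: Sequence[int], v: Sequence[int], x: Sequence[int]) -> tuple[int, ...]:
    """Per-locus median of three integer state vectors.

    99 states resolve by majority; with a single 99 the two typed states
    yield their floor midpoint (deterministic integer consensus).
    """
    out = []
    for a, b, c in zip(u, v, x):
        vals = (a, b, c)
        nulls = sum(s == NULL_STATE for s in vals)
        if nulls >= 2:
            out.append(NULL_STATE)
        elif nulls == 1:
            lo, hi = sorted(s for s in vals if s != NULL_STATE)
            out.append(lo + (hi - lo) // 2)
        else:
            out.append(sorted(vals)[1])
    return tuple(out)


def _edge_list(nodes, dist):
    edges = []
    for i, j in itertools.combinations(range(len(nodes)), 2):
        edges.append((dist(nodes[i], nodes[j]), i, j))
    edges.sort()
    return edges


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _msn_edges(nodes, dist, epsilon: float):
    """Minimum spanning network: Kruskal in cost batches; every link in a
    batch that joins components distinct at batch start is kept."""
    edges = _edge_list(nodes, dist)
    uf = _UnionFind(len(nodes))
    kept = []
    idx = 0
    while idx < len(edges):
        batch_min = edges[idx][0]
        batch = []
        while idx < len(edges) and edges[idx][0] <= batch_min + epsilon + 1e-12:
            batch.append(edges[idx])
            idx += 1
        # evaluate against components as they stood before the batch
        snapshot = {i: uf.find(i) for i in range(len(nodes))}
        adds = [(d, i, j) for d, i, j in batch if snapshot[i] != snapshot[j]]
        for d, i, j in adds:
            kept.append((i, j, d))
            uf.union(i, j)
    return kept


def _mst_length(nodes, dist) -> float:
    uf = _UnionFind(len(nodes))
    total = 0.0
    for d, i, j in _edge_list(nodes, dist):
        if uf.find(i) != uf.find(j):
            uf.union(i, j)
            total += d
    return total


@dataclass
class Network:
    """Final median-joining network.

    ``graph`` is a networkx Graph whose nodes carry ``vector``,
    ``multiplicity`` and ``kind`` (observed/median) attributes and whose
    edges carry ``length``.
    """

    graph: nx.Graph
    loci: tuple[str, ...]
    epsilon: float

    @property
    def total_length(self) -> float:
        return sum(d for _, _, d in self.graph.edges(data="length"))

    def observed_nodes(self) -> list:
        return [n for n, k in self.graph.nodes(data="kind") if k == "observed"]

    def median_nodes(self) -> list:
        return [n for n, k in self.graph.nodes(data="kind") if k == "median"]

    def nodes_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": n,
                "vector": "-".join(str(s) for s in data["vector"]),
                "multiplicity": data["multiplicity"],
                "kind": data["kind"],
            }
            for n, data in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows).set_index("id")

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "length": d}
            for u, v, d in self.graph.edges(data="length")
        ]
        return pd.DataFrame(rows)

    def write_graphml(self, path: str) -> None:
        g = nx.Graph()
        for n, data in self.graph.nodes(data=True):
            g.add_node(
                n,
                vector="-".join(str(s) for s in data["vector"]),
                multiplicity=data["multiplicity"],
                kind=data["kind"],
            )
        for u, v, d in self.graph.edges(data="length"):
            g.add_edge(u, v, length=float(d))
        nx.write_graphml(g, path)


def median_joining(
    inp: NetworkInput,
    epsilon: float = 0.0,
    mode: str = "stepwise",
    max_rounds: int = 1000,
) -> Network:
    """Construct the median-joining network of the input haplotypes.

    *mode* selects the per-locus difference: ``stepwise`` (|delta repeats|,
    the default — repeat counts are ordered states) or ``mismatch``
    (0/1).  *epsilon* relaxes link and median admission by the usual
    tolerance; 0 reproduces the strict minimum spanning network behaviour.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if mode not in ("stepwise", "mismatch"):
        raise ValueError("mode must be 'stepwise' or 'mismatch'")
    w = inp.weights
    base = weighted_distance if mode == "stepwise" else _mismatch_distance
    dist = lambda a, b: base(a, b, w)

    observed = list(inp.vectors)
    if len(observed) == 0:
        raise ValueError("no haplotypes")
    nodes = list(observed)
    if len(nodes) > 1:
        for _ in range(max_rounds):
            length = _mst_length(nodes, dist)
            links = _msn_edges(nodes, dist, epsilon)
            adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
            for i, j, _ in links:
                adj[i].add(j)
                adj[j].add(i)
            node_set = set(nodes)
            candidates: dict[tuple[int, ...], float] = {}
            for c in range(len(nodes)):
                for i, j in itertools.combinations(sorted(adj[c]), 2):
                    m = quasi_median(nodes[c], nodes[i], nodes[j])
                    if m in node_set:
                        continue
                    cost = dist(m, nodes[c]) + dist(m, nodes[i]) + dist(m, nodes[j])
                    if m not in candidates or cost < candidates[m]:
                        candidates[m] = cost
            if not candidates:
                break
            cmin = min(candidates.values())
            chosen = sorted(
                m for m, c in candidates.items() if c <= cmin + epsilon + 1e-12
            )
            trial = nodes + chosen
            if _mst_length(trial, dist) < length - 1e-12:
                nodes = trial
            else:
                break
        else:
            raise RuntimeError("median-joining did not converge")

    observed_set = set(observed)
    # prune weakly attached medians, recomputing links until stable
    while True:
        links = _msn_edges(nodes, dist, epsilon)
        degree = {i: 0 for i in range(len(nodes))}
        for i, j, _ in links:
            degree[i] += 1
            degree[j] += 1
        drop = {
            i for i in range(len(nodes))
            if nodes[i] not in observed_set and degree[i] <= 1
        }
        if not drop:
            break
        nodes = [v for i, v in enumerate(nodes) if i not in drop]

    links = _msn_edges(nodes, dist, epsilon) if len(nodes) > 1 else []
    g = nx.Graph()
    mult = dict(zip(inp.vectors, inp.multiplicities))
    ids = {}
    obs_count = med_count = 0
    for v in nodes:
        if v in observed_set:
            obs_count += 1
            ids[v] = f"H{obs_count}"
            g.add_node(ids[v], vector=v, multiplicity=mult[v], kind="observed")
        else:
            med_count += 1
            ids[v] = f"mv{med_count}"
            g.add_node(ids[v], vector=v, multiplicity=0, kind="median")
    for i, j, d in links:
        g.add_edge(ids[nodes[i]], ids[nodes[j]], length=d)
    return Network(g, inp.loci, epsilon)
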