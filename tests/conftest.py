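"""Shared fixtures: programmatic graph and catalog generators."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nwe.graph_core import WeightedGraph


def random_connected_graph(rng: np.random.Generator, n: int | None = None) -> WeightedGraph:
    """Random connected weighted graph: spanning tree plus ~n extra edges."""
    if n is None:
        n = int(rng.integers(4, 50))
    nodes = [f"n{i:03d}" for i in range(n)]
    edges: dict[tuple[str, str], float] = {}
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges[tuple(sorted((nodes[j], nodes[i])))] = float(rng.uniform(0.1, 10.0))
    for _ in range(n):
        i, j = rng.integers(0, n, 2)
        if i != j:
            key = tuple(sorted((nodes[i], nodes[j])))
            edges.setdefault(key, float(rng.uniform(0.1, 10.0)))
    return WeightedGraph(edges)


def clique_graph(sizes: list[int], weight: float = 1.0, prefix: str = "P") -> tuple[WeightedGraph, list[frozenset[str]]]:
    """Disjoint cliques with uniform internal edge weight; returns graph + planted sets."""
    edges: dict[tuple[str, str], float] = {}
    planted: list[frozenset[str]] = []
    pid = 0
    for size in sizes:
        members = [f"{prefix}{pid + j:03d}" for j in range(size)]
        pid += size
        planted.append(frozenset(members))
        for u, v in itertools.combinations(members, 2):
            edges[(u, v)] = weight
    return WeightedGraph(edges), planted


@pytest.fixture
def triangle() -> WeightedGraph:
    """3-node triangle with weights 2, 4, 1."""
    return WeightedGraph({("a", "b"): 2.0, ("b", "c"): 4.0, ("a", "c"): 1.0})


@pytest.fixture
def path_abc() -> WeightedGraph:
    """3-node path a-b-c with unit weights."""
    return WeightedGraph({("a", "b"): 1.0, ("b", "c"): 1.0})


@pytest.fixture
def fig3_graph() -> WeightedGraph:
    """The motivating two-member cluster: u with incident weights 100/50/80,
    v with incident weights 1/3, connected through a shared neighbourhood."""
    return WeightedGraph(
        {
            ("u", "x1"): 100.0,
            ("u", "x2"): 50.0,
            ("u", "x3"): 80.0,
            ("v", "y1"): 1.0,
            ("v", "y2"): 3.0,
            ("x1", "y1"): 2.0,
        }
    )
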