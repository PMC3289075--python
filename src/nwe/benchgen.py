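"""Synthetic benchmark machinery: altered clique graphs and shuffled networks.

The benchmark starts from a complex catalog (a built-in generator produces
disjoint synthetic complexes so no database download is needed).  The *test
graph* turns every complex into a clique.  *Altered graphs* perturb the
test graph by deleting a fraction ``del`` of its edges and adding a
fraction ``add`` of spurious non-edges (both fractions relative to the
original edge count), then weight surviving original edges with integers
drawn uniformly from [u_min, 100] and added edges from [1, u_max] — the
two-regime weighting that separates true signal from noise.  The full 2x2x2x2
grid of (del, add, u_min, u_max) yields 16 altered graphs.  Independently,
a degree-preserving shuffle randomises a weighted network's topology by
double edge swaps while keeping every node's degree and the multiset of
edge weights.

A grid search evaluates a clustering runner over graphs x parameter sets by
mean quantitative f-measure.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph_core import ComplexCatalog, WeightedGraph
from .matching_stats import evaluate
from .nwe_expand import NWEParams

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkConfig",
    "synthesize_catalog",
    "test_graph",
    "AlteredEdges",
    "alter_graph",
    "assign_weights",
    "altered_graph_suite",
    "degree_preserving_shuffle",
    "grid_search",
    "table1_nwe_grid",
]


def _round_half_up(x: float) -> int:
    """Round half away from zero (documented tie rule for edge-count fractions)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid of alteration and shuffle settings for the synthetic benchmark."""

    del_ratios: tuple[float, ...] = (0.4, 0.8)
    add_ratios: tuple[float, ...] = (0.4, 1.0)
    u_mins: tuple[int, ...] = (30, 70)
    u_maxs: tuple[int, ...] = (30, 70)
    shuffle_ratios: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    replicates: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for u in (*self.u_mins, *self.u_maxs):
            if not (1 <= u <= 100):
                raise ValueError("u_min/u_max values must lie in [1, 100]")
        for r in (*self.del_ratios, *self.add_ratios, *self.shuffle_ratios):
            if r < 0:
                raise ValueError("ratios must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def synthesize_catalog(
    n_complexes: int = 20,
    size_dist: Sequence[int] | Callable[[np.random.Generator], int] | None = None,
    rng_seed: int = 0,
) -> ComplexCatalog:
    """Generate a catalog of disjoint synthetic complexes.

    ``size_dist`` may be an explicit sequence of sizes (one per complex), a
    callable drawing a size from an RNG, or None for the default truncated
    geometric on [4, 20] (p = 0.25), which mimics the small-complex-heavy
    size profile of curated catalogs.  Deterministic per ``rng_seed``.
    """
    if n_complexes < 1:
        raise ValueError("n_complexes must be >= 1")
    rng = np.random.default_rng(rng_seed)

    def default_draw(r: np.random.Generator) -> int:
        while True:
            s = 3 + int(r.geometric(0.25))
            if 4 <= s <= 20:
                return s

    if size_dist is None:
        sizes = [default_draw(rng) for _ in range(n_complexes)]
    elif callable(size_dist):
        sizes = [int(size_dist(rng)) for _ in range(n_complexes)]
    else:
        if len(size_dist) != n_complexes:
            raise ValueError("explicit size list must have one entry per complex")
        sizes = [int(s) for s in size_dist]
    if any(s < 2 for s in sizes):
        raise ValueError("complex sizes must be >= 2")

    complexes = []
    pid = 0
    for ci, size in enumerate(sizes):
        members = frozenset(f"Y{pid + j:04d}" for j in range(size))
        pid += size
        complexes.append((f"S{ci + 1:03d}", members))
    return ComplexCatalog(tuple(complexes), min_size=min(sizes))


def test_graph(catalog: ComplexCatalog) -> WeightedGraph:
    """Clique graph of a catalog: an edge (weight 1) for every within-complex pair."""
    edges: dict[tuple[str, str], float] = {}
    for _, members in catalog:
        ordered = sorted(members)
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                edges[(u, v)] = 1.0
    if not edges:
        raise ValueError("catalog produces no edges (all complexes of size < 2?)")
    return WeightedGraph(edges)


@dataclass(frozen=True)
class AlteredEdges:
    """Edge sets of an altered graph, labelled by provenance."""

    nodes: tuple[str, ...]
    kept: tuple[tuple[str, str], ...]     # surviving original edges
    added: tuple[tuple[str, str], ...]    # spurious edges absent from the test graph


def alter_graph(
    graph: WeightedGraph,
    del_ratio: float,
    add_ratio: float,
    rng_seed: int = 0,
) -> AlteredEdges:
    """Randomly delete and add edges, fractions relative to |E| of ``graph``.

    Deletes round(del_ratio * |E|) original edges uniformly at random and
    adds round(add_ratio * |E|) distinct non-edges (no self-loops, never an
    original edge) sampled uniformly.  Raises if the graph has too few
    non-edges to satisfy the request.
    """
    if not (0 <= del_ratio < 1):
        raise ValueError("del_ratio must lie in [0, 1)")
    if add_ratio < 0:
        raise ValueError("add_ratio must be >= 0")
    rng = np.random.default_rng(rng_seed)
    nodes = graph.nodes
    n = len(nodes)
    originals = sorted((u, v) for u, v, _ in graph.edges())
    n_edges = len(originals)
    n_del = _round_half_up(del_ratio * n_edges)
    n_add = _round_half_up(add_ratio * n_edges)

    keep_idx = rng.choice(n_edges, size=n_edges - n_del, replace=False)
    kept = tuple(originals[i] for i in sorted(keep_idx))

    # enumerate candidate non-edges as encoded upper-triangle indices
    iu, ju = np.triu_indices(n, k=1)
    codes = iu.astype(np.int64) * n + ju
    index = {v: i for i, v in enumerate(nodes)}
    orig_codes = np.array(
        [min(index[u], index[v]) * n + max(index[u], index[v]) for u, v in originals],
        dtype=np.int64,
    )
    mask = ~np.isin(codes, orig_codes)
    candidates = codes[mask]
    if n_add > len(candidates):
        raise ValueError(
            f"cannot add {n_add} edges: only {len(candidates)} non-edges available"
        )
    pick = rng.choice(len(candidates), size=n_add, replace=False)
    added = tuple(
        sorted(
            (nodes[int(c // n)], nodes[int(c % n)]) for c in candidates[np.sort(pick)]
        )
    )
    return AlteredEdges(nodes=nodes, kept=kept, added=added)


def assign_weights(
    altered: AlteredEdges,
    u_min: int,
    u_max: int,
    rng_seed: int = 0,
) -> WeightedGraph:
    """Two-regime integer weighting of an altered graph.

    Surviving original edges draw from Uniform{u_min, ..., 100} (high
    regime); added edges draw from Uniform{1, ..., u_max} (low regime).
    """
    if not (1 <= u_min <= 100 and 1 <= u_max <= 100):
        raise ValueError("u_min and u_max must lie in [1, 100]")
    rng = np.random.default_rng(rng_seed)
    edges: dict[tuple[str, str], float] = {}
    high = rng.integers(u_min, 101, size=len(altered.kept))
    for e, w in zip(altered.kept, high):
        edges[e] = float(w)
    low = rng.integers(1, u_max + 1, size=len(altered.added))
    for e, w in zip(altered.added, low):
        edges[e] = float(w)
    return WeightedGraph(edges)


def altered_graph_suite(
    catalog: ComplexCatalog,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> dict[str, WeightedGraph]:
    """The full grid of altered graphs A_{add,del,umin,umax}.

    One alteration per (del, add) pair, then one weighting per
    (u_min, u_max) pair applied to it; with the default 2x2x2x2 grid this
    yields 16 graphs.  All sub-seeds derive deterministically from
    ``config.rng_seed``.
    """
    base = test_graph(catalog)
    suite: dict[str, WeightedGraph] = {}
    for di, (d, a) in enumerate(itertools.product(config.del_ratios, config.add_ratios)):
        alt_seed = np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, 1, di]).generate_state(1)[0]
        altered = alter_graph(base, d, a, rng_seed=int(alt_seed))
        for wi, (umin, umax) in enumerate(itertools.product(config.u_mins, config.u_maxs)):
            w_seed = np.random.SeedSequence(
                [config.rng_seed & 0x7FFFFFFF, 2, di, wi]
            ).generate_state(1)[0]
            name = f"A_add{a:g}_del{d:g}_umin{umin}_umax{umax}"
            suite[name] = assign_weights(altered, umin, umax, rng_seed=int(w_seed))
    return suite


def degree_preserving_shuffle(
    graph: WeightedGraph,
    k: float,
    rng_seed: int = 0,
) -> WeightedGraph:
    """Randomise topology by double edge swaps, preserving every node's degree.

    Performs round(k * |E|) *successful* swaps: two edges (a, b) and (c, d)
    are rewired to (a, d) and (c, b) — each new edge inheriting the weight
    of the old edge sharing its first endpoint — unless the rewiring would
    create a self-loop or a duplicate edge.  The degree sequence, the edge
    count and the multiset of edge weights are all invariant.  Raises if
    100x the target number of attempts is exceeded (graph too constrained).
    """
    if k < 0:
        raise ValueError("shuffle ratio must be >= 0")
    rng = np.random.default_rng(rng_seed)
    edges = [((u, v) if u <= v else (v, u)) for u, v, _ in graph.edges()]
    weights = {e: graph.weight(*e) for e in edges}
    target = _round_half_up(k * len(edges))
    if target == 0:
        return WeightedGraph(dict(weights))
    edge_set = set(edges)
    done = 0
    attempts = 0
    max_attempts = 100 * target
    while done < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"exceeded {max_attempts} swap attempts for {target} swaps; "
                "graph too constrained to shuffle"
            )
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i] if rng.integers(0, 2) else edges[i][::-1]
        c, d = edges[j] if rng.integers(0, 2) else edges[j][::-1]
        e1 = (a, d) if a <= d else (d, a)
        e2 = (c, b) if c <= b else (b, c)
        if a == d or c == b or e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        w1 = weights.pop(edges[i])
        w2 = weights.pop(edges[j])
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edges[i] = e1
        edges[j] = e2
        edge_set.add(e1)
        edge_set.add(e2)
        weights[e1] = w1
        weights[e2] = w2
        done += 1
    return WeightedGraph(dict(weights))


def table1_nwe_grid() -> list[NWEParams]:
    """The searched parameter grid: 3 restart x 3 cutoff x 3 overlap x 1 min x 3 max = 81."""
    grid = []
    for alpha in (0.6, 0.7, 0.8):
        for cutoff in (0.5, 0.6, 0.7):
            for overlap in (0.1, 0.2, 0.3):
                for max_size in (11, 50, 100):
                    grid.append(
                        NWEParams(
                            alpha=alpha,
                            early_cutoff=cutoff,
                            overlap_threshold=overlap,
                            min_size=4,
                            max_size=max_size,
                        )
                    )
    return grid


def grid_search(
    runner: Callable[[WeightedGraph, NWEParams], object],
    graphs: Mapping[str, WeightedGraph],
    catalog: ComplexCatalog,
    param_grid: Sequence[NWEParams],
    min_size: int = 4,
) -> tuple[NWEParams, pd.DataFrame]:
    """Evaluate every parameter set on every graph; pick the best mean f-measure.

    ``runner(graph, params)`` must return a cluster collection scorable by
    :func:`nwe.matching_stats.evaluate`.  A runner failure on one graph is
    recorded as f-measure 0 with a warning.  Ties are broken toward the
    first parameter set in grid order.  Returns the winner and the full
    score table (one row per parameter set, one column per graph plus the
    mean).
    """
    if not param_grid:
        raise ValueError("parameter grid must be nonempty")
    rows = []
    best_idx = -1
    best_mean = -1.0
    for pi, params in enumerate(param_grid):
        row: dict[str, object] = {
            "alpha": params.alpha,
            "early_cutoff": params.early_cutoff,
            "overlap_threshold": params.overlap_threshold,
            "min_size": params.min_size,
            "max_size": params.max_size,
            "mode": params.mode,
        }
        fs = []
        for name, graph in graphs.items():
            try:
                clusters = runner(graph, params)
                f = evaluate(clusters, catalog, min_size=min_size).f_measure
            except Exception as exc:  # noqa: BLE001 - record and continue
                logger.warning("runner failed on %s with %r: %s", name, params, exc)
                f = 0.0
            row[f"f[{name}]"] = f
            fs.append(f)
        mean_f = float(np.mean(fs)) if fs else 0.0
        row["mean_f"] = mean_f
        rows.append(row)
        if mean_f > best_mean:
            best_mean = mean_f
            best_idx = pi
    table = pd.DataFrame(rows)
    return param_grid[best_idx], table
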