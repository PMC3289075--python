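"""Random walks with restarts on a weighted PPI network.

At every tick a walker at node ``u`` either moves to a neighbour ``v`` with
probability proportional to the edge weight w(u, v), or — with restart
probability ``alpha`` — teleports back to a start node drawn from the
restart vector ``b``.  The fixed point

    x = alpha * b + (1 - alpha) * P^T x

is the stationary vector; its entry p_C(v) is the "random walk distance"
from the start set C to v.  By linearity of the fixed-point equation, the
stationary vector for any weighted start set is the same convex combination
of the single-seed stationary vectors, so all p_s can be precomputed once
per network (optionally persisted to an on-disk cache) and recombined for
every candidate cluster.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy import sparse

from .graph_core import WeightedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "WalkSettings",
    "StationaryVector",
    "TransitionMatrix",
    "transition_probabilities",
    "rwr",
    "rwr_single_all",
    "SingleVectors",
    "combine_stationary",
]


@dataclass(frozen=True)
class WalkSettings:
    """Restart probability, L1 convergence threshold and iteration cap.

    ``alpha`` close to 1 keeps the walker near the start set (the stationary
    vector approaches the restart vector); smaller ``alpha`` lets the walk
    explore a wider neighbourhood and needs more iterations to converge.
    """

    alpha: float = 0.6
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probabilities P(u, v) = w(u,v) / deg_w(u)."""

    matrix: sparse.csr_matrix
    nodes: tuple[str, ...]

    def prob(self, u: str, v: str) -> float:
        i = self.nodes.index(u)
        j = self.nodes.index(v)
        return float(self.matrix[i, j])


class StationaryVector:
    """Probability distribution over graph nodes, with walk metadata.

    ``meta`` records the graph digest, alpha, tolerance, the start support
    and the final iteration count/residual, so that vectors from different
    walks can be checked for compatibility before being combined.
    """

    __slots__ = ("p", "nodes", "meta", "_index")

    def __init__(self, p: np.ndarray, nodes: tuple[str, ...], meta: Mapping[str, object]):
        if len(p) != len(nodes):
            raise ValueError("probability array does not match node list")
        self.p = np.asarray(p, dtype=np.float64)
        self.nodes = nodes
        self.meta = dict(meta)
        self._index: dict[str, int] | None = None

    def __getitem__(self, node: str) -> float:
        if self._index is None:
            self._index = {v: i for i, v in enumerate(self.nodes)}
        return float(self.p[self._index[node]])

    def as_dict(self) -> dict[str, float]:
        return {v: float(x) for v, x in zip(self.nodes, self.p)}

    def sum(self) -> float:
        return float(self.p.sum())


def transition_probabilities(graph: WeightedGraph) -> TransitionMatrix:
    """Normalise edge weights into row-stochastic transition probabilities.

    Every row sums to 1 (no isolated nodes by graph invariant).  Note that
    this normalisation is scale-invariant: multiplying all edge weights by a
    constant leaves P unchanged, i.e. absolute evidence strength is lost.
    """
    adj = graph.adjacency_matrix()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / deg)
    return TransitionMatrix(matrix=(inv @ adj).tocsr(), nodes=graph.nodes)


def _restart_array(graph: WeightedGraph, b: Mapping[str, float]) -> np.ndarray:
    """Validate a restart distribution and densify it over the node order."""
    arr = np.zeros(graph.n_nodes)
    total = 0.0
    for node, mass in b.items():
        if node not in graph:
            raise ValueError(f"restart node {node!r} not in graph")
        if mass < 0:
            raise ValueError(f"negative restart mass on {node!r}")
        arr[graph.index(node)] = mass
        total += mass
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"restart vector sums to {total}, not 1")
    return arr / arr.sum()


def _power_iterate(
    pt: sparse.csr_matrix, b_arr: np.ndarray, settings: WalkSettings
) -> tuple[np.ndarray, int, float]:
    alpha = settings.alpha
    x = b_arr.copy()
    residual = np.inf
    for it in range(1, settings.max_iter + 1):
        x_new = alpha * b_arr + (1.0 - alpha) * pt.dot(x)
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < settings.tol:
            return x, it, residual
    raise RuntimeError(
        f"random walk did not converge within {settings.max_iter} iterations "
        f"(last L1 residual {residual:.3e})"
    )


def rwr(
    graph: WeightedGraph,
    b: Mapping[str, float],
    settings: WalkSettings = WalkSettings(),
) -> StationaryVector:
    """Stationary vector of a random walk with restarts with restart vector b.

    Power iteration from x0 = b until the L1 distance between consecutive
    iterates drops below ``settings.tol``.  Raises ``RuntimeError`` with the
    last residual on non-convergence.
    """
    tm = transition_probabilities(graph)
    pt = tm.matrix.T.tocsr()
    b_arr = _restart_array(graph, b)
    x, iters, residual = _power_iterate(pt, b_arr, settings)
    meta = {
        "digest": graph.digest,
        "alpha": settings.alpha,
        "tol": settings.tol,
        "start": tuple(sorted(n for n, m in b.items() if m > 0)),
        "iterations": iters,
        "residual": residual,
    }
    return StationaryVector(x, graph.nodes, meta)


class SingleVectors(Mapping[str, "StationaryVector"]):
    """All single-seed stationary vectors of one network.

    Mapping from seed node to its stationary vector, plus counters saying
    how many vectors were freshly iterated vs read back from the cache.
    """

    def __init__(
        self,
        vectors: dict[str, StationaryVector],
        nodes: tuple[str, ...],
        n_computed: int,
        n_cache_hits: int,
    ):
        self._vectors = vectors
        self.nodes = nodes
        self.n_computed = n_computed
        self.n_cache_hits = n_cache_hits

    def __getitem__(self, seed: str) -> StationaryVector:
        return self._vectors[seed]

    def __iter__(self) -> Iterator[str]:
        return iter(self._vectors)

    def __len__(self) -> int:
        return len(self._vectors)

    def matrix(self) -> np.ndarray:
        """Dense (n_seeds x n_nodes) matrix S with S[i, j] = p_{node_i}(node_j)."""
        return np.vstack([self._vectors[v].p for v in self.nodes])


def _cache_dir_for(cache_dir: str | Path, graph: WeightedGraph, settings: WalkSettings) -> Path:
    key = f"{graph.digest[:16]}-a{settings.alpha!r}-t{settings.tol!r}"
    return Path(cache_dir) / key


def _atomic_save_npy(path: Path, arr: np.ndarray) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        np.save(tmp, arr)
        os.replace(tmp + ".npy", path)
    finally:
        for leftover in (tmp, tmp + ".npy"):
            if os.path.exists(leftover):
                os.unlink(leftover)


def rwr_single_all(
    graph: WeightedGraph,
    settings: WalkSettings = WalkSettings(),
    cache_dir: str | Path | None = None,
) -> SingleVectors:
    """Compute (or reload) the stationary vector p_s for every node s.

    With ``cache_dir`` set, results are persisted one file per seed under a
    directory keyed by the graph content digest, alpha and tolerance, with a
    self-describing ``meta.json`` (digest, alpha, tol, node order).  A second
    call with identical inputs reads every vector back without iterating;
    corrupt or missing entries are recomputed with a warning.
    """
    tm = transition_probabilities(graph)
    pt = tm.matrix.T.tocsr()
    nodes = graph.nodes

    cdir: Path | None = None
    if cache_dir is not None:
        cdir = _cache_dir_for(cache_dir, graph, settings)
        cdir.mkdir(parents=True, exist_ok=True)
        meta_path = cdir / "meta.json"
        meta = {
            "digest": graph.digest,
            "alpha": settings.alpha,
            "tol": settings.tol,
            "nodes": list(nodes),
        }
        if meta_path.exists():
            try:
                stored = json.loads(meta_path.read_text())
            except (OSError, json.JSONDecodeError):
                stored = None
            if stored != meta:
                logger.warning("cache metadata mismatch in %s; rebuilding", cdir)
                for f in cdir.glob("*.npy"):
                    f.unlink()
                meta_path.write_text(json.dumps(meta))
        else:
            meta_path.write_text(json.dumps(meta))

    vectors: dict[str, StationaryVector] = {}
    n_computed = 0
    n_hits = 0
    for i, seed in enumerate(nodes):
        base_meta = {
            "digest": graph.digest,
            "alpha": settings.alpha,
            "tol": settings.tol,
            "start": (seed,),
        }
        arr: np.ndarray | None = None
        fpath = cdir / f"s{i:06d}.npy" if cdir is not None else None
        if fpath is not None and fpath.exists():
            try:
                loaded = np.load(fpath)
                if loaded.shape == (len(nodes),) and np.isfinite(loaded).all():
                    arr = loaded
                    n_hits += 1
                else:
                    raise ValueError("bad cached array")
            except (OSError, ValueError):
                logger.warning("corrupt cache entry %s; recomputing", fpath)
                arr = None
        if arr is None:
            b_arr = np.zeros(len(nodes))
            b_arr[i] = 1.0
            arr, iters, residual = _power_iterate(pt, b_arr, settings)
            base_meta["iterations"] = iters
            base_meta["residual"] = residual
            n_computed += 1
            if fpath is not None:
                _atomic_save_npy(fpath, arr)
        else:
            base_meta["iterations"] = 0
        vectors[seed] = StationaryVector(arr, nodes, base_meta)
    logger.info(
        "single-seed vectors: %d computed, %d from cache (%d nodes)",
        n_computed, n_hits, len(nodes),
    )
    return SingleVectors(vectors, nodes, n_computed=n_computed, n_cache_hits=n_hits)


def combine_stationary(
    vectors: Mapping[str, StationaryVector],
    weights: Mapping[str, float],
) -> StationaryVector:
    """Convex combination sum_s (w_s / sum w) * p_s of single-seed vectors.

    With equal weights this is exactly the arithmetic mean, i.e. the
    stationary vector of a walk restarting uniformly over the seeds; with
    weights proportional to node weights it is the node-weighted restart
    walk.  All vectors must come from the same (graph, alpha, tol).
    """
    used = [s for s, w in weights.items() if w != 0]
    if not used:
        raise ValueError("weights must not all be zero")
    ref = None
    total = 0.0
    for s in weights:
        w = weights[s]
        if w < 0:
            raise ValueError(f"negative weight for seed {s!r}")
        if s not in vectors:
            raise ValueError(f"no stationary vector for seed {s!r}")
        total += w
    acc: np.ndarray | None = None
    for s in used:
        vec = vectors[s]
        key = (vec.meta.get("digest"), vec.meta.get("alpha"), vec.meta.get("tol"), vec.nodes)
        if ref is None:
            ref = key
        elif key != ref:
            raise ValueError("stationary vectors come from mismatched walks")
        contrib = (weights[s] / total) * vec.p
        acc = contrib if acc is None else acc + contrib
    assert acc is not None and ref is not None
    meta = {
        "digest": ref[0],
        "alpha": ref[1],
        "tol": ref[2],
        "start": tuple(sorted(used)),
        "combined_from": len(used),
    }
    return StationaryVector(acc, vectors[used[0]].nodes, meta)
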