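"""Node-weighted greedy cluster expansion (NWE) and its uniform-restart twin.

A cluster is grown from a seed protein by repeatedly adding the outside
node with the highest random-walk distance from the current cluster.  The
restart mass over cluster members is distributed proportionally to node
weight — the total evidence weight of a protein's interactions — so that
evidence-rich members steer the expansion (``mode="node-weighted"``).
With ``mode="uniform"`` every member restarts with equal mass, which is
the RRW behaviour the method extends.

Each intermediate cluster inside the [min_size, max_size] window is scored
(mean intra-cluster random-walk distance over ordered pairs) and assigned
an empirical statistical significance against uniformly drawn same-size
node sets; the most significant intermediate is the seed's candidate.
Candidates are then de-duplicated by overlap ratio, keeping the more
significant of any redundant pair.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .graph_core import Cluster, ClusterSet, WeightedGraph
from .random_walk import SingleVectors, WalkSettings, rwr_single_all

logger = logging.getLogger(__name__)

__all__ = [
    "NWEParams",
    "node_weights",
    "restart_weights",
    "ScoreMatrix",
    "cluster_score",
    "cluster_significance",
    "expand_from_seed",
    "overlap_ratio",
    "dedup_clusters",
    "run_nwe",
]

# score ties are judged at a tolerance coarser than the walk convergence
# threshold (1e-10), so numerically identical scores compare as equal
_SCORE_TIE_TOL = 1e-9


@dataclass(frozen=True)
class NWEParams:
    """Algorithm parameters; the defaults are the grid-search optima.

    alpha:            restart probability of the walk, in (0, 1].
    early_cutoff:     expansion stops once the best outside node's
                      random-walk distance falls below this fraction of the
                      distance at which the previous node was admitted.
    overlap_threshold: maximum allowed overlap ratio between kept clusters.
    min_size/max_size: cluster size window considered for output.
    mode:             "node-weighted" (NWE) or "uniform" (RRW) restarts.
    significance_samples: Monte-Carlo sample count M for the empirical
                      p-value (resolution 1/(M+1)).
    rng_seed:         master seed for the significance draws.
    """

    alpha: float = 0.6
    early_cutoff: float = 0.5
    overlap_threshold: float = 0.3
    min_size: int = 4
    max_size: int = 100
    mode: str = "node-weighted"
    significance_samples: int = 999
    rng_seed: int = 0
    tol: float = 1e-10
    max_iter: int = 10_000
    overlap_measure: str = "containment"

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.early_cutoff < 1):
            raise ValueError("early_cutoff must lie in (0, 1)")
        if not (0 < self.overlap_threshold < 1):
            raise ValueError("overlap_threshold must lie in (0, 1)")
        if self.min_size < 1 or self.max_size < 1:
            raise ValueError("size bounds must be positive")
        if self.mode not in ("node-weighted", "uniform"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.significance_samples < 99:
            raise ValueError("significance_samples must be >= 99")
        if self.overlap_measure not in ("containment", "jaccard"):
            raise ValueError(f"unknown overlap measure {self.overlap_measure!r}")

    def walk_settings(self) -> WalkSettings:
        return WalkSettings(alpha=self.alpha, tol=self.tol, max_iter=self.max_iter)


def node_weights(graph: WeightedGraph) -> dict[str, float]:
    """Node weight w_v: total sum of the weights of all edges adjacent to v."""
    return graph.weighted_degrees()


def restart_weights(
    cluster: Iterable[str],
    node_weight_map: Mapping[str, float],
    mode: str = "node-weighted",
) -> dict[str, float]:
    """Restart distribution over a cluster's members.

    node-weighted: b_i = w_i / sum_{j in C} w_j;  uniform: b_i = 1/|C|.
    """
    members = sorted(set(cluster))
    if not members:
        raise ValueError("cluster must be nonempty")
    if mode == "uniform":
        mass = 1.0 / len(members)
        return {m: mass for m in members}
    if mode != "node-weighted":
        raise ValueError(f"unknown mode {mode!r}")
    total = float(sum(node_weight_map[m] for m in members))
    return {m: node_weight_map[m] / total for m in members}


class ScoreMatrix:
    """Dense matrix of single-seed stationary probabilities.

    S[i, j] = p_{node_i}(node_j).  Built once per network from the
    precomputed single-seed vectors; cluster scores and Monte-Carlo
    significances reduce to submatrix sums.
    """

    def __init__(self, singles: SingleVectors):
        self.nodes = singles.nodes
        self._index = {v: i for i, v in enumerate(self.nodes)}
        self.S = singles.matrix()

    @property
    def n(self) -> int:
        return len(self.nodes)

    def indices(self, members: Iterable[str]) -> np.ndarray:
        return np.array(sorted(self._index[m] for m in members), dtype=np.intp)

    def score_indices(self, idx: np.ndarray) -> float:
        k = len(idx)
        if k < 2:
            raise ValueError("cluster score needs at least 2 members")
        sub = self.S[np.ix_(idx, idx)]
        return float((sub.sum() - np.trace(sub)) / (k * (k - 1)))

    def sample_scores(self, k: int, m_samples: int, rng: np.random.Generator) -> np.ndarray:
        """Scores of ``m_samples`` uniform random size-k node subsets."""
        # argpartition of uniform noise = uniform subset without replacement
        noise = rng.random((m_samples, self.n))
        subsets = np.argpartition(noise, k - 1, axis=1)[:, :k]
        block = self.S[subsets[:, :, None], subsets[:, None, :]]
        diag = self.S[subsets, subsets]
        return (block.sum(axis=(1, 2)) - diag.sum(axis=1)) / (k * (k - 1))


def _as_matrix(singles: SingleVectors | ScoreMatrix) -> ScoreMatrix:
    return singles if isinstance(singles, ScoreMatrix) else ScoreMatrix(singles)


def cluster_score(members: Iterable[str], singles: SingleVectors | ScoreMatrix) -> float:
    """Mean random-walk distance over ordered pairs (u, v), u != v, within C.

    Self-pairs are excluded: p_u(u) is dominated by the restart mass and
    would swamp the mean.
    """
    sm = _as_matrix(singles)
    return sm.score_indices(sm.indices(members))


def _members_entropy(members: Iterable[str]) -> int:
    return zlib.crc32("\t".join(sorted(members)).encode())


def cluster_significance(
    members: Iterable[str],
    singles: SingleVectors | ScoreMatrix,
    m_samples: int = 999,
    rng_seed: int = 0,
) -> float:
    """Empirical p-value of a cluster's score against uniform same-size sets.

    Draws ``m_samples`` uniform random node subsets R of size |C| and returns
    (1 + #{R : score(R) > score(C)}) / (m_samples + 1); the add-one term
    accounts for the observed cluster itself, so a draw that merely ties it
    (e.g. redraws the same subset) is not double-counted and the best
    possible cluster attains exactly 1/(M+1).  Deterministic given
    ``rng_seed``: the RNG stream is derived from the seed and the sorted
    member list, so the value does not depend on evaluation order.
    """
    if m_samples < 99:
        raise ValueError("m_samples must be >= 99")
    sm = _as_matrix(singles)
    members = set(members)
    if len(members) > sm.n:
        raise ValueError("cluster larger than the graph")
    target = sm.score_indices(sm.indices(members))
    rng = np.random.default_rng(
        np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, _members_entropy(members)])
    )
    scores = sm.sample_scores(len(members), m_samples, rng)
    hits = int((scores > target + 1e-12).sum())
    return (1 + hits) / (m_samples + 1)


def _score_and_significance(
    members: frozenset[str],
    sm: ScoreMatrix,
    params: NWEParams,
    cache: dict[frozenset[str], tuple[float, float]] | None,
) -> tuple[float, float]:
    if cache is not None and members in cache:
        return cache[members]
    if len(members) < 2:
        stats = (0.0, 1.0)
    else:
        score = cluster_score(members, sm)
        sig = cluster_significance(
            members, sm, m_samples=params.significance_samples, rng_seed=params.rng_seed
        )
        stats = (score, sig)
    if cache is not None:
        cache[members] = stats
    return stats


def _better_candidate(cand: Cluster, best: Cluster) -> bool:
    """Selection order: significance asc, then score desc (1e-9 tie band),
    then size desc, then lexicographically smallest member tuple."""
    if cand.significance != best.significance:
        return cand.significance < best.significance
    if abs(cand.score - best.score) > _SCORE_TIE_TOL:
        return cand.score > best.score
    if cand.size != best.size:
        return cand.size > best.size
    return cand.sorted_members() < best.sorted_members()


def expand_from_seed(
    graph: WeightedGraph,
    seed: str,
    params: NWEParams,
    singles: SingleVectors,
    score_matrix: ScoreMatrix | None = None,
    return_trace: bool = False,
    _stats_cache: dict[frozenset[str], tuple[float, float]] | None = None,
) -> Cluster | None | tuple[Cluster | None, tuple[str, ...]]:
    """Greedily expand a cluster from ``seed`` and return its best intermediate.

    Starting from C = {seed}, repeatedly combines the members' single-seed
    stationary vectors (restart mass per ``params.mode``) and adds the
    outside node with the highest random-walk distance from C, breaking
    ties toward the lexicographically smallest ID.  Expansion stops at
    ``max_size``, when no outside node is reachable, or on early cutoff:
    once |C| >= min_size, a best-outsider probability below
    ``early_cutoff`` times the admission probability of the previous node
    ends the walk.  Among intermediates within the size window the one with
    minimal significance is returned (ties: higher score, then larger
    cluster); ``None`` if the window captured nothing.

    With ``return_trace=True`` also returns the node addition sequence.
    """
    if seed not in graph:
        raise ValueError(f"seed {seed!r} not in graph")
    sm = score_matrix if score_matrix is not None else ScoreMatrix(singles)
    nodes = sm.nodes
    n = sm.n

    if params.mode == "node-weighted":
        nw = node_weights(graph)
        weight_arr = np.array([nw[v] for v in nodes])
        if np.all(weight_arr == weight_arr[0]):
            # equal node weights reduce exactly to the uniform-restart walk;
            # use unit weights so the reduction holds bitwise, not just to
            # rounding error (exact ties must break identically in both modes)
            weight_arr = np.ones(n)
    else:
        weight_arr = np.ones(n)

    seed_idx = sm._index[seed]
    in_cluster = np.zeros(n, dtype=bool)
    in_cluster[seed_idx] = True
    trace: list[str] = [seed]
    # running unnormalised combination of member vectors (Theorem-1 shortcut)
    acc = weight_arr[seed_idx] * sm.S[seed_idx]
    wsum = weight_arr[seed_idx]

    recorded: list[frozenset[str]] = []
    q_prev: float | None = None

    while True:
        size = int(in_cluster.sum())
        if params.min_size <= size <= params.max_size:
            recorded.append(frozenset(nodes[i] for i in np.flatnonzero(in_cluster)))
        if size >= params.max_size:
            break
        p = acc / wsum
        p_masked = np.where(in_cluster, -1.0, p)
        j = int(np.argmax(p_masked))  # node order is sorted: first max = lex smallest
        p_star = float(p_masked[j])
        if p_star <= 0.0:
            break  # nothing reachable outside the cluster
        if size >= params.min_size and q_prev is not None and p_star < params.early_cutoff * q_prev:
            break
        in_cluster[j] = True
        trace.append(nodes[j])
        acc = acc + weight_arr[j] * sm.S[j]
        wsum += weight_arr[j]
        q_prev = p_star

    best: Cluster | None = None
    for members in recorded:
        score, sig = _score_and_significance(members, sm, params, _stats_cache)
        cand = Cluster(members=members, score=score, significance=sig)
        if best is None or _better_candidate(cand, best):
            best = cand
    if return_trace:
        return best, tuple(trace)
    return best


def overlap_ratio(c1: Iterable[str], c2: Iterable[str], measure: str = "containment") -> float:
    """Overlap between two clusters in [0, 1].

    ``containment`` (default): |C1 n C2| / min(|C1|, |C2|) — near-subsets
    count as fully redundant.  ``jaccard``: |C1 n C2| / |C1 u C2|.
    """
    s1, s2 = set(c1), set(c2)
    if not s1 or not s2:
        raise ValueError("clusters must be nonempty")
    inter = len(s1 & s2)
    if measure == "containment":
        return inter / min(len(s1), len(s2))
    if measure == "jaccard":
        return inter / len(s1 | s2)
    raise ValueError(f"unknown overlap measure {measure!r}")


def dedup_clusters(
    candidates: Iterable[Cluster],
    overlap_threshold: float = 0.3,
    measure: str = "containment",
) -> ClusterSet:
    """Greedy redundancy filter: keep the more significant of overlapping pairs.

    Candidates are ordered by (significance asc, score desc, size desc,
    member list); a candidate is kept iff its overlap ratio with every
    already-kept cluster is at most ``overlap_threshold``.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (c.significance, -round(c.score, 9), -c.size, c.sorted_members()),
    )
    kept: list[Cluster] = []
    for cand in ordered:
        if all(
            overlap_ratio(cand.members, k.members, measure) <= overlap_threshold
            for k in kept
        ):
            kept.append(cand)
    return ClusterSet(tuple(kept))


def run_nwe(
    graph: WeightedGraph,
    params: NWEParams = NWEParams(),
    cache_dir: str | None = None,
) -> ClusterSet:
    """Full pipeline: single-seed walks, per-seed expansion, de-duplication.

    Every node of the graph is used as a seed; each seed contributes its
    best-significance intermediate cluster as a candidate.  With
    ``params.mode == "uniform"`` this reproduces the equal-restart (RRW)
    behaviour.  Deterministic given ``params.rng_seed``.
    """
    singles = rwr_single_all(graph, params.walk_settings(), cache_dir)
    sm = ScoreMatrix(singles)
    stats_cache: dict[frozenset[str], tuple[float, float]] = {}
    candidates: list[Cluster] = []
    for seed in graph.nodes:
        result = expand_from_seed(
            graph, seed, params, singles, score_matrix=sm, _stats_cache=stats_cache
        )
        if result is not None:
            candidates.append(result)
    # identical member sets from different seeds collapse to one candidate
    unique: dict[frozenset[str], Cluster] = {}
    for cand in candidates:
        unique.setdefault(cand.members, cand)
    clusters = dedup_clusters(
        unique.values(), params.overlap_threshold, params.overlap_measure
    )
    logger.info(
        "run_nwe: %d seeds -> %d candidates (%d distinct) -> %d clusters",
        graph.n_nodes, len(candidates), len(unique), len(clusters),
    )
    provenance = {
        "network_digest": graph.digest,
        "params": {k: getattr(params, k) for k in NWEParams.__dataclass_fields__},
        "n_seeds": graph.n_nodes,
        "n_candidates": len(candidates),
    }
    return ClusterSet(clusters.clusters, provenance=provenance)
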