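"""Containers and on-disk formats for networks, complex catalogs and clusters.

A protein-protein interaction (PPI) network is an undirected graph whose
nodes are protein identifiers and whose edges carry a strictly positive
weight — the integrated strength of experimental evidence for the physical
interaction (WI-PHI-style edge lists are the canonical input).  A complex
catalog is a list of gold-standard protein sets (CYC2008/MIPS-style, one
complex per line).  Predicted clusters are written one per line as
tab-separated member IDs with the cluster's statistical significance
appended as the last token.

Protein identifiers are opaque, case-sensitive strings; no ORF/gene-name
normalisation is attempted.
"""

from __future__ import annotations

import hashlib
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "WeightedGraph",
    "ComplexCatalog",
    "Cluster",
    "ClusterSet",
    "read_edge_list",
    "write_edge_list",
    "read_complex_catalog",
    "read_clusters",
    "write_clusters",
]


class FormatError(ValueError):
    """An input file violates its declared format."""


def _atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (tmp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class WeightedGraph:
    """Undirected graph with string node IDs and positive edge weights.

    Invariants enforced at construction: no self-loops, all weights strictly
    positive, no isolated nodes (every node is an endpoint of at least one
    edge), each undirected edge stored once.
    """

    __slots__ = ("_adj", "_edges", "_nodes", "_index", "_csr", "_digest")

    def __init__(self, edges: Mapping[tuple[str, str], float]):
        adj: dict[str, dict[str, float]] = {}
        canon: dict[tuple[str, str], float] = {}
        for (u, v), w in edges.items():
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            w = float(w)
            if not np.isfinite(w) or w <= 0:
                raise ValueError(f"non-positive weight {w!r} on edge ({u!r}, {v!r})")
            key = (u, v) if u <= v else (v, u)
            if key in canon:
                raise ValueError(f"duplicate edge {key!r}")
            canon[key] = w
            adj.setdefault(u, {})[v] = w
            adj.setdefault(v, {})[u] = w
        if not canon:
            raise ValueError("graph must contain at least one edge")
        self._edges = canon
        self._adj = adj
        self._nodes: tuple[str, ...] = tuple(sorted(adj))
        self._index = {v: i for i, v in enumerate(self._nodes)}
        self._csr: sparse.csr_matrix | None = None
        self._digest: str | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node IDs in lexicographic order."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def index(self, node: str) -> int:
        return self._index[node]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for (u, v), w in self._edges.items():
            yield u, v, w

    def has_edge(self, u: str, v: str) -> bool:
        key = (u, v) if u <= v else (v, u)
        return key in self._edges

    def weight(self, u: str, v: str) -> float:
        key = (u, v) if u <= v else (v, u)
        return self._edges[key]

    def neighbors(self, u: str) -> Mapping[str, float]:
        return self._adj[u]

    def weighted_degree(self, u: str) -> float:
        return float(sum(self._adj[u].values()))

    def weighted_degrees(self) -> dict[str, float]:
        """Node weight map: total evidence weight incident to each protein."""
        return {v: float(sum(nbrs.values())) for v, nbrs in self._adj.items()}

    # -- derived structures ------------------------------------------------

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Symmetric weighted adjacency in CSR form, rows in node order."""
        if self._csr is None:
            n = self.n_nodes
            rows, cols, vals = [], [], []
            for (u, v), w in self._edges.items():
                i, j = self._index[u], self._index[v]
                rows += [i, j]
                cols += [j, i]
                vals += [w, w]
            self._csr = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(n, n), dtype=np.float64
            )
        return self._csr

    @property
    def digest(self) -> str:
        """SHA-256 of the canonicalised edge list (content, not file path)."""
        if self._digest is None:
            h = hashlib.sha256()
            for u, v in sorted(self._edges):
                w = self._edges[(u, v)]
                h.update(f"{u}\t{v}\t{w!r}\n".encode())
            self._digest = h.hexdigest()
        return self._digest

    def scaled(self, c: float) -> "WeightedGraph":
        """Copy of the graph with every edge weight multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return WeightedGraph({e: w * c for e, w in self._edges.items()})

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"WeightedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


_DEDUP_POLICIES: dict[str, Callable[[float, float], float]] = {
    "max": max,
    "sum": lambda a, b: a + b,
    "first": lambda a, b: a,
}


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    dedup_policy: str = "max",
) -> WeightedGraph:
    """Read a 3-column (protein1, protein2, weight) edge list.

    Both plain whitespace/tab-separated files and the WI-PHI export shape are
    accepted (``dialect`` is informational; both share the same column
    layout).  A header line is detected by a non-numeric third column.
    Self-loops are dropped with a logged count; duplicate pairs are resolved
    by ``dedup_policy`` (``max`` — default, ``sum`` or ``first``).

    Raises
    ------
    FormatError
        On a malformed line (fewer than 3 columns, non-numeric or
        non-positive weight), with the offending line number, or if no
        usable edge survives.
    """
    if dedup_policy not in _DEDUP_POLICIES:
        raise ValueError(f"unknown dedup policy {dedup_policy!r}")
    combine = _DEDUP_POLICIES[dedup_policy]

    edges: dict[tuple[str, str], float] = {}
    n_self_loops = 0
    n_dups = 0
    first_data_line = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(cols)}")
            if first_data_line:
                first_data_line = False
                if not _is_number(cols[2]):
                    logger.debug("header line detected at %s:%d", path, lineno)
                    continue
            u, v, wtok = cols[0], cols[1], cols[2]
            if not _is_number(wtok):
                raise FormatError(f"{path}:{lineno}: non-numeric weight {wtok!r}")
            w = float(wtok)
            if not np.isfinite(w) or w <= 0:
                raise FormatError(f"{path}:{lineno}: weight must be a positive real, got {wtok!r}")
            if u == v:
                n_self_loops += 1
                continue
            key = (u, v) if u <= v else (v, u)
            if key in edges:
                n_dups += 1
                edges[key] = combine(edges[key], w)
            else:
                edges[key] = w
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, n_self_loops)
    if n_dups:
        logger.warning("%s: resolved %d duplicate edge line(s) with policy %r", path, n_dups, dedup_policy)
    if not edges:
        raise FormatError(f"{path}: no usable edges")
    g = WeightedGraph(edges)
    logger.info("%s: read %d nodes, %d edges", path, g.n_nodes, g.n_edges)
    return g


def write_edge_list(graph: WeightedGraph, path: str | Path, header: str | None = None) -> None:
    """Write a graph back to a 3-column TSV edge list (atomic)."""
    lines = []
    if header:
        for hline in header.splitlines():
            lines.append(f"# {hline}")
    for u, v in sorted((u, v) for u, v, _ in graph.edges()):
        w = graph.weight(u, v)
        wtxt = f"{int(w)}" if float(w).is_integer() else f"{w!r}"
        lines.append(f"{u}\t{v}\t{wtxt}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


@dataclass(frozen=True)
class ComplexCatalog:
    """Gold-standard protein complexes with a minimum-size filter applied."""

    complexes: tuple[tuple[str, frozenset[str]], ...]
    min_size: int = 1

    def __post_init__(self) -> None:
        for name, members in self.complexes:
            if len(members) < self.min_size:
                raise ValueError(f"complex {name!r} smaller than min_size={self.min_size}")
            if any(not m for m in members):
                raise ValueError(f"complex {name!r} contains an empty member ID")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self.complexes)

    def member_sets(self) -> list[frozenset[str]]:
        return [members for _, members in self.complexes]

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.complexes:
            out |= members
        return out


def read_complex_catalog(
    path: str | Path,
    min_size: int = 4,
    named: bool = False,
) -> ComplexCatalog:
    """Read a one-complex-per-line catalog of whitespace-separated protein IDs.

    With ``named=True`` the first column of each line is the complex name;
    otherwise names are generated.  Complexes with fewer than ``min_size``
    distinct members are excluded; duplicate IDs within a line are collapsed
    with a warning.
    """
    complexes: list[tuple[str, frozenset[str]]] = []
    n_read = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if named:
                if len(tokens) < 2:
                    raise FormatError(f"{path}:{lineno}: named catalog line needs >=2 columns")
                name, ids = tokens[0], tokens[1:]
            else:
                name, ids = f"cpx{lineno:04d}", tokens
            n_read += 1
            members = frozenset(ids)
            if len(members) < len(ids):
                logger.warning("%s:%d: duplicate IDs within complex %r collapsed", path, lineno, name)
            if len(members) >= min_size:
                complexes.append((name, members))
    if n_read == 0:
        raise FormatError(f"{path}: empty catalog")
    logger.info("%s: read %d complexes, kept %d of size >= %d", path, n_read, len(complexes), min_size)
    return ComplexCatalog(tuple(complexes), min_size=min_size)


@dataclass(frozen=True)
class Cluster:
    """A predicted protein set with its score and statistical significance.

    ``significance`` is a p-value-like quantity in (0, 1]; lower means a
    more surprising (better) cluster.  ``score`` is the mean intra-cluster
    random-walk distance (higher is denser).
    """

    members: frozenset[str]
    score: float = 0.0
    significance: float = 1.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not (0 < self.significance <= 1):
            raise ValueError("significance must lie in (0, 1]")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass(frozen=True)
class ClusterSet:
    """Deterministically ordered collection of predicted clusters."""

    clusters: tuple[Cluster, ...] = ()
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self.clusters)

    def __getitem__(self, i: int) -> Cluster:
        return self.clusters[i]

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.clusters]


def write_clusters(clusters: Iterable[Cluster] | ClusterSet, path: str | Path) -> None:
    """Write clusters one per line: tab-separated member IDs, significance last."""
    lines = []
    for c in clusters:
        lines.append("\t".join(c.sorted_members()) + f"\t{c.significance:.6f}")
    text = "\n".join(lines)
    _atomic_write_text(path, text + "\n" if text else "")


def read_clusters(path: str | Path) -> ClusterSet:
    """Read a cluster file written by :func:`write_clusters`.

    The last whitespace-separated token of each line is the significance;
    the remaining tokens are member IDs.  Scores are not persisted in this
    format and read back as 0.0.
    """
    out: list[Cluster] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise FormatError(f"{path}:{lineno}: expected members plus significance")
            if not _is_number(tokens[-1]):
                raise FormatError(f"{path}:{lineno}: unreadable significance token {tokens[-1]!r}")
            sig = float(tokens[-1])
            if not (0 < sig <= 1):
                raise FormatError(f"{path}:{lineno}: significance {sig} outside (0, 1]")
            out.append(Cluster(members=frozenset(tokens[:-1]), significance=sig))
    return ClusterSet(tuple(out), provenance={"source": str(path)})
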