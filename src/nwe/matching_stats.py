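"""Quantitative matching statistics between predicted clusters and a catalog.

The concordance rate between two protein sets is a rigorous set-similarity
score: 1 only for identical sets, 0 for disjoint ones, and strictly below 1
for proper subsets.  Cluster-wise precision (best concordance of a cluster
against any known complex) and complex-wise recall (best concordance of a
complex against any cluster) are aggregated into quantitative precision and
recall as log-size-weighted means — a given overlap proportion is less
likely by chance for a larger set, so larger sets weigh more.  Precision
averages only clusters that overlap the catalog at all (the catalog is
incomplete; non-overlapping clusters may be genuine novel complexes), while
recall averages over *all* known complexes.  The f-measure is the harmonic
mean of the two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .graph_core import Cluster, ClusterSet, ComplexCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "concordance",
    "cluster_precision",
    "complex_recall",
    "quantitative_precision",
    "quantitative_recall",
    "f_measure",
    "EvaluationReport",
    "evaluate",
]


def concordance(s1: Iterable[str], s2: Iterable[str], measure: str = "jaccard") -> float:
    """Concordance rate between two protein sets, in [0, 1].

    ``jaccard`` (default): |s1 n s2| / |s1 u s2|.  ``sqoverlap``:
    |s1 n s2|^2 / (|s1| * |s2|).  Both are 1 iff the sets are identical,
    0 iff disjoint, and < 1 for proper subsets.
    """
    a, b = set(s1), set(s2)
    if not a or not b:
        raise ValueError("concordance is undefined for empty sets")
    inter = len(a & b)
    if measure == "jaccard":
        return inter / len(a | b)
    if measure == "sqoverlap":
        return inter * inter / (len(a) * len(b))
    raise ValueError(f"unknown concordance measure {measure!r}")


def cluster_precision(
    cluster: Iterable[str],
    catalog: Sequence[Iterable[str]],
    measure: str = "jaccard",
) -> float:
    """Best concordance of a predicted cluster with any known complex."""
    if not catalog:
        raise ValueError("catalog must be nonempty")
    return max(concordance(cluster, k, measure) for k in catalog)


def complex_recall(
    complex_members: Iterable[str],
    clusters: Sequence[Iterable[str]],
    measure: str = "jaccard",
) -> float:
    """Best concordance of a known complex with any predicted cluster."""
    if not clusters:
        return 0.0
    return max(concordance(complex_members, c, measure) for c in clusters)


def quantitative_precision(
    clusters: Sequence[Iterable[str]],
    catalog: Sequence[Iterable[str]],
    measure: str = "jaccard",
) -> float:
    """Log-size-weighted mean of the *non-zero* cluster-wise precisions.

    P = sum_{c in C'} log|c| * precision_K(c) / sum_{c in C'} log|c| with
    C' = {c : precision_K(c) > 0}.  Invariant to the logarithm base.
    Returns 0 if no cluster overlaps the catalog.
    """
    num = 0.0
    z = 0.0
    n_size1 = 0
    for c in clusters:
        members = set(c)
        p = cluster_precision(members, catalog, measure)
        if p <= 0:
            continue
        w = math.log(len(members))
        if w == 0:
            n_size1 += 1
            continue
        num += w * p
        z += w
    if n_size1:
        logger.warning("%d overlapping size-1 cluster(s) carry zero log weight", n_size1)
    if z == 0:
        return 0.0
    return num / z


def quantitative_recall(
    clusters: Sequence[Iterable[str]],
    catalog: Sequence[Iterable[str]],
    measure: str = "jaccard",
) -> float:
    """Log-size-weighted mean recall over *all* known complexes.

    R = sum_{k in K} log|k| * recall_C(k) / sum_{k in K} log|k|; complexes
    matched by no cluster contribute zero recall but full weight.
    """
    if not catalog:
        raise ValueError("catalog must be nonempty")
    cluster_sets = [set(c) for c in clusters]
    num = 0.0
    z = 0.0
    for k in catalog:
        members = set(k)
        w = math.log(len(members))
        z += w
        num += w * complex_recall(members, cluster_sets, measure)
    if z == 0:
        return 0.0
    return num / z


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2PR / (P + R); 0 when both components are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvaluationReport:
    """Summary and per-item tables of a cluster-vs-catalog evaluation."""

    precision: float
    recall: float
    f_measure: float
    n_clusters: int
    n_overlapping: int
    per_cluster: pd.DataFrame
    per_complex: pd.DataFrame

    def summary(self) -> str:
        frac = self.n_overlapping / self.n_clusters if self.n_clusters else 0.0
        return (
            f"# clusters\t{self.n_clusters}\n"
            f"# overlaps\t{self.n_overlapping} ({frac:.2f})\n"
            f"Precision\t{self.precision:.4f}\n"
            f"Recall\t{self.recall:.4f}\n"
            f"F-measure\t{self.f_measure:.4f}\n"
        )


def _member_sets(collection) -> list[frozenset[str]]:
    if isinstance(collection, (ClusterSet, ComplexCatalog)):
        return collection.member_sets()
    out = []
    for item in collection:
        if isinstance(item, Cluster):
            out.append(item.members)
        else:
            out.append(frozenset(item))
    return out


def evaluate(
    clusters,
    catalog,
    min_size: int = 4,
    measure: str = "jaccard",
) -> EvaluationReport:
    """Score any collection of predicted clusters against a complex catalog.

    Accepts ClusterSet/ComplexCatalog instances or plain iterables of
    protein sets, so external methods' cluster files can be scored too.
    The ``min_size`` filter (default 4) applies to both clusters and
    complexes before any statistic is computed.
    """
    cluster_sets = [s for s in _member_sets(clusters) if len(s) >= min_size]
    complex_sets = [s for s in _member_sets(catalog) if len(s) >= min_size]
    if not complex_sets:
        raise ValueError(f"catalog has no complexes of size >= {min_size}")

    per_cluster_rows = []
    for s in cluster_sets:
        p = cluster_precision(s, complex_sets, measure)
        per_cluster_rows.append(
            {"members": ";".join(sorted(s)), "size": len(s), "precision": p}
        )
    per_complex_rows = []
    for s in complex_sets:
        r = complex_recall(s, cluster_sets, measure) if cluster_sets else 0.0
        per_complex_rows.append(
            {"members": ";".join(sorted(s)), "size": len(s), "recall": r}
        )

    per_cluster = pd.DataFrame(per_cluster_rows, columns=["members", "size", "precision"])
    per_complex = pd.DataFrame(per_complex_rows, columns=["members", "size", "recall"])

    if cluster_sets:
        precision = quantitative_precision(cluster_sets, complex_sets, measure)
        recall = quantitative_recall(cluster_sets, complex_sets, measure)
    else:
        precision = 0.0
        recall = 0.0
    n_overlapping = int((per_cluster["precision"] > 0).sum()) if cluster_sets else 0
    return EvaluationReport(
        precision=precision,
        recall=recall,
        f_measure=f_measure(precision, recall),
        n_clusters=len(cluster_sets),
        n_overlapping=n_overlapping,
        per_cluster=per_cluster,
        per_complex=per_complex,
    )
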