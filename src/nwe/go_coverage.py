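"""Semantic homogeneity of predicted clusters via GO-slim term coverage.

The coverage of a cluster C by a term t is the fraction of C's members
annotated with t; the coverage of C over an ontology aspect is the maximum
over that aspect's terms.  Unannotated members stay in the denominator, so
coverage penalises them.  Records are split by whether the cluster overlaps
the gold-standard catalog, binned into the frequency distribution
(r - 0.1, r] for r = 0.1 ... 1.0 (plus an exact-zero bin), and the Pearson
correlation between cluster significance and coverage is tested two-sided
against a zero population correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import ComplexCatalog, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "CoverageRecord",
    "read_go_slim",
    "coverage",
    "coverage_histogram",
    "significance_coverage_correlation",
]

_ASPECTS = ("C", "P", "F")


@dataclass(frozen=True)
class AnnotationMap:
    """Gene-product -> GO-slim term sets for one ontology aspect.

    Aspects: C (cellular component), P (biological process),
    F (molecular function).  Proteins absent from the map have an empty
    annotation set.
    """

    aspect: str
    mapping: Mapping[str, frozenset[str]]

    def terms(self, protein: str) -> frozenset[str]:
        return self.mapping.get(protein, frozenset())

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class CoverageRecord:
    """Best-term coverage of one cluster over one ontology aspect."""

    members: frozenset[str]
    best_term: str | None
    coverage: float
    overlaps_catalog: bool | None = None


def read_go_slim(
    path: str | Path,
    aspect: str,
    dialect: str = "auto",
) -> AnnotationMap:
    """Read a gene -> GO-slim mapping, filtered to one ontology aspect.

    Dialects: ``sgd`` — the SGD ``go_slim_mapping.tab`` layout (tab-separated:
    ORF, gene name, SGDID, aspect, slim term, GO ID, feature type); ``simple``
    — 3 columns (protein, aspect, term); ``auto`` picks per line by column
    count.  Multiple rows per protein accumulate term sets.
    """
    if aspect not in _ASPECTS:
        raise ValueError(f"unknown ontology aspect {aspect!r}; expected one of {_ASPECTS}")
    if dialect not in ("auto", "sgd", "simple"):
        raise ValueError(f"unknown dialect {dialect!r}")
    mapping: dict[str, set[str]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("!"):
                continue
            cols = line.split("\t")
            if dialect == "sgd" or (dialect == "auto" and len(cols) >= 6):
                if len(cols) < 6:
                    raise FormatError(f"{path}:{lineno}: SGD mapping needs >= 6 columns")
                protein, row_aspect, term = cols[0], cols[3], cols[4]
            elif dialect == "simple" or (dialect == "auto" and len(cols) == 3):
                protein, row_aspect, term = cols[0], cols[1], cols[2]
            else:
                raise FormatError(
                    f"{path}:{lineno}: unrecognised column layout ({len(cols)} columns)"
                )
            if row_aspect not in _ASPECTS:
                raise FormatError(f"{path}:{lineno}: unknown aspect code {row_aspect!r}")
            n_rows += 1
            if row_aspect != aspect or not term:
                continue
            mapping.setdefault(protein, set()).add(term)
    if not mapping:
        logger.warning("%s: no annotations for aspect %r (%d rows read)", path, aspect, n_rows)
    return AnnotationMap(aspect=aspect, mapping={p: frozenset(t) for p, t in mapping.items()})


def coverage(
    cluster: Iterable[str],
    annotation: AnnotationMap,
    catalog: ComplexCatalog | Sequence[Iterable[str]] | None = None,
) -> CoverageRecord:
    """Maximum term coverage of a cluster over the annotation's aspect.

    cov_t = |{p in C : t in ann(p)}| / |C|; the record carries the maximum
    over terms and the lexicographically smallest maximising term (None if
    no member is annotated).  With a catalog given, the record also flags
    whether the cluster shares any protein with any complex.
    """
    members = frozenset(cluster)
    if not members:
        raise ValueError("cluster must be nonempty")
    counts: dict[str, int] = {}
    for p in members:
        for t in annotation.terms(p):
            counts[t] = counts.get(t, 0) + 1
    if counts:
        best_count = max(counts.values())
        best_term = min(t for t, c in counts.items() if c == best_count)
        cov = best_count / len(members)
    else:
        best_term = None
        cov = 0.0
    overlaps: bool | None = None
    if catalog is not None:
        sets = (
            catalog.member_sets()
            if isinstance(catalog, ComplexCatalog)
            else [set(k) for k in catalog]
        )
        overlaps = any(members & set(k) for k in sets)
    return CoverageRecord(
        members=members, best_term=best_term, coverage=cov, overlaps_catalog=overlaps
    )


def _bin_label(cov: float) -> str:
    """Assign a coverage to its bin: exact zero, else (r - 0.1, r]."""
    if cov == 0.0:
        return "0"
    return f"{_bin_upper(cov):.1f}"


def _bin_upper(cov: float) -> float:
    """Smallest r in {0.1, ..., 1.0} with cov <= r (half-open bins (r-0.1, r])."""
    # nudge guards against 0.7000000001-style float noise landing one bin up
    r = np.ceil(round(cov, 12) * 10 - 1e-9) / 10
    return float(min(max(r, 0.1), 1.0))


def coverage_histogram(records: Sequence[CoverageRecord]) -> pd.DataFrame:
    """Frequency distribution of coverages, split by catalog overlap.

    Rows are the exact-zero bin plus (r - 0.1, r] for r = 0.1 ... 1.0;
    columns count clusters with catalog overlap ("overlapping"), without
    ("non_overlapping") and in total.  Every record lands in exactly one bin.
    """
    labels = ["0"] + [f"{r / 10:.1f}" for r in range(1, 11)]
    counts = {lab: {"overlapping": 0, "non_overlapping": 0, "total": 0} for lab in labels}
    for rec in records:
        lab = _bin_label(rec.coverage)
        counts[lab]["total"] += 1
        if rec.overlaps_catalog is True:
            counts[lab]["overlapping"] += 1
        elif rec.overlaps_catalog is False:
            counts[lab]["non_overlapping"] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index.name = "bin"
    return df


def significance_coverage_correlation(
    significances: Sequence[float],
    coverages: Sequence[float],
) -> tuple[float, float]:
    """Pearson r between significance and coverage, with a two-sided t-test.

    The test statistic is t = r sqrt((n - 2) / (1 - r^2)) on n - 2 degrees
    of freedom under the null of zero population correlation.  A negative r
    means lower significance values (more significant clusters) go with
    higher coverage.  Raises on fewer than 3 pairs or a constant series.
    """
    x = np.asarray(significances, dtype=float)
    y = np.asarray(coverages, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("significances and coverages must be equal-length 1-D series")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant series")
    res = stats.pearsonr(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
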