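"""Z-score over-representation analysis across a pathway collection.

For a measurement table, a boolean criterion (e.g. ``[P.Value] < 0.05``)
and a collection of pathways, each pathway receives a standardised score

    z = (r - n R / N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) )

where N is the number of distinct measured genes in the whole dataset, R
how many of them meet the criterion, n how many are linked to the pathway,
and r how many of those meet the criterion.  Under the null hypothesis
that the pathway's genes are an exchangeable draw of n genes from the N
measured ones, r is hypergeometric with mean nR/N and the variance above
(finite-population correction included), so z > 0 means the pathway holds
more criterion-meeting genes than expected from the dataset-wide rate and
z < 0 fewer.  z is undefined (reported NaN) when the variance is zero.

Gene identity for counting: rows are unified by mapping to a single
unification system (by default the collection's dominant xref system), so
duplicate probes for one gene count once; rows that cannot be mapped into
that system at all are excluded from N (they can never hit a pathway) and
their count is reported.  No multiple-testing correction is applied: the
ranked raw Z scores are the result.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .dataset import (
    CriterionAST,
    MeasurementTable,
    criterion_columns,
    criterion_met,
    parse_criterion,
)
from .idmapper import MappingStore, map_identifier
from .model import PathwayDoc

__all__ = [
    "CriterionCounts",
    "PathwayScore",
    "RankedResult",
    "StatisticsError",
    "count_criterion",
    "zscore",
    "rank_pathways",
    "write_results_tsv",
]


class StatisticsError(Exception):
    pass


@dataclass(frozen=True)
class CriterionCounts:
    """(N, R, n, r) for one pathway against one dataset and criterion."""

    N: int  # distinct measured, mappable genes dataset-wide
    R: int  # of N, meeting the criterion
    n: int  # of N, linked to the pathway
    r: int  # of n, meeting the criterion

    def __post_init__(self):
        ok = 0 <= self.r <= self.n <= self.N and self.r <= self.R <= self.N
        if not ok:
            raise StatisticsError(
                f"invalid counts N={self.N} R={self.R} n={self.n} r={self.r}: "
                "need 0 <= r <= n <= N and r <= R <= N"
            )


@dataclass
class PathwayScore:
    name: str
    source: str  # file path or collection id
    counts: CriterionCounts
    z: float  # NaN when undefined (zero variance)

    @property
    def z_defined(self) -> bool:
        return not math.isnan(self.z)


@dataclass
class RankedResult:
    """Scores in rank order plus the settings they were computed under."""

    scores: list[PathwayScore]
    criterion_text: str
    dataset_source: str
    N: int
    R: int
    excluded_unmappable_rows: int = 0


# ---------------------------------------------------------------------------
# Counting

def _dominant_system(collection: Sequence[PathwayDoc]) -> Optional[str]:
    codes = Counter(
        node.xref.system_code
        for doc in collection
        for node in doc.data_nodes()
        if node.xref is not None
    )
    if not codes:
        return None
    # most common; ties broken alphabetically for determinism
    best = max(codes.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def _unify_rows(
    table: MeasurementTable,
    store: MappingStore,
    unify_code: str,
) -> tuple[dict[int, tuple[str, frozenset[str]]], int]:
    """Map each row to its images in the unification system.

    A multi-mapped row is keyed by the lexicographically smallest of its
    images so it counts once; the full image set is kept for pathway
    membership.  Returns (row index -> (key, images), #unmappable rows).
    """
    mapped: dict[int, tuple[str, frozenset[str]]] = {}
    unmappable = 0
    for i, (ident, code) in enumerate(zip(table.identifiers, table.system_codes)):
        if not ident:
            unmappable += 1
            continue
        try:
            images = map_identifier(store, ident, code, unify_code)
        except Exception:
            images = set()
        if not images:
            unmappable += 1
            continue
        mapped[i] = (min(images), frozenset(images))
    return mapped, unmappable


def _gene_table(
    table: MeasurementTable,
    store: MappingStore,
    unify_code: str,
    ast: CriterionAST,
) -> tuple[dict[str, bool], dict[str, set[str]], int]:
    """Collapse rows into unified genes: key -> criterion hit (any row), and
    key -> union of images in the unification system."""
    mapped, unmappable = _unify_rows(table, store, unify_code)
    gene_hit: dict[str, bool] = {}
    gene_images: dict[str, set[str]] = {}
    for i, (key, images) in mapped.items():
        gene_hit[key] = gene_hit.get(key, False) or criterion_met(ast, table.rows[i])
        gene_images.setdefault(key, set()).update(images)
    return gene_hit, gene_images, unmappable


def _pathway_images(doc: PathwayDoc, store: MappingStore, unify_code: str) -> set[str]:
    """Union of all node xref images in the unification system."""
    images: set[str] = set()
    for node in doc.data_nodes():
        if node.xref is None:
            continue
        try:
            images |= map_identifier(store, node.xref.identifier, node.xref.system_code, unify_code)
        except Exception:
            pass
    return images


def count_criterion(
    doc: PathwayDoc,
    table: MeasurementTable,
    store: MappingStore,
    criterion: Union[str, CriterionAST],
    unify_code: Optional[str] = None,
) -> CriterionCounts:
    """Compute (N, R, n, r) for one pathway.

    Counts run over distinct unified gene identities.  A gene meets the
    criterion when any of its rows does; a row with missing cells in the
    criterion counts toward N but not R (measured, not changed).
    """
    ast = parse_criterion(criterion) if isinstance(criterion, str) else criterion
    missing_cols = criterion_columns(ast) - set(table.column_names)
    if missing_cols:
        raise StatisticsError(
            f"criterion references absent columns {sorted(missing_cols)}; "
            f"table has {table.column_names}"
        )
    if unify_code is None:
        unify_code = _dominant_system([doc]) or (
            table.system_codes[0] if table.system_codes else "L"
        )

    gene_hit, gene_images, _ = _gene_table(table, store, unify_code, ast)
    pathway_images = _pathway_images(doc, store, unify_code)
    N = len(gene_hit)
    R = sum(gene_hit.values())
    in_pathway = [k for k in gene_hit if gene_images[k] & pathway_images]
    n = len(in_pathway)
    r = sum(gene_hit[k] for k in in_pathway)
    return CriterionCounts(N=N, R=R, n=n, r=r)


# ---------------------------------------------------------------------------
# The statistic

def zscore(counts: CriterionCounts) -> float:
    """Standardised over-representation score; NaN when variance is zero.

    Mean and variance are those of the hypergeometric distribution of r
    when n genes are drawn without replacement from N of which R are hits.
    """
    N, R, n, r = counts.N, counts.R, counts.n, counts.r
    if N <= 1 or n == 0 or R == 0 or R == N or n == N:
        return math.nan
    p = R / N
    variance = n * p * (1 - p) * (1 - (n - 1) / (N - 1))
    if variance <= 0:
        return math.nan
    return (r - n * p) / math.sqrt(variance)


# ---------------------------------------------------------------------------
# Ranking a collection

def rank_pathways(
    collection: Sequence[tuple[PathwayDoc, str]] | Sequence[PathwayDoc],
    table: MeasurementTable,
    store: MappingStore,
    criterion: Union[str, CriterionAST],
    unify_code: Optional[str] = None,
) -> RankedResult:
    """Score every pathway in a collection and rank by descending z.

    ``collection`` is a sequence of PathwayDoc or (PathwayDoc, source) pairs.
    Undefined-z pathways sort last; ties break by pathway name ascending.
    """
    if not collection:
        raise StatisticsError("pathway collection is empty")
    docs: list[tuple[PathwayDoc, str]] = [
        item if isinstance(item, tuple) else (item, "") for item in collection
    ]
    ast = parse_criterion(criterion) if isinstance(criterion, str) else criterion
    criterion_text = criterion if isinstance(criterion, str) else "<ast>"

    if unify_code is None:
        unify_code = _dominant_system([d for d, _ in docs]) or (
            table.system_codes[0] if table.system_codes else "L"
        )

    # N/R are dataset-wide, identical across pathways: compute once
    gene_hit, gene_images, unmappable = _gene_table(table, store, unify_code, ast)
    N, R = len(gene_hit), sum(gene_hit.values())

    scores = []
    for doc, source in docs:
        pathway_images = _pathway_images(doc, store, unify_code)
        in_pathway = [k for k in gene_hit if gene_images[k] & pathway_images]
        counts = CriterionCounts(
            N=N, R=R, n=len(in_pathway), r=sum(gene_hit[k] for k in in_pathway)
        )
        scores.append(PathwayScore(doc.name, source, counts, zscore(counts)))

    scores.sort(
        key=lambda s: (
            1 if not s.z_defined else 0,   # undefined last
            -(s.z if s.z_defined else 0.0),
            s.name,
        )
    )
    return RankedResult(
        scores=scores,
        criterion_text=criterion_text,
        dataset_source=table.source,
        N=N,
        R=R,
        excluded_unmappable_rows=unmappable,
    )


def write_results_tsv(result: RankedResult, destination) -> None:
    """Stable tabular export: pathway, file, n, r, N, R, z (NaN for undefined)."""
    lines = ["pathway\tfile\tn\tr\tN\tR\tz"]
    for s in result.scores:
        z_text = "NaN" if not s.z_defined else f"{s.z:.6g}"
        c = s.counts
        lines.append(f"{s.name}\t{s.source}\t{c.n}\t{c.r}\t{c.N}\t{c.R}\t{z_text}")
    data = ("\n".join(lines) + "\n").encode("utf-8")
    if hasattr(destination, "write"):
        destination.write(data)
    else:
        with open(destination, "wb") as fh:
            fh.write(data)
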