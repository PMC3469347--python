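"""Whole-gene expression quantification and cross-scaffold comparison.

Two routes produce a per-gene count table: mapping reads directly to the
reference gene set, or mapping to a de novo assembly and summing the
counts of the contigs assigned to each gene.  Tables are compared with
Spearman rank correlation on the shared genes, and in log2 space via MA
coordinates and residuals about the line of unity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

from scipy import stats

from .io_formats import CountsTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression: unique-read count C, length L and RPKM.

    ``length_used`` is the full gene length when reads were mapped
    directly, but only the covered portion of the gene when quantifying
    via a fragmented assembly, so that RPKM reflects the sequence actually
    available for mapping.
    """

    gene_id: str
    count: int
    length_used: int
    rpkm: float


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement between two per-gene quantifications.

    ``spearman_rho`` is computed over all shared genes (zeros included via
    ranks); MA points and unity residuals only over shared genes positive
    in both tables, since logs of zero are undefined.  Residuals are
    r = log2(x) − log2(y), zero when the two methods agree exactly.
    """

    n_shared: int
    spearman_rho: float
    mva_points: dict[str, tuple[float, float]]  # gene -> (A, M)
    residuals: dict[str, float]


def aggregate_via_assembly(
    contig_counts: CountsTable, assignments: Mapping[str, str]
) -> CountsTable:
    """Sum contig counts per assigned gene; unassigned contigs are dropped.

    The library size ``total_mapped`` is carried through unchanged: reads
    on unassigned contigs were still mapped.
    """
    gene_counts: dict[str, int] = {}
    n_dropped = 0
    dropped_reads = 0
    for contig, count in contig_counts.counts.items():
        gene = assignments.get(contig)
        if gene is None:
            n_dropped += 1
            dropped_reads += count
            continue
        gene_counts[gene] = gene_counts.get(gene, 0) + count
    if n_dropped:
        logger.warning(
            "%d contigs (%d reads) had no gene assignment and were dropped",
            n_dropped, dropped_reads,
        )
    return CountsTable(counts=gene_counts, total_mapped=contig_counts.total_mapped)


def rpkm(count: int, length: int, total_mapped: int) -> float:
    """Reads per kilobase of gene model per million mapped reads."""
    return 1e9 * count / (total_mapped * length)


def rpkm_table(
    gene_counts: CountsTable, lengths: Mapping[str, int]
) -> list[ExpressionRecord]:
    """RPKM for every counted gene; a counted gene must have a length."""
    records = []
    for gene, count in gene_counts.counts.items():
        if gene not in lengths:
            raise ValueError(f"no length for gene {gene!r}")
        length = lengths[gene]
        records.append(
            ExpressionRecord(
                gene_id=gene,
                count=count,
                length_used=length,
                rpkm=rpkm(count, length, gene_counts.total_mapped),
            )
        )
    return records


def _values(table: list[ExpressionRecord], value: str) -> dict[str, float]:
    if value not in ("count", "rpkm"):
        raise ValueError(f"value must be 'count' or 'rpkm', got {value!r}")
    return {r.gene_id: (r.count if value == "count" else r.rpkm) for r in table}


def compare(
    table_x: list[ExpressionRecord],
    table_y: list[ExpressionRecord],
    value: str = "count",
) -> ComparisonResult:
    """Compare two quantifications of the same genes.

    Spearman's rho uses average ranks for ties over the genes present in
    both tables; MA points (A = mean of log2 values, M = log2 x − log2 y)
    and residuals about the line of unity are restricted to genes positive
    in both tables.
    """
    x_vals = _values(table_x, value)
    y_vals = _values(table_y, value)
    shared = sorted(set(x_vals) & set(y_vals))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")

    xs = [x_vals[g] for g in shared]
    ys = [y_vals[g] for g in shared]
    rho = float(stats.spearmanr(xs, ys).statistic)

    mva: dict[str, tuple[float, float]] = {}
    residuals: dict[str, float] = {}
    for gene in shared:
        x, y = x_vals[gene], y_vals[gene]
        if x > 0 and y > 0:
            lx, ly = math.log2(x), math.log2(y)
            mva[gene] = ((lx + ly) / 2.0, lx - ly)
            residuals[gene] = lx - ly
    return ComparisonResult(
        n_shared=len(shared),
        spearman_rho=rho,
        mva_points=mva,
        residuals=residuals,
    )
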