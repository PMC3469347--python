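"""Assembly metrics and the contig reference ratio (CRR) family.

The CRR of a reference gene is the fraction of its length covered by
assembly contigs, computed as an interval union so that stacked contigs
over the same region are counted once.  Three variants are reported per
gene: ``sum_crr`` (union over every contig), ``longest_crr`` (best single
contig) and ``all_crr`` (the per-contig ratios).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .assignment import ThresholdConfig, apply_thresholds, best_hit
from .io_formats import AlignmentRecord, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssemblyMetrics:
    """Length-based summary statistics of a contig set."""

    n_contigs: int
    total_len: int
    mean_len: float
    median_len: float
    max_len: int
    n50: int


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, pairwise-disjoint half-open intervals within [0, ref_length)."""

    intervals: tuple[tuple[int, int], ...]

    @property
    def covered_length(self) -> int:
        return sum(hi - lo for lo, hi in self.intervals)


@dataclass(frozen=True)
class CoverageProfile:
    """Coverage of one reference gene by contig alignments."""

    gene_id: str
    ref_length: int
    covered_length: int
    sum_crr: float
    longest_crr: float
    all_crr: tuple[float, ...]
    n_contigs_hitting: int


@dataclass(frozen=True)
class TranscriptomeSummary:
    """Transcriptome-wide roll-up of per-gene coverage profiles.

    Mean/median CRR are over represented genes only (genes with at least
    one passing hit); genes never hit contribute to ``n_ref_genes`` alone.
    """

    n_ref_genes: int
    n_genes_hit: int
    total_covered_len: int
    mean_crr: float
    median_crr: float
    n_genes_crr_ge_threshold: int
    threshold: float


def basic_metrics(contigs: list[SequenceRecord]) -> AssemblyMetrics:
    """Standard assembly metrics; N50 is the length-weighted median contig size."""
    if not contigs:
        raise ValueError("empty assembly")
    lengths = sorted((c.length for c in contigs), reverse=True)
    total = sum(lengths)
    running = 0
    n50 = lengths[-1]
    for length in lengths:
        running += length
        if running >= total / 2:
            n50 = length
            break
    return AssemblyMetrics(
        n_contigs=len(lengths),
        total_len=total,
        mean_len=total / len(lengths),
        median_len=statistics.median(lengths),
        max_len=lengths[0],
        n50=n50,
    )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals; touching intervals are merged."""
    ordered = sorted((lo, hi) for lo, hi in intervals if hi > lo)
    merged: list[tuple[int, int]] = []
    for lo, hi in ordered:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return tuple(merged)


def union_coverage(
    alignments: Iterable[AlignmentRecord], ref_length: int
) -> IntervalSet:
    """Union of subject intervals of alignments to one reference gene.

    Intervals extending past ``ref_length`` (alignment end-effects) are
    clipped with a warning, never an error.
    """
    clipped: list[tuple[int, int]] = []
    for aln in alignments:
        lo, hi = aln.subject_interval
        if hi > ref_length or lo < 0:
            logger.warning(
                "clipping alignment %s->%s interval [%d,%d) to reference length %d",
                aln.qseqid, aln.sseqid, lo, hi, ref_length,
            )
            lo, hi = max(lo, 0), min(hi, ref_length)
        if hi > lo:
            clipped.append((lo, hi))
    return IntervalSet(intervals=merge_intervals(clipped))


def crr_profiles(
    alignments: Iterable[AlignmentRecord],
    ref_lengths: Mapping[str, int],
    cfg: ThresholdConfig,
    coverage_mode: str = "all",
) -> dict[str, CoverageProfile]:
    """Per-gene coverage profiles from a raw alignment table.

    Thresholds are applied internally via ``cfg``.  With
    ``coverage_mode="all"`` (default) every passing alignment contributes
    coverage to its subject gene, so one contig may cover several genes;
    with ``"best-hit"`` only alignments to each contig's best-hit gene
    count.
    """
    if coverage_mode not in ("all", "best-hit"):
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    passing = apply_thresholds(alignments, cfg)
    if coverage_mode == "best-hit":
        chosen = best_hit(passing, method=cfg.name)
        passing = [
            a for a in passing if chosen[a.qseqid].subject_id == a.sseqid
        ]

    by_gene: dict[str, list[AlignmentRecord]] = {}
    for aln in passing:
        by_gene.setdefault(aln.sseqid, []).append(aln)

    profiles: dict[str, CoverageProfile] = {}
    for gene, rows in by_gene.items():
        if gene not in ref_lengths:
            raise ValueError(f"no reference length for gene {gene!r}")
        ref_len = ref_lengths[gene]
        union = union_coverage(rows, ref_len)
        # Per-contig unioned span on this gene.
        by_contig: dict[str, list[AlignmentRecord]] = {}
        for aln in rows:
            by_contig.setdefault(aln.qseqid, []).append(aln)
        per_contig = tuple(
            union_coverage(contig_rows, ref_len).covered_length / ref_len
            for contig_rows in by_contig.values()
        )
        profiles[gene] = CoverageProfile(
            gene_id=gene,
            ref_length=ref_len,
            covered_length=union.covered_length,
            sum_crr=union.covered_length / ref_len,
            longest_crr=max(per_contig) if per_contig else 0.0,
            all_crr=per_contig,
            n_contigs_hitting=len(by_contig),
        )
    return profiles


def summarize(
    profiles: Mapping[str, CoverageProfile],
    n_ref_genes: int,
    threshold: float = 0.9,
) -> TranscriptomeSummary:
    """Roll per-gene profiles up to transcriptome level."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    crrs = [p.sum_crr for p in profiles.values()]
    return TranscriptomeSummary(
        n_ref_genes=n_ref_genes,
        n_genes_hit=len(profiles),
        total_covered_len=sum(p.covered_length for p in profiles.values()),
        mean_crr=statistics.fmean(crrs) if crrs else 0.0,
        median_crr=statistics.median(crrs) if crrs else 0.0,
        n_genes_crr_ge_threshold=sum(1 for c in crrs if c >= threshold),
        threshold=threshold,
    )
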