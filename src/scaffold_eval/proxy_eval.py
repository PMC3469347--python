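"""Error and information loss from annotating via a divergent reference.

When no gene set exists for the target species, contigs are grouped by
translated search against a genomic reference species (GRS) and mapped
back to target genes through RBH orthology.  Where a direct target gene
set is also available (the benchmarking setting), each contig's proxy
route can be triangulated against its direct assignment: the proxy call
is correct when the RBH partner of its GRS gene equals the direct gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .assignment import OrthologPair, ThresholdConfig, rbh_map
from .coverage import crr_profiles, summarize
from .io_formats import AlignmentRecord, CountsTable, SequenceRecord

#: Per-contig triangulation statuses.
STATUSES = ("correct", "incorrect", "no_direct", "no_rbh", "unassigned")


@dataclass(frozen=True)
class TriangulationResult:
    """Per-contig correctness of proxy assignment, and the error rate.

    ``error_pct`` is over triangulable contigs only (those with both a
    direct and a proxy assignment whose GRS gene has an RBH partner); the
    full status counts are kept so alternative denominators can be
    recomputed.
    """

    status: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATUSES}
        for s in self.status.values():
            out[s] += 1
        return out

    @property
    def n_evaluable(self) -> int:
        c = self.counts
        return c["correct"] + c["incorrect"]

    @property
    def error_pct(self) -> float:
        n = self.n_evaluable
        if n == 0:
            raise ValueError("no triangulable contigs; error_pct undefined")
        return 100.0 * self.counts["incorrect"] / n


@dataclass(frozen=True)
class GrsSummary:
    """How much of the target transcriptome a GRS proxy still recovers."""

    grs_name: str
    n_genes_in_set: int
    n_genes_with_ta_hit: int
    n_genes_crr_ge_threshold: int
    threshold: float
    pct_decrease_vs_baseline: float | None = None


def pct_decrease(baseline: float, value: float) -> float:
    """Percent drop from a baseline count, 100 * (baseline - value) / baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (baseline - value) / baseline


def triangulate(
    direct: Mapping[str, str],
    proxy: Mapping[str, str],
    rbh: Iterable[OrthologPair] | Mapping[str, str],
) -> TriangulationResult:
    """Label every contig's proxy assignment against its direct one.

    ``direct`` maps contig -> target gene, ``proxy`` maps contig -> GRS
    gene, ``rbh`` pairs GRS genes (gene_a) with target genes (gene_b).
    Contigs appearing in neither mapping are not invented; the universe is
    the union of both mappings' contigs.
    """
    grs_to_target = rbh if isinstance(rbh, Mapping) else rbh_map(rbh)
    status: dict[str, str] = {}
    for contig in set(direct) | set(proxy):
        if contig not in proxy:
            status[contig] = "unassigned"
        elif contig not in direct:
            status[contig] = "no_direct"
        else:
            partner = grs_to_target.get(proxy[contig])
            if partner is None:
                status[contig] = "no_rbh"
            elif partner == direct[contig]:
                status[contig] = "correct"
            else:
                status[contig] = "incorrect"
    return TriangulationResult(status=status)


def grs_summary(
    proxy_alignments: Iterable[AlignmentRecord],
    grs_genes: list[SequenceRecord],
    cfg: ThresholdConfig,
    threshold: float = 0.9,
    baseline: int | None = None,
    grs_name: str = "GRS",
) -> GrsSummary:
    """Count GRS genes hit by contigs and those with CRR >= threshold.

    Coverage is computed in the units of the translated search (amino
    acids for protein references).
    """
    ref_lengths = {g.id: g.length for g in grs_genes}
    profiles = crr_profiles(proxy_alignments, ref_lengths, cfg)
    summary = summarize(profiles, n_ref_genes=len(grs_genes), threshold=threshold)
    return GrsSummary(
        grs_name=grs_name,
        n_genes_in_set=len(grs_genes),
        n_genes_with_ta_hit=summary.n_genes_hit,
        n_genes_crr_ge_threshold=summary.n_genes_crr_ge_threshold,
        threshold=threshold,
        pct_decrease_vs_baseline=(
            pct_decrease(baseline, summary.n_genes_crr_ge_threshold)
            if baseline is not None
            else None
        ),
    )


def proxy_expression(
    contig_counts: CountsTable,
    proxy: Mapping[str, str],
    rbh: Iterable[OrthologPair] | Mapping[str, str],
) -> CountsTable:
    """Per-target-gene counts via the proxy route.

    A contig's reads land on the target gene that is the RBH partner of
    its assigned GRS gene; contigs whose GRS gene has no RBH partner
    contribute nothing.
    """
    grs_to_target = rbh if isinstance(rbh, Mapping) else rbh_map(rbh)
    contig_to_target = {
        contig: grs_to_target[gene]
        for contig, gene in proxy.items()
        if gene in grs_to_target
    }
    gene_counts: dict[str, int] = {}
    for contig, count in contig_counts.counts.items():
        target = contig_to_target.get(contig)
        if target is None:
            continue
        gene_counts[target] = gene_counts.get(target, 0) + count
    return CountsTable(counts=gene_counts, total_mapped=contig_counts.total_mapped)
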