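"""Threshold filtering, unique best-hit assignment and RBH orthology.

Assignment of a de novo contig to a reference gene uses the single best
surviving hit after threshold filtering; orthology between two gene sets
uses the reciprocal-best-hit (RBH) criterion.  Best hits are ranked by
bitscore first (database-size independent), then e-value, alignment
length, and finally subject id for full determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import AlignmentRecord


@dataclass(frozen=True)
class ThresholdConfig:
    """Hit-filtering criteria; any criterion left ``None`` is not applied.

    ``min_pident`` is strict (>), ``min_len`` inclusive (>=), ``max_evalue``
    inclusive (<=), ``min_bitscore`` inclusive (>=).  ``min_len`` is in the
    search's own units (nt for nucleotide searches, aa for translated and
    protein searches).
    """

    name: str = "custom"
    min_pident: float | None = None
    min_len: int | None = None
    max_evalue: float | None = None
    min_bitscore: float | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (self.min_pident, self.min_len, self.max_evalue, self.min_bitscore)
        ):
            raise ValueError("at least one criterion must be set")

    def passes(self, aln: AlignmentRecord) -> bool:
        if self.min_pident is not None and not aln.pident > self.min_pident:
            return False
        if self.min_len is not None and not aln.aln_len >= self.min_len:
            return False
        if self.max_evalue is not None and not aln.evalue <= self.max_evalue:
            return False
        if self.min_bitscore is not None and not aln.bitscore >= self.min_bitscore:
            return False
        return True


#: Direct nucleotide assignment of contigs to the target gene set.
NT_DIRECT = ThresholdConfig(name="nt_direct", min_pident=95.0, min_len=100, max_evalue=1e-6)
#: Translated assignment of contigs to a divergent protein gene set.
PX_DEFAULT = ThresholdConfig(name="px_default", min_bitscore=50.0, max_evalue=1e-6, min_len=33)
#: Stringent variant used to trade annotation breadth for accuracy.
PX_STRINGENT = ThresholdConfig(name="px_stringent", min_bitscore=100.0, max_evalue=1e-25, min_len=33)
#: Protein-protein reciprocal-best-hit orthology thresholds.
PP_RBH = ThresholdConfig(name="pp_rbh", min_pident=60.0, min_len=33, max_evalue=1e-5)

PROFILES: dict[str, ThresholdConfig] = {
    cfg.name: cfg for cfg in (NT_DIRECT, PX_DEFAULT, PX_STRINGENT, PP_RBH)
}


@dataclass(frozen=True)
class Assignment:
    """A query uniquely assigned to its best-scoring subject."""

    query_id: str
    subject_id: str
    method: str
    bitscore: float


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit pairing between gene sets A and B."""

    gene_a: str
    gene_b: str


def apply_thresholds(
    alignments: Iterable[AlignmentRecord], cfg: ThresholdConfig
) -> list[AlignmentRecord]:
    """Drop rows failing any set criterion; input order is preserved."""
    return [aln for aln in alignments if cfg.passes(aln)]


def _hit_rank(aln: AlignmentRecord) -> tuple:
    # Maximise bitscore, then minimise e-value, maximise length, smallest id.
    return (-aln.bitscore, aln.evalue, -aln.aln_len, aln.sseqid)


def best_hit(
    alignments: Iterable[AlignmentRecord], method: str = "custom"
) -> dict[str, Assignment]:
    """One assignment per query: the subject with the maximal bitscore.

    Ties break on lower e-value, then greater alignment length, then
    lexicographically smaller subject id.  Input is expected to be
    threshold-filtered already; a query with no surviving rows simply gets
    no assignment.
    """
    best: dict[str, AlignmentRecord] = {}
    for aln in alignments:
        cur = best.get(aln.qseqid)
        if cur is None or _hit_rank(aln) < _hit_rank(cur):
            best[aln.qseqid] = aln
    return {
        q: Assignment(query_id=q, subject_id=a.sseqid, method=method, bitscore=a.bitscore)
        for q, a in best.items()
    }


def reciprocal_best_hits(
    aln_ab: Iterable[AlignmentRecord],
    aln_ba: Iterable[AlignmentRecord],
    cfg: ThresholdConfig = PP_RBH,
) -> list[OrthologPair]:
    """Mutual best hits between set A (queries of ``aln_ab``) and set B.

    Both tables are filtered with ``cfg`` before the per-direction best
    hits are computed; a pair (a, b) is emitted iff a's best hit is b and
    b's best hit is a.  Output is sorted by ``gene_a``.
    """
    fwd = best_hit(apply_thresholds(aln_ab, cfg), method=cfg.name)
    rev = best_hit(apply_thresholds(aln_ba, cfg), method=cfg.name)
    pairs = [
        OrthologPair(gene_a=a, gene_b=hit.subject_id)
        for a, hit in fwd.items()
        if rev.get(hit.subject_id) is not None
        and rev[hit.subject_id].subject_id == a
    ]
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def rbh_map(pairs: Iterable[OrthologPair]) -> dict[str, str]:
    """Mapping gene_a -> gene_b from a list of RBH pairs."""
    return {p.gene_a: p.gene_b for p in pairs}


def assignment_map(assignments: Mapping[str, Assignment]) -> dict[str, str]:
    """Plain query -> subject mapping from a best-hit result."""
    return {q: a.subject_id for q, a in assignments.items()}
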