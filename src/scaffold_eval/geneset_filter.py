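"""Redundancy filtering of a predicted gene set from self-alignment results.

Alternative splice variants and very recent duplicates show up as
near-identical pairs in an all-vs-all self search.  For every pair passing
the policy the shorter member is removed (exact duplicate ties broken on
id), so the surviving set carries one representative per redundancy group.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AlignmentRecord, SequenceRecord


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds a self-hit must pass to mark a pair as redundant.

    ``min_pident`` is strict (>); ``min_len`` and ``max_evalue`` are
    inclusive.  ``min_len`` is in the alignment's own units (nt for
    nucleotide searches, aa for protein searches).
    """

    min_pident: float
    min_len: int
    max_evalue: float

    def __post_init__(self) -> None:
        if not 0 < self.min_pident <= 100:
            raise ValueError("min_pident must be in (0, 100]")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")

    def passes(self, aln: AlignmentRecord) -> bool:
        return (
            aln.pident > self.min_pident
            and aln.aln_len >= self.min_len
            and aln.evalue <= self.max_evalue
        )


#: Nucleotide gene sets: identity > 95% over >= 100 nt, e-value <= 1e-6.
NT_POLICY = FilterPolicy(min_pident=95.0, min_len=100, max_evalue=1e-6)
#: Protein gene sets: identity > 90% over >= 33 aa, e-value <= 1e-6.
AA_POLICY = FilterPolicy(min_pident=90.0, min_len=33, max_evalue=1e-6)


def filter_redundant(
    records: list[SequenceRecord],
    self_alignments: list[AlignmentRecord],
    policy: FilterPolicy,
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Remove the shorter member of every redundant pair.

    Passing pairs are processed in a deterministic order — sorted by
    (e-value ascending, min id, max id) — skipping pairs one of whose
    members is already gone, so the result is independent of input row
    order and idempotent.  Equal-length pairs drop the lexicographically
    greater id.  Returns ``(kept, removed)`` with ``removed`` listing
    ``(removed_id, partner_id)``.
    """
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate record ids in input")

    # Best (lowest e-value) passing hit per unordered pair.
    pair_evalue: dict[tuple[str, str], float] = {}
    for aln in self_alignments:
        if aln.qseqid == aln.sseqid:
            continue  # self-hit
        for name in (aln.qseqid, aln.sseqid):
            if name not in by_id:
                raise ValueError(f"alignment references unknown id {name!r}")
        if not policy.passes(aln):
            continue
        key = (min(aln.qseqid, aln.sseqid), max(aln.qseqid, aln.sseqid))
        if key not in pair_evalue or aln.evalue < pair_evalue[key]:
            pair_evalue[key] = aln.evalue

    ordered = sorted(pair_evalue.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1]))

    removed: list[tuple[str, str]] = []
    gone: set[str] = set()
    for (id_a, id_b), _ev in ordered:
        if id_a in gone or id_b in gone:
            continue
        len_a, len_b = by_id[id_a].length, by_id[id_b].length
        if len_a < len_b:
            loser, partner = id_a, id_b
        elif len_b < len_a:
            loser, partner = id_b, id_a
        else:  # exact-length tie: drop the lexicographically greater id
            loser, partner = max(id_a, id_b), min(id_a, id_b)
        gone.add(loser)
        removed.append((loser, partner))

    kept = [r for r in records if r.id not in gone]
    return kept, removed
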