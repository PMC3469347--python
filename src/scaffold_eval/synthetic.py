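"""Truth-labelled synthetic worlds for offline evaluation of the pipeline.

The generator emulates the benchmarking setting the toolkit targets: a
target-species gene set (nucleotide coding sequences with their protein
translations), a divergent reference proteome related to it by a known
ortholog map, a fragmented de novo assembly whose contigs carry partial
gene coverage and non-coding UTR overhangs, alignment tables for every
search the pipeline consumes, and unique-read count tables drawn from
log-normal expression levels.  Every object carries its ground truth, so
assignment error, coverage and expression recovery can be scored exactly.

Randomness is split into fixed named substreams keyed on the master seed.
Divergence-dependent draws live in their own stream and use per-site
uniform thresholds, so regenerating the same seed at a larger divergence
degrades every gene monotonically — a divergence sweep at fixed seed is a
paired comparison, not six independent simulations.

Alignment e-values and bitscores come from a simple surrogate that is
monotone in identity x length (amino-acid rows: 3*identity - 1 bits per
column; nucleotide rows: 2*(2*identity - 1) bits per column; e-value
1e6 * 2^-bitscore).  Downstream logic only consumes thresholds and
orderings, so a scoring-matrix model would add nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from Bio.Data import CodonTable

from .io_formats import (
    AlignmentRecord,
    CountsTable,
    SequenceRecord,
    write_alignments,
    write_annotations,
    write_counts,
    write_fasta,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

#: Divergence levels (million years) spanning the range a researcher is
#: likely to face when picking a reference species, from a very close
#: relative to a ~160 My distant one.
DIVERGENCE_LEVELS_MY = (5.0, 13.0, 25.0, 40.0, 83.0, 160.0)

#: Shortest contig piece cut from a gene (nt); 35 codons, so translated
#: hits can clear a 33-aa length threshold.
MIN_PIECE_NT = 105

# Named substreams of the master seed.
_STAGES = {"genes": 0, "divergence": 1, "contigs": 2, "expression": 3, "noise": 4, "annotation": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGES[stage], seed])


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    return {aa: sorted(codons) for aa, codons in out.items()}


_CODONS = _codon_map()


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of a synthetic world.

    Defaults describe a small but realistic bulk RNA-Seq benchmarking
    setting: ~1.3 kb log-normal coding genes, log-normal expression
    spanning ~3 orders of magnitude, a Poisson number of contig fragments
    per gene covering a Beta-distributed fraction of it, 10% UTR overhang
    on contigs, a 5% spurious-alignment rate and a 5% recent-duplicate
    rate.  ``subst_rate`` (amino-acid substitutions per site per million
    years) is set so that identity falls to roughly 45% at the far end of
    the 5-160 My divergence range.
    """

    n_genes: int = 50
    gene_len_meanlog: float = 7.2   # median ~1340 nt
    gene_len_sdlog: float = 0.45
    expr_meanlog: float = 4.0
    expr_sdlog: float = 1.2
    total_reads: int = 100_000
    divergence_my: float = 0.0
    subst_rate: float = 0.005
    rate_heterogeneity: float = 2.0  # gamma shape across genes, mean 1
    frags_per_gene: float = 3.0      # Poisson mean
    coverage_frac: tuple[float, float] = (8.0, 2.0)  # Beta(a, b); b=0 -> exactly 1
    utr_frac: float = 0.10
    spurious_hit_rate: float = 0.05
    dup_family_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("utr_frac", "spurious_hit_rate", "dup_family_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.divergence_my < 0 or self.subst_rate < 0:
            raise ValueError("divergence_my and subst_rate must be non-negative")
        if self.rate_heterogeneity <= 0:
            raise ValueError("rate_heterogeneity must be positive")

    @classmethod
    def noise_free(cls, **overrides) -> "SimParams":
        """A zero-divergence, zero-noise world: contigs tile genes fully,
        no UTR overhangs, no spurious hits, no recent duplicates."""
        base = dict(
            divergence_my=0.0,
            spurious_hit_rate=0.0,
            utr_frac=0.0,
            dup_family_rate=0.0,
            coverage_frac=(1.0, 0.0),
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class Placement:
    """True origin of one contig: source gene and half-open nt interval."""

    gene: str
    start: int
    end: int
    utr_left: int
    utr_right: int
    ident_noise: float  # per-contig jitter on translated-search identity
    reverse: bool       # emit subject coordinates reversed (minus strand)


@dataclass
class TruthSet:
    """A synthetic world plus its complete ground truth."""

    params: SimParams
    genes: list[SequenceRecord]            # target nt genes, incl. paralogs
    proteins: dict[str, SequenceRecord]    # target proteins by gene id
    grs_proteins: list[SequenceRecord]     # divergent reference proteome
    ortholog_map: dict[str, str]           # grs id -> target gene id
    gene_to_grs: dict[str, str]            # inverse (base genes only)
    identity: dict[str, float]             # realized aa identity per base gene
    paralog_map: dict[str, str]            # paralog id -> parent id
    contigs: list[SequenceRecord]
    placements: dict[str, Placement]
    expression: dict[str, float]           # true expression weight per gene
    gene_counts: CountsTable               # direct-mapping unique reads
    contig_counts: CountsTable

    @property
    def gene_lengths(self) -> dict[str, int]:
        return {g.id: g.length for g in self.genes}

    def covered_fraction(self, gene: str) -> float:
        """Realized fraction of a gene tiled by its contigs (truth)."""
        length = self.gene_lengths[gene]
        covered = sum(
            p.end - p.start for p in self.placements.values() if p.gene == gene
        )
        return covered / length


@dataclass
class AlignmentTables:
    """The four search results the pipeline consumes."""

    nt: list[AlignmentRecord]      # contig vs target genes (nucleotide)
    px: list[AlignmentRecord]      # contig vs GRS proteins (translated)
    pp_ab: list[AlignmentRecord]   # GRS proteins vs target proteins
    pp_ba: list[AlignmentRecord]   # target proteins vs GRS proteins


def _aa_bits(identity: float, aa_len: int) -> float:
    return max(0.0, aa_len * (3.0 * identity - 1.0))


def _nt_bits(identity: float, nt_len: int) -> float:
    return max(0.0, nt_len * 2.0 * (2.0 * identity - 1.0))


def _evalue(bits: float) -> float:
    return float(min(10.0, 1e6 * 2.0 ** (-bits)))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(NT_ALPHABET))[rng.integers(0, 4, size=n)])


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, size=n)])


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    )


def _mutate_protein(
    protein: str, p_sub: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Substitute each site with probability ``p_sub`` to a different aa.

    Draws one uniform and one replacement per site regardless of whether
    the site mutates, so the stream consumption is divergence-independent
    and identity is monotone in ``p_sub`` at fixed seed.
    """
    sites = np.array(list(protein))
    us = rng.random(len(sites))
    picks = rng.integers(0, 19, size=len(sites))
    n_changed = 0
    for i in range(len(sites)):
        if us[i] < p_sub:
            alternatives = AA_ALPHABET.replace(sites[i], "")
            sites[i] = alternatives[picks[i] % len(alternatives)]
            n_changed += 1
    return "".join(sites), 1.0 - n_changed / len(sites)


def simulate(params: SimParams) -> TruthSet:
    """Generate a complete truth-labelled world; deterministic given seed."""
    # --- target genes ------------------------------------------------
    rng_g = _rng(params.seed, "genes")
    n = params.n_genes
    lens_nt = np.maximum(
        102,
        (np.exp(rng_g.normal(params.gene_len_meanlog, params.gene_len_sdlog, n)) // 3 * 3).astype(int),
    )
    base_ids = [f"g{i:04d}" for i in range(n)]
    proteins: dict[str, SequenceRecord] = {}
    genes: list[SequenceRecord] = []
    for gid, L in zip(base_ids, lens_nt):
        prot = _random_protein(rng_g, int(L) // 3)
        proteins[gid] = SequenceRecord(id=gid, seq=prot, moltype="aa")
        genes.append(SequenceRecord(id=gid, seq=_back_translate(prot, rng_g), moltype="nt"))

    # recent duplicates: ~2% diverged copies without their own ortholog
    paralog_map: dict[str, str] = {}
    dup_us = rng_g.random(n)
    for i, gid in enumerate(base_ids):
        if dup_us[i] < params.dup_family_rate:
            pid = gid + "p"
            pprot, _ = _mutate_protein(proteins[gid].seq, 0.02, rng_g)
            proteins[pid] = SequenceRecord(id=pid, seq=pprot, moltype="aa")
            genes.append(SequenceRecord(id=pid, seq=_back_translate(pprot, rng_g), moltype="nt"))
            paralog_map[pid] = gid

    # --- divergent reference proteome --------------------------------
    rng_d = _rng(params.seed, "divergence")
    rates = rng_d.gamma(params.rate_heterogeneity, 1.0 / params.rate_heterogeneity, n)
    perm = rng_d.permutation(n)
    grs_proteins: list[SequenceRecord] = []
    ortholog_map: dict[str, str] = {}
    gene_to_grs: dict[str, str] = {}
    identity: dict[str, float] = {}
    for i, gid in enumerate(base_ids):
        lam = params.subst_rate * params.divergence_my * rates[i]
        p_sub = 1.0 - math.exp(-lam)
        mutated, ident = _mutate_protein(proteins[gid].seq, p_sub, rng_d)
        grs_id = f"GRS{perm[i]:04d}"
        grs_proteins.append(SequenceRecord(id=grs_id, seq=mutated, moltype="aa"))
        ortholog_map[grs_id] = gid
        gene_to_grs[gid] = grs_id
        identity[gid] = ident
    grs_proteins.sort(key=lambda r: r.id)

    # --- contigs ------------------------------------------------------
    rng_c = _rng(params.seed, "contigs")
    beta_a, beta_b = params.coverage_frac
    contigs: list[SequenceRecord] = []
    placements: dict[str, Placement] = {}
    for gene in genes:
        L = gene.length
        k = int(rng_c.poisson(params.frags_per_gene))
        cov = 1.0 if beta_b == 0 else float(rng_c.beta(beta_a, beta_b))
        if k == 0:
            continue  # gene absent from the assembly
        covered = int(round(cov * L))
        if covered < MIN_PIECE_NT:
            k_eff, piece_lens = 1, [max(covered, 30)]
        else:
            k_eff = max(1, min(k, covered // MIN_PIECE_NT))
            extra = rng_c.multinomial(
                covered - k_eff * MIN_PIECE_NT, rng_c.dirichlet(np.ones(k_eff))
            )
            piece_lens = [MIN_PIECE_NT + int(e) for e in extra]
        free = L - sum(piece_lens)
        gaps = rng_c.multinomial(free, np.ones(k_eff + 1) / (k_eff + 1))
        pos = 0
        for j, plen in enumerate(piece_lens):
            pos += int(gaps[j])
            start, end = pos, pos + plen
            pos = end
            utr_total = int(round(plen * params.utr_frac / (1.0 - params.utr_frac)))
            utr_left, utr_right = utr_total // 2, utr_total - utr_total // 2
            cid = f"{gene.id}_c{j}"
            seq = (
                _random_nt(rng_c, utr_left)
                + gene.seq[start:end]
                + _random_nt(rng_c, utr_right)
            )
            placements[cid] = Placement(
                gene=gene.id,
                start=start,
                end=end,
                utr_left=utr_left,
                utr_right=utr_right,
                ident_noise=float(rng_c.normal(0.0, 0.01)),
                reverse=bool(rng_c.random() < 0.3),
            )
            contigs.append(SequenceRecord(id=cid, seq=seq, moltype="nt"))

    # --- expression & read counts ------------------------------------
    rng_e = _rng(params.seed, "expression")
    all_ids = [g.id for g in genes]
    expr = np.exp(rng_e.normal(params.expr_meanlog, params.expr_sdlog, len(all_ids)))
    probs = expr / expr.sum()
    gene_reads = rng_e.multinomial(params.total_reads, probs)
    expression = {gid: float(e) for gid, e in zip(all_ids, expr)}
    gene_counts = CountsTable(
        counts={gid: int(c) for gid, c in zip(all_ids, gene_reads)},
        total_mapped=params.total_reads,
    )
    by_gene: dict[str, list[str]] = {}
    for cid, placement in placements.items():
        by_gene.setdefault(placement.gene, []).append(cid)
    contig_counts: dict[str, int] = {}
    for gene in genes:
        cids = by_gene.get(gene.id)
        if not cids:
            continue
        weights = [placements[c].end - placements[c].start for c in cids]
        uncovered = gene.length - sum(weights)
        probs_c = np.array(weights + [uncovered], dtype=float)
        probs_c /= probs_c.sum()
        draws = rng_e.multinomial(gene_counts.counts[gene.id], probs_c)
        for cid, d in zip(cids, draws[:-1]):
            contig_counts[cid] = int(d)

    return TruthSet(
        params=params,
        genes=genes,
        proteins=proteins,
        grs_proteins=grs_proteins,
        ortholog_map=ortholog_map,
        gene_to_grs=gene_to_grs,
        identity=identity,
        paralog_map=paralog_map,
        contigs=contigs,
        placements=placements,
        expression=expression,
        gene_counts=gene_counts,
        contig_counts=CountsTable(counts=contig_counts, total_mapped=params.total_reads),
    )


def _row(
    q: str, s: str, ident: float, length: int, qstart: int, qend: int,
    sstart: int, send: int, bits: float, units: str,
) -> AlignmentRecord:
    pident = round(100.0 * min(1.0, max(0.0, ident)), 2)
    return AlignmentRecord(
        qseqid=q, sseqid=s, pident=pident, aln_len=length,
        mismatch=int(round(length * (1.0 - ident))), gapopen=0,
        qstart=qstart, qend=qend, sstart=sstart, send=send,
        evalue=_evalue(bits), bitscore=round(bits, 1), subject_units=units,
    )


def emit_alignments(truth: TruthSet, params: SimParams | None = None) -> AlignmentTables:
    """Turn true placements and orthologies into the four alignment tables.

    True rows carry identity decreasing in realized divergence and scores
    monotone in identity x length; spurious rows with modest bitscores are
    injected per contig at ``spurious_hit_rate``.  At zero divergence a
    spurious row never outscores the true row of the same contig.
    """
    params = params or truth.params
    rng_n = _rng(params.seed, "noise")
    detection_floor = 25.0  # bits below which a search reports nothing

    prot_len = {pid: rec.length for pid, rec in truth.proteins.items()}
    grs_len = {g.id: g.length for g in truth.grs_proteins}
    grs_ids = [g.id for g in truth.grs_proteins]
    gene_ids = [g.id for g in truth.genes]
    gene_len = truth.gene_lengths

    nt_rows: list[AlignmentRecord] = []
    px_rows: list[AlignmentRecord] = []

    for contig in truth.contigs:
        placement = truth.placements[contig.id]
        gid = placement.gene
        piece = placement.end - placement.start
        qstart, qend = placement.utr_left + 1, placement.utr_left + piece

        # direct nucleotide hit to the source gene (same species: identity 1)
        sstart, send = placement.start + 1, placement.end
        if placement.reverse:
            sstart, send = send, sstart
        nt_rows.append(
            _row(contig.id, gid, 1.0, piece, qstart, qend, sstart, send,
                 _nt_bits(1.0, piece), "nt")
        )
        # cross-hit to a recent duplicate at ~98% identity
        partner = truth.paralog_map.get(gid) or next(
            (p for p, parent in truth.paralog_map.items() if parent == gid), None
        )
        if partner is not None:
            p_end = min(placement.end, gene_len[partner])
            if p_end - placement.start >= 50:
                nt_rows.append(
                    _row(contig.id, partner, 0.98, p_end - placement.start,
                         qstart, qstart + (p_end - placement.start) - 1,
                         placement.start + 1, p_end,
                         _nt_bits(0.98, p_end - placement.start), "nt")
                )

        # translated hit to the GRS ortholog of the source (or parent) gene
        source = truth.paralog_map.get(gid, gid)
        grs_id = truth.gene_to_grs.get(source)
        true_px_bits = None
        if grs_id is not None:
            ident = truth.identity[source] + placement.ident_noise
            if gid in truth.paralog_map:
                ident *= 0.98  # duplicate diverged a little further
            ident = min(1.0, max(0.0, ident))
            aa_lo = placement.start // 3
            aa_len = min(piece // 3, grs_len[grs_id] - aa_lo)
            bits = _aa_bits(ident, aa_len) if aa_len >= 5 else 0.0
            if bits >= detection_floor:
                true_px_bits = bits
                px_rows.append(
                    _row(contig.id, grs_id, ident, aa_len, qstart, qstart + 3 * aa_len - 1,
                         aa_lo + 1, aa_lo + aa_len, bits, "aa")
                )

        # spurious rows (always drawn, applied at spurious_hit_rate, so the
        # noise stream is identical across divergence levels)
        u_nt, u_px = rng_n.random(2)
        nt_subject = gene_ids[int(rng_n.integers(0, len(gene_ids)))]
        nt_len = int(rng_n.integers(100, 200))
        nt_ident = float(rng_n.uniform(0.90, 0.96))
        nt_frac = float(rng_n.random())
        px_subject = grs_ids[int(rng_n.integers(0, len(grs_ids)))]
        px_len = int(rng_n.integers(33, 61))
        px_ident = float(rng_n.uniform(0.30, 0.60))
        px_bits = float(rng_n.uniform(40.0, 90.0))
        px_frac = float(rng_n.random())
        if u_nt < params.spurious_hit_rate and nt_subject != gid:
            slen = gene_len[nt_subject]
            nt_len = min(nt_len, slen)
            s0 = 1 + int(nt_frac * (slen - nt_len))
            nt_rows.append(
                _row(contig.id, nt_subject, nt_ident, nt_len, 1, nt_len,
                     s0, s0 + nt_len - 1, _nt_bits(nt_ident, nt_len), "nt")
            )
        if u_px < params.spurious_hit_rate and px_subject != grs_id:
            if params.divergence_my == 0 and true_px_bits is not None:
                px_bits = min(px_bits, 0.8 * true_px_bits)
            slen = grs_len[px_subject]
            px_len = min(px_len, slen)
            s0 = 1 + int(px_frac * (slen - px_len))
            px_rows.append(
                _row(contig.id, px_subject, px_ident, px_len, 1, 3 * px_len,
                     s0, s0 + px_len - 1, px_bits, "aa")
            )

    # protein-protein tables (both directions) for RBH
    pp_ab: list[AlignmentRecord] = []
    pp_ba: list[AlignmentRecord] = []
    for grs_id, gid in sorted(truth.ortholog_map.items()):
        targets = [(gid, truth.identity[gid])]
        paralog = next(
            (p for p, parent in truth.paralog_map.items() if parent == gid), None
        )
        if paralog is not None:
            targets.append((paralog, truth.identity[gid] * 0.98))
        for target, ident in targets:
            plen = min(grs_len[grs_id], prot_len[target])
            bits = _aa_bits(ident, plen)
            if bits < detection_floor:
                continue
            pp_ab.append(_row(grs_id, target, ident, plen, 1, plen, 1, plen, bits, "aa"))
            pp_ba.append(_row(target, grs_id, ident, plen, 1, plen, 1, plen, bits, "aa"))
    return AlignmentTables(nt=nt_rows, px=px_rows, pp_ab=pp_ab, pp_ba=pp_ba)


def make_annotations(
    truth: TruthSet,
    n_categories: int = 20,
    background_rate: float = 0.15,
    planted_category: str = "GO:9999999",
) -> tuple[dict[str, set[str]], list[str], list[str]]:
    """Random gene-to-category table with one planted biased category.

    Returns ``(annotations, list1, list2)`` where ``list1`` is the first
    half of the base genes.  The planted category is given to 90% of
    list1 and 5% of list2 (deterministic prefix counts), guaranteeing
    separation detectable by a two-list Fisher comparison.
    """
    rng_a = _rng(truth.params.seed, "annotation")
    base_ids = [g.id for g in truth.genes if g.id not in truth.paralog_map]
    half = len(base_ids) // 2
    list1, list2 = base_ids[:half], base_ids[half:]
    categories = [f"GO:{i:07d}" for i in range(1, n_categories + 1)]
    ann: dict[str, set[str]] = {}
    for gid in base_ids:
        mask = rng_a.random(n_categories) < background_rate
        ann[gid] = {c for c, m in zip(categories, mask) if m}
    for gid in list1[: max(1, int(round(0.9 * len(list1))))]:
        ann[gid].add(planted_category)
    for gid in list2[: int(round(0.05 * len(list2)))]:
        ann[gid].add(planted_category)
    return ann, list1, list2


def emit_fixture(truth: TruthSet, outdir: str | Path) -> dict:
    """Write a full fixture directory and return its manifest.

    Files are all plain text: three FASTA sets plus contigs, four
    alignment tables, two count tables, an annotation table and truth
    TSVs.  The manifest (YAML) records the seed, parameters and file
    list.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = emit_alignments(truth)
    ann, list1, list2 = make_annotations(truth)

    files: dict[str, str] = {}

    def _register(name: str) -> Path:
        files[name] = name
        return outdir / name

    write_fasta(truth.genes, _register("target_genes.fasta"))
    write_fasta(truth.proteins.values(), _register("target_proteins.fasta"))
    write_fasta(truth.grs_proteins, _register("grs_proteins.fasta"))
    write_fasta(truth.contigs, _register("contigs.fasta"))
    write_alignments(tables.nt, _register("aln_contig_vs_target.nt.tsv"))
    write_alignments(tables.px, _register("aln_contig_vs_grs.px.tsv"))
    write_alignments(tables.pp_ab, _register("aln_grs_vs_target.pp.tsv"))
    write_alignments(tables.pp_ba, _register("aln_target_vs_grs.pp.tsv"))
    write_counts(truth.contig_counts, _register("contig_counts.tsv"))
    write_counts(truth.gene_counts, _register("gene_counts.tsv"))
    write_annotations(ann, _register("annotations.tsv"))

    with open(_register("truth_orthologs.tsv"), "w") as fh:
        for grs_id, gid in sorted(truth.ortholog_map.items()):
            fh.write(f"{grs_id}\t{gid}\n")
    with open(_register("truth_placements.tsv"), "w") as fh:
        for cid, p in sorted(truth.placements.items()):
            fh.write(f"{cid}\t{p.gene}\t{p.start}\t{p.end}\n")
    with open(_register("truth_expression.tsv"), "w") as fh:
        for gid in sorted(truth.expression):
            fh.write(f"{gid}\t{truth.expression[gid]:.4f}\n")

    manifest = {
        "seed": truth.params.seed,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(truth.params).items()
        },
        "n_genes": len(truth.genes),
        "n_contigs": len(truth.contigs),
        "planted_category": "GO:9999999",
        "planted_list1": list1,
        "planted_list2": list2,
        "files": sorted(files),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
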