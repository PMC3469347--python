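import dataclasses
from pathlib import Path

import numpy as np
import pytest

from scaffold_eval.enrichment import compare_lists
from scaffold_eval.io_formats import (
    read_alignments,
    read_annotations,
    read_counts,
    read_fasta,
)
from scaffold_eval.synthetic import (
    MIN_PIECE_NT,
    SimParams,
    emit_alignments,
    emit_fixture,
    make_annotations,
    simulate,
)


class TestSimulate:
    def test_zero_divergence_proteins_identical(self):
        truth = simulate(SimParams(divergence_my=0.0, seed=3))
        for grs in truth.grs_proteins:
            target = truth.ortholog_map[grs.id]
            assert grs.seq == truth.proteins[target].seq

    def test_same_seed_identical_output(self):
        a = simulate(SimParams(seed=42, divergence_my=30.0))
        b = simulate(SimParams(seed=42, divergence_my=30.0))
        assert [r.seq for r in a.genes] == [r.seq for r in b.genes]
        assert a.contig_counts.counts == b.contig_counts.counts
        assert a.identity == b.identity
        ta, tb = emit_alignments(a), emit_alignments(b)
        assert ta.nt == tb.nt and ta.px == tb.px

    def test_placements_lie_within_source_genes(self):
        truth = simulate(SimParams(seed=5))
        lengths = truth.gene_lengths
        for cid, p in truth.placements.items():
            assert 0 <= p.start < p.end <= lengths[p.gene]
            piece = truth.contigs
        by_id = {c.id: c for c in truth.contigs}
        for cid, p in truth.placements.items():
            contig = by_id[cid]
            core = contig.seq[p.utr_left: p.utr_left + (p.end - p.start)]
            gene = next(g for g in truth.genes if g.id == p.gene)
            assert core == gene.seq[p.start: p.end]

    def test_contig_counts_never_exceed_gene_totals(self):
        truth = simulate(SimParams(seed=6))
        per_gene: dict[str, int] = {}
        for cid, count in truth.contig_counts.counts.items():
            gene = truth.placements[cid].gene
            per_gene[gene] = per_gene.get(gene, 0) + count
        for gene, total in per_gene.items():
            assert total <= truth.gene_counts.counts[gene]

    def test_mean_coverage_tracks_generative_beta(self):
        # Beta(8, 2) assembled fraction: mean realized sum coverage across
        # seeds should sit near 0.8
        fractions = []
        for seed in range(8):
            truth = simulate(SimParams(seed=seed, n_genes=40))
            for gene in truth.genes:
                if any(p.gene == gene.id for p in truth.placements.values()):
                    fractions.append(truth.covered_fraction(gene.id))
        assert abs(np.mean(fractions) - 0.8) < 0.05

    def test_divergence_monotone_in_identity_at_fixed_seed(self):
        idents = []
        for my in (0.0, 20.0, 80.0, 160.0):
            truth = simulate(SimParams(seed=9, divergence_my=my))
            idents.append(truth.identity)
        for lo, hi in zip(idents, idents[1:]):
            for gene in lo:
                assert hi[gene] <= lo[gene] + 1e-12

    def test_min_gene_length_exercises_aa_thresholds(self):
        truth = simulate(SimParams(seed=1, gene_len_meanlog=4.0, gene_len_sdlog=0.5))
        assert all(g.length >= 102 for g in truth.genes)
        assert all(g.length % 3 == 0 for g in truth.genes)


class TestEmitAlignments:
    def test_zero_noise_best_hits_are_true_genes(self, noise_free_world):
        truth, tables = noise_free_world
        from scaffold_eval.assignment import best_hit

        for table, id_map in ((tables.nt, None), (tables.px, truth.gene_to_grs)):
            hits = best_hit(table)
            for contig, assignment in hits.items():
                true_gene = truth.placements[contig].gene
                expected = true_gene if id_map is None else id_map[true_gene]
                assert assignment.subject_id == expected

    def test_bitscore_decreases_with_divergence(self):
        """At fixed seed, every surviving translated hit loses bitscore as
        divergence grows, so assignment quality can only degrade."""
        by_level = {}
        for my in (5.0, 40.0, 160.0):
            tables = emit_alignments(simulate(SimParams(seed=4, divergence_my=my)))
            by_level[my] = {
                (r.qseqid, r.sseqid): r.bitscore
                for r in tables.px
            }
        for lo, hi in ((5.0, 40.0), (40.0, 160.0)):
            common = set(by_level[lo]) & set(by_level[hi])
            assert common
            assert all(by_level[hi][k] <= by_level[lo][k] + 1e-9 for k in common)

    def test_spurious_rows_never_beat_true_rows_at_zero_divergence(self):
        params = SimParams(seed=8, divergence_my=0.0, spurious_hit_rate=0.5)
        truth = simulate(params)
        tables = emit_alignments(truth)
        best_true: dict[str, float] = {}
        spurious: dict[str, float] = {}
        for r in tables.px:
            true_grs = truth.gene_to_grs.get(
                truth.paralog_map.get(
                    truth.placements[r.qseqid].gene, truth.placements[r.qseqid].gene))
            if r.sseqid == true_grs:
                best_true[r.qseqid] = max(best_true.get(r.qseqid, 0.0), r.bitscore)
            else:
                spurious[r.qseqid] = max(spurious.get(r.qseqid, 0.0), r.bitscore)
        assert spurious  # the 50% rate must actually produce noise rows
        for contig, noise_bits in spurious.items():
            if contig in best_true:
                assert noise_bits < best_true[contig]

    def test_coordinates_are_one_based_inclusive(self, noisy_world):
        truth, tables = noisy_world
        lengths = truth.gene_lengths
        for r in tables.nt:
            assert min(r.sstart, r.send) >= 1
            assert max(r.sstart, r.send) <= lengths[r.sseqid]
            assert r.s_hi - r.s_lo == abs(r.send - r.sstart) + 1

    def test_reversed_subject_coordinates_present(self, noisy_world):
        _truth, tables = noisy_world
        assert any(r.sstart > r.send for r in tables.nt)


class TestFixture:
    def test_fixture_files_parse_and_manifest_complete(self, tmp_path):
        truth = simulate(SimParams(seed=2, n_genes=20))
        manifest = emit_fixture(truth, tmp_path)
        assert len(manifest["files"]) >= 10
        assert (tmp_path / "manifest.yaml").exists()
        contigs = read_fasta(tmp_path / "contigs.fasta")
        assert len(contigs) == len(truth.contigs)
        genes = read_fasta(tmp_path / "target_genes.fasta")
        assert len(genes) == manifest["n_genes"]
        rows = read_alignments(tmp_path / "aln_contig_vs_target.nt.tsv")
        assert rows
        counts = read_counts(tmp_path / "contig_counts.tsv")
        assert counts.total_mapped == truth.params.total_reads
        ann = read_annotations(tmp_path / "annotations.tsv")
        assert ann
        truth_rows = (tmp_path / "truth_placements.tsv").read_text().splitlines()
        assert len(truth_rows) == len(truth.placements)

    def test_planted_category_detected(self):
        truth = simulate(SimParams(seed=13, n_genes=50))
        ann, list1, list2 = make_annotations(truth)
        results = compare_lists(list1, list2, ann)
        planted = {r.category: r for r in results}["GO:9999999"]
        assert planted.p_raw < 0.05
        assert planted.direction == "over"
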