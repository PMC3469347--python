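import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scaffold_eval.assignment import NT_DIRECT
from scaffold_eval.coverage import (
    basic_metrics,
    crr_profiles,
    merge_intervals,
    summarize,
    union_coverage,
)
from scaffold_eval.io_formats import SequenceRecord

from conftest import make_aln
from oracles import coverage_by_positions, n50_by_definition


def contigs_of(lengths):
    return [SequenceRecord(id=f"c{i}", seq="A" * n) for i, n in enumerate(lengths)]


class TestBasicMetrics:
    def test_worked_example(self):
        m = basic_metrics(contigs_of([5, 4, 3, 2, 1]))
        assert m.total_len == 15
        assert m.n50 == 4  # cumulative 5, 9 first reaches 7.5 at the 4-contig
        assert m.max_len == 5 and m.median_len == 3

    def test_single_contig(self):
        m = basic_metrics(contigs_of([10]))
        assert m.n50 == m.mean_len == m.median_len == m.max_len == 10

    def test_empty_assembly_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            basic_metrics([])

    @pytest.mark.parametrize("seed", range(10))
    def test_n50_matches_definition_scan(self, seed):
        rng = random.Random(seed)
        lengths = [rng.randint(100, 5000) for _ in range(1000)]
        m = basic_metrics(contigs_of(lengths))
        assert m.n50 == n50_by_definition(lengths)
        assert min(lengths) <= m.n50 <= max(lengths)


class TestUnionCoverage:
    def test_stacked_identical_intervals_counted_once(self):
        # five contigs all aligned to (1-based inclusive) 150..550 of a gene:
        # the union is one interval of exact half-open length 401
        rows = [make_aln(f"c{i}", "g", length=401, sstart=150, send=550)
                for i in range(5)]
        cov = union_coverage(rows, ref_length=1000)
        assert cov.intervals == ((149, 550),)
        assert cov.covered_length == 401

    def test_partial_overlap(self):
        rows = [make_aln("c1", "g", length=100, sstart=1, send=100),
                make_aln("c2", "g", length=100, sstart=51, send=150)]
        cov = union_coverage(rows, ref_length=200)
        assert cov.covered_length == 150
        assert cov.covered_length == coverage_by_positions(
            [r.subject_interval for r in rows], 200)

    def test_no_alignments(self):
        cov = union_coverage([], ref_length=100)
        assert cov.intervals == () and cov.covered_length == 0

    def test_overhang_is_clipped_not_an_error(self, caplog):
        rows = [make_aln("c1", "g", length=100, sstart=951, send=1050)]
        with caplog.at_level("WARNING"):
            cov = union_coverage(rows, ref_length=1000)
        assert cov.covered_length == 50
        assert any("clipping" in rec.message for rec in caplog.records)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_per_position_oracle(self, seed):
        rng = random.Random(seed)
        ref_len = rng.randint(50, 2000)
        rows = []
        for i in range(rng.randint(1, 30)):
            lo = rng.randint(0, ref_len - 2)
            hi = rng.randint(lo + 1, ref_len)
            rows.append(make_aln(f"c{i}", "g", length=hi - lo,
                                 sstart=lo + 1, send=hi))
        cov = union_coverage(rows, ref_len)
        assert cov.covered_length == coverage_by_positions(
            [r.subject_interval for r in rows], ref_len)

    def test_permutation_invariance_and_idempotence(self):
        rng = random.Random(3)
        rows = [make_aln(f"c{i}", "g", length=50, sstart=s + 1, send=s + 50)
                for i, s in enumerate(rng.sample(range(900), 20))]
        base = union_coverage(rows, 1000)
        rng.shuffle(rows)
        assert union_coverage(rows, 1000) == base
        assert merge_intervals(base.intervals) == base.intervals

    def test_adding_an_alignment_never_decreases_coverage(self):
        rng = random.Random(4)
        rows = []
        last = 0
        for i in range(30):
            lo = rng.randint(0, 900)
            rows.append(make_aln(f"c{i}", "g", length=60, sstart=lo + 1, send=lo + 60))
            cur = union_coverage(rows, 1000).covered_length
            assert cur >= last
            last = cur


@given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 100)),
                max_size=30))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_merge_intervals_is_a_disjoint_sorted_union(spans):
    intervals = [(lo, lo + ln) for lo, ln in spans]
    merged = merge_intervals(intervals)
    for (_a, b), (c, _d) in zip(merged, merged[1:]):
        assert b < c  # disjoint and non-touching
    assert sum(hi - lo for lo, hi in merged) == coverage_by_positions(intervals, 700)
    assert merge_intervals(merged) == merged


class TestCrrProfiles:
    def test_full_coverage_single_contig(self):
        rows = [make_aln("c1", "g1", length=300, sstart=1, send=300)]
        p = crr_profiles(rows, {"g1": 300}, NT_DIRECT)["g1"]
        assert p.sum_crr == p.longest_crr == 1.0
        assert p.n_contigs_hitting == 1

    def test_complementary_halves(self):
        # two non-overlapping contigs each covering half: full union coverage,
        # but the best single contig only reaches 0.5
        rows = [make_aln("c1", "g1", length=150, sstart=1, send=150),
                make_aln("c2", "g1", length=150, sstart=151, send=300)]
        p = crr_profiles(rows, {"g1": 300}, NT_DIRECT)["g1"]
        assert p.sum_crr == 1.0
        assert p.longest_crr == 0.5
        assert sorted(p.all_crr) == [0.5, 0.5]

    def test_missing_ref_length_names_gene(self):
        rows = [make_aln("c1", "ghost", length=150)]
        with pytest.raises(ValueError, match="ghost"):
            crr_profiles(rows, {"g1": 300}, NT_DIRECT)

    @pytest.mark.parametrize("seed", range(15))
    def test_sum_crr_matches_boolean_array_oracle(self, seed):
        rng = random.Random(seed)
        ref_lengths = {f"g{i}": rng.randint(200, 1500) for i in range(20)}
        rows = []
        for i in range(300):
            gene = f"g{rng.randint(0, 19)}"
            L = ref_lengths[gene]
            lo = rng.randint(0, L - 120)
            rows.append(make_aln(f"c{rng.randint(0, 80)}", gene, length=110,
                                 sstart=lo + 1, send=lo + 110, pident=99.0))
        profiles = crr_profiles(rows, ref_lengths, NT_DIRECT)
        for gene, p in profiles.items():
            expected = coverage_by_positions(
                [r.subject_interval for r in rows if r.sseqid == gene],
                ref_lengths[gene])
            assert p.covered_length == expected
            assert p.sum_crr == expected / ref_lengths[gene]
            assert p.longest_crr <= p.sum_crr + 1e-12

    def test_hybrid_coverage_at_least_max_of_parts(self):
        rng = random.Random(9)
        ref_lengths = {"g": 1000}
        set_a = [make_aln(f"a{i}", "g", length=100, sstart=s + 1, send=s + 100)
                 for i, s in enumerate(rng.sample(range(900), 5))]
        set_b = [make_aln(f"b{i}", "g", length=100, sstart=s + 1, send=s + 100)
                 for i, s in enumerate(rng.sample(range(900), 5))]
        crr_a = crr_profiles(set_a, ref_lengths, NT_DIRECT)["g"].sum_crr
        crr_b = crr_profiles(set_b, ref_lengths, NT_DIRECT)["g"].sum_crr
        crr_ab = crr_profiles(set_a + set_b, ref_lengths, NT_DIRECT)["g"].sum_crr
        assert crr_ab >= max(crr_a, crr_b)


class TestSummarize:
    def test_counting_with_threshold(self):
        rows = []
        for gene, frac in [("g1", 1.0), ("g2", 0.95), ("g3", 0.5)]:
            n = int(1000 * frac)
            rows.append(make_aln("c_" + gene, gene, length=n, sstart=1, send=n))
        profiles = crr_profiles(rows, {f"g{i}": 1000 for i in range(1, 4)}, NT_DIRECT)
        s = summarize(profiles, n_ref_genes=10)
        assert s.n_genes_hit == 3
        assert s.n_genes_crr_ge_threshold == 2  # 1.0 and 0.95
        assert s.n_ref_genes == 10

    def test_empty_profiles(self):
        s = summarize({}, n_ref_genes=5)
        assert s.n_genes_hit == 0 and s.n_genes_crr_ge_threshold == 0
        assert s.mean_crr == s.median_crr == 0.0
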