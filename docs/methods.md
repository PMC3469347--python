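# Methods

## Coordinates and interval arithmetic

Tabular alignment rows arrive 1-based inclusive, with subject coordinates
possibly reversed for minus-strand nucleotide hits. Internally everything
is 0-based half-open on the forward subject strand: an inclusive hit
`sstart..send` becomes `[min−1, max)`, so interval lengths are exact and
unions are additive. A consequence worth spelling out: five contigs all
aligned to positions 150..550 of a gene cover one union interval of
**401** positions; the end−start figure of 400 sometimes quoted for such
a span is the same interval described as a range rather than a count. The
toolkit always reports the exact half-open union length. Query
coordinates are parsed but not normalized — only subject intervals drive
coverage. Alignments extending past the subject's annotated length
(end-effects of local alignment) are clipped with a warning, never
rejected. For translated and protein searches subject intervals are in
amino-acid units and are never converted to nucleotides; coverage of a
protein reference is reported in aa.

## Coverage (CRR) conventions

`sum_crr` uses *every* alignment passing thresholds, from any contig — a
contig may contribute coverage to several genes. This reflects coverage
"by at least one contig" computed before unique assignment; a
`coverage-mode=best-hit` option restricts each contig's contribution to
its single best-hit gene for users who prefer the stricter reading.
Transcriptome-level mean/median CRR are over represented genes only
(genes with no passing hit are counted in `n_ref_genes` but excluded from
averages, which would otherwise be dominated by absent genes). N50 is the
length-weighted median contig size: the contig length at which the
descending cumulative sum first reaches half the total.

## Assignment and orthology

Threshold profiles (identity strict `>`, length and e-value inclusive,
bitscore inclusive):

| profile | use | criteria |
|---|---|---|
| `nt_direct` | contig → target gene, BLASTn-style | identity > 95%, ≥ 100 nt, e ≤ 1e-6 |
| `px_default` | contig → GRS protein, translated | bitscore ≥ 50, e ≤ 1e-6, ≥ 33 aa |
| `px_stringent` | stricter variant of the above | bitscore ≥ 100, e ≤ 1e-25, ≥ 33 aa |
| `pp_rbh` | protein ↔ protein orthology | identity > 60%, ≥ 33 aa, e ≤ 1e-5 |

Best hits maximize bitscore (database-size independent), with ties broken
by lower e-value, longer alignment, then lexicographically smaller
subject id, so assignment is fully deterministic. A query whose rows are
all filtered gets *no* assignment — never a fallback. RBH pairs are
mutual best hits after `pp_rbh` filtering. The redundancy filter for
predicted gene sets removes, for each pair passing its policy (nt:
identity > 95% over ≥ 100 nt, e ≤ 1e-6; protein: > 90% over ≥ 33 aa),
the shorter member (id tie-break on equal lengths). Pairs are processed
sorted by (e-value, min id, max id), skipping pairs with an
already-removed member; how redundancy *clusters* of three or more
members should collapse is genuinely under-determined, and this order
rule is one concrete, deterministic, idempotent choice.

## Triangulated proxy error

Each contig with a proxy (translated-search) assignment is labelled:
`no_direct` if it has no direct assignment, `no_rbh` if its GRS gene has
no RBH partner, else `correct`/`incorrect` by whether the RBH partner
equals the direct gene. `error_pct` uses only triangulable contigs
(`correct + incorrect`) as denominator — correctness is undefined for the
others — but the full status partition is always reported so alternative
denominators can be recomputed. RBH orthology is treated as ground truth
for scoring, so mis-assignments are attributed to the translated search.

## Expression

RPKM is `10⁹·C/(N·L)` with `N` the library's total mapped reads. For the
via-assembly route, `L` may be the covered gene length rather than the
full length, reflecting the sequence actually available for mapping.
Spearman correlation between two quantifications uses average ranks over
the genes present in both tables (zeros kept); MA coordinates and
residuals `r = log2(x) − log2(y)` use base 2 and drop genes with a zero
in either table, since their logs are undefined. Residuals are 0 when
the two methods agree exactly. Counting-scheme subtleties of the
upstream read mapper (broken pairs, multi-hit caps, uniqueness) are
upstream concerns: count tables are trusted as given.

## Enrichment

For each category in either gene list the 2×2 table (in/out × list1/
list2) is tested with the two-tailed Fisher exact test under the
probability-mass definition (sum of hypergeometric probabilities of
tables no more probable than observed; computed by `scipy`). Lists are
deduplicated first; genes missing from the annotation table count with
zero categories. Significance counting is strict `p < alpha` on raw
p-values by default — the multiple-testing behaviour of the GUI tools
this mirrors is not documented — with BH-adjusted values always reported
alongside. Categories are tested as directly annotated; no ontology-graph
propagation.

## Synthetic worlds

The generator emulates the benchmarking setting: a target gene set,
a divergent reference proteome with known orthology, a fragmented
assembly, alignment tables and read counts, all truth-labelled.

Defaults (one world): 50 genes with log-normal lengths (median ~1.3 kb,
floor 102 nt so translated thresholds are exercisable); log-normal
expression (sd of logs 1.2, spanning ~3 decades) and 100 000 reads
multinomially allocated to genes; per gene a Poisson(3) number of contig
fragments covering a Beta(8,2) fraction (mean 0.8) of it, fragment
placement uniform, each fragment at least 105 nt; contigs carry 10%
random non-coding UTR overhang; 5% of genes have a recent paralog (2% aa
divergence, no own ortholog — the copy-number confound); 5% of contigs
get a spurious alignment row. Divergence: per-gene rates are Gamma(2)
with mean 1, the substitution probability at `t` My is `1 − exp(−r·λ·t)`
with `λ = 0.005`/site/My, giving ~45% mean identity at 160 My —
bracketing the "distant usable reference" regime. Reads are conserved
exactly: contig counts are a multinomial split of the gene's reads over
its fragments plus the uncovered remainder, so a fully tiled gene's
contig counts sum to its direct count.

Alignment statistics come from a monotone surrogate, not a scoring
matrix: aa rows score `3·identity − 1` bits per column, nt rows
`2·(2·identity − 1)`, e-value `1e6·2^−bits`, with a 25-bit detection
floor. Downstream logic consumes only thresholds and orderings, so this
is sufficient; absolute bitscores should not be compared with real BLAST
output. Spurious rows draw bitscores in U(40, 90) — below any true hit
at zero divergence (enforced), overtaking weak true hits as divergence
grows, which is what makes mis-assignment error rise with distance.
Protein mutation is uniform over amino acids (no BLOSUM weighting):
identity, the only consumed quantity, is controlled directly. No indels,
no codon model, no read-level errors; real data add alignment ambiguity
and mapping noise these fixtures do not represent, so passing recovery
tests bounds algorithmic correctness, not real-world accuracy.

Randomness is split into named substreams (genes, divergence, contigs,
expression, noise, annotation) of one master seed, and divergence-
dependent mutation uses per-site uniform thresholds, so raising
divergence at a fixed seed degrades every gene monotonically while all
other draws stay identical. Divergence sweeps therefore reuse each seed
at every level — a paired design in which error/correlation trends are
not confounded by between-world sampling noise. Sweeps run at 20 genes
(median ~2.5 kb) × ~10 fragments each (~200 contigs) × 10 seeds × 6
levels (5, 13, 25, 40, 83, 160 My), sizes chosen to keep a full sweep
under a few seconds while leaving ~50+ triangulable contigs per world at
the far end.

The Fisher null calibration uses a 2000-gene universe, a 400-gene random
list against its complement, and 60 categories with prevalence U(0.1,
0.5) over 80 replicates: large enough margins that the hypergeometric
support is dense and the exact test's discreteness does not make it
visibly conservative at alpha = 0.05.

## Known limitations

- Isoforms are invisible: coverage and expression are whole-gene.
- Chimeric/over-predicted contigs are not penalized by CRR.
- The surrogate score model cannot reproduce absolute BLAST statistics.
- Paralog handling is deliberately simple (one recent copy per family);
  deep gene families and birth–death dynamics are out of scope.
- Orphan genes (no homolog in the reference) appear only implicitly, as
  genes whose hits fall below thresholds at high divergence.
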