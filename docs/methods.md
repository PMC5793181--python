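# Methods

`srnascape` re-creates, as a tested and reusable pipeline, the analysis of
small non-coding RNA (sRNA) sequencing data from triple-negative breast
cancer (TNBC) cell lines: quantification of seven sRNA species, isomiR and
tRNA-fragment profiling, differential expression between the four TNBC
transcriptional subtypes (BL1, BL2, M, LAR), and miRNA–mRNA Spearman
correlation networks. Everything is exercised on synthetic data with known
ground truth; this note records the models, the defaults, and the design
choices made where the design was genuinely open.

## Read processing model

Raw single-end reads (~50 nt) are assumed to be `insert + 3' adapter`,
possibly truncated at the read length. Processing is:

1. **Adapter trimming.** The leftmost position where the read suffix matches
   a prefix of the adapter with mismatch fraction ≤ `max_error_rate`
   (default 0.1) over an overlap of ≥ `min_overlap` (default 5 nt) truncates
   the read. These defaults follow common small-RNA trimming practice; the
   adapter itself defaults to the Illumina TruSeq small-RNA 3' adapter
   (`TGGAATTCTCGGGTGCCAAGG`) and is configurable, since library kits vary.
   Reads without a detectable adapter are kept.
2. **Length filter.** Trimmed reads shorter than 16 nt are discarded; 16 nt
   is retained (the rule is strictly "less than 16").
3. **Tag collapsing.** Identical trimmed sequences collapse to one
   *tag* with a copy number per sample; quantification downstream is purely
   sequence + copy-number driven, and quality scores are ignored after
   trimming. Collapsing is lossless: expanding tags by copies reproduces
   the usable read multiset exactly, and the funnel conserves counts
   (`n_raw = n_usable + n_too_short`) to the read.

Reads containing `N` are retained; `N` matches no base anywhere (trimming
and alignment both count it as a mismatch).

## Alignment

Tags map to the whole genome full-length, on both strands, with **at most
one substitution and no gaps**. Because miRNAs carry 1–3 non-templated
additions (NTA) at the 3' end, alignment retries with the last
k = 0..`max_nta` (default 3) bases removed. NTA bases are excluded from
mismatch counting, so the reported hit tier minimizes **(mismatches, then
trimmed length)**: a tag ending in two genuinely non-genomic bases is
reported as (0 mismatches, NTA = 2) rather than (1 mismatch, NTA = 1).
The aligned portion must stay ≥ 16 nt. All hits of the best tier are
reported (ties are real multimapping).

The search is seed-and-verify against a precomputed 8-mer position index:
under ≤ 1 mismatch one half of the query is exact (pigeonhole), so every
indexed occurrence of either half's leading 8-mer is a candidate, verified
over the full query. The test suite checks the aligner against an
exhaustive numpy scan over every position, strand and trim length — the
oracle is independent code, never the implementation.

## Annotation and quantification

Features come from a GFF3-like annotation with seven categories: miRNA,
tRNA (with an anticodon label such as `Val_CAC`), snoRNA, snRNA, yRNA, 7SK,
7SL. A hit is attributed to same-strand features covering at least
`overlap_fraction` (default 0.8) of the aligned span. When a tag touches
loci of several categories, only the highest-priority category survives —
**miRNA > tRNA > snoRNA > snRNA > yRNA > 7SK > 7SL** — so category totals
are disjoint and reproducible; the order puts the most specifically
annotated, shortest species first. Ties within the winning category split
the tag's weight equally (deterministic, count-preserving; random choice
and discarding were rejected for non-determinism and count loss).

miRNA-assigned tags are classified by their 5' offset from the annotated 5'
start, measured on the **biological** 5' end (for minus-strand loci the
offset is computed from the genomic end coordinate): offset 0 is canonical;
+1 and +2 are isomiRs, quantified as separate features (`mir|+1`,
`mir|+2`) of species "isomiR", matching how isomiRs are tabulated as their
own species. Any other offset still counts as evidence for the miRNA locus
by default (`strict_5p_offsets=False`); strict mode excludes such tags into
a separate tally instead.

Counting conserves mass exactly: per sample,
`Σ species totals + unannotated (+ strict-mode exclusions) = mapped copies`.
Unmapped tags are tallied separately. Detection curves report, per sample,
the number of features with count ≥ threshold for thresholds 1, 5, 10, 15,
20 — non-increasing by construction. Median expression profiles use the
per-feature median across samples (even n: mean of the central pair), with
ties broken lexicographically.

## tRNA analysis

tRNA counts aggregate to anticodon families; fractions (family count /
total tRNA count per sample) are the unit of comparison so results are
library-size free. Positional coverage adds each tRNA read's
copies × weight to feature positions `[offset, offset + aligned_length)`,
clipped to the locus; per-family profiles pool loci into 100 percentile
bins so families of different lengths (76–90 nt typically) are comparable.
The **5'-half fraction** — the share of unbinned depth at positions
< L/2 — summarizes the characteristic dominance of 5'-half tRNA fragments.
Reads with offsets outside [−2, L) are excluded from coverage and tallied;
−2 tolerates small 5' wobble. Family-level differential comparisons use
rank-sum tests on fractions (one-vs-rest), with effect = difference of
group mean fractions and BH FDR across families.

## Differential expression

Counts normalize to CPM; when a species matrix is one slice of a larger
quantification, CPM uses per-sample totals pooled over **all** species, so
sparse species stay on a comparable scale and never divide by zero. Tests
run on log2(CPM + 1) (pseudocount 1: zero-safe and standard).

Per feature, three criteria are computed for a comparison (pairwise or
one-vs-rest): a two-sided Wilcoxon rank-sum p, a two-sided Welch t p, and
the log2 fold change of group mean CPM (+1). Features are ranked by each
criterion and **aggregate rank = sum of the three ranks**, a rank
aggregation over complementary evidence in the spirit of consensus callers
that sum per-method ranks. FDR is BH over the rank-sum p-values;
`significant` requires FDR < α (default 0.05) and |log2FC| ≥ 1 (defaults,
config-exposed). The rank-sum p uses the exact null for tie-free rows and
the tie-corrected normal approximation otherwise (scipy's vectorized "auto"
mode would downgrade every row as soon as any row has ties).

With n = 7 vs 7 the exact two-sided rank-sum p cannot go below
2/C(14,7) ≈ 5.8 × 10⁻⁴, so a *single* true positive among hundreds of
features can never clear BH at 0.05; power scenarios in the tests therefore
spike a small set of features (~5% of the panel), which is also the more
realistic regime.

**Exclusivity.** A feature is exclusive to subtype S iff significant in
"S vs others" and in no other subtype's one-vs-rest test — sets are
pairwise disjoint by construction. Exclusivity is defined from one-vs-rest
comparisons alone (not intersected with pairwise results); this matches the
"vs. others" framing of per-subtype unique-sRNA tables.

**Compositional caveat.** CPM couples features through the library total:
when spiked features hold a non-negligible share of a subtype's library,
every other feature's CPM is depressed in that subtype, which can make
strong spikes significant (as apparent depletion) in *other* subtypes'
one-vs-rest tests and thereby shrink exclusive sets. The effect scales with
(spiked share × fold change) relative to the counting noise floor
(≈ 1/√count); test scenarios are sized so it stays below the noise floor
(e.g., 2000-feature panels), and the default pipeline run, where miRNA
spikes are deliberately abundant, exhibits the leakage — a real property of
total-count normalization, not a defect of the test.

## Correlation networks

All correlations are Spearman's rank correlation (mid-ranks for ties,
Pearson on ranks), chosen for robustness to outliers and to monotone scale
differences between platforms. p-values: t approximation with n − 2 df for
n ≥ 10; for n < 10, exact permutation over all n! orderings, or 10,000
sampled permutations when n! exceeds 10,000 (n = 8 and 9). Expression
enters as log2(CPM + 1) for count matrices (`normalize="cpm"`); matrices
that are already depth-normalized can pass through unchanged
(`normalize="none"`). Constant and all-zero rows are dropped and audited.
BH q-values are computed across all pairs within each sRNA category.

The **direction-bias profile** bins records by |rho| (width 0.1, last bin
closed at 1.0; the bin width is a reporting choice) and reports the
fraction of positive correlations per bin; zero-rho records carry no
direction and are excluded. Gene-class summaries count, per listed tumor
suppressor or oncogene, the distinct miRNAs correlated negatively/
positively at |rho| ≥ 0.5 and q ≤ 0.05 (both config-exposed; "significantly
correlated" has no canonical numeric definition). The subtype target table
pairs miRNAs significantly up (down) in "S vs others" with class-listed
genes they correlate negatively with, emitting both relation directions
with explicit labels (`decreased_target_of_increased_miRNA`,
`increased_target_of_decreased_miRNA`) and full provenance rather than
guessing a single table semantics. Network export writes deterministic
edge/node tables (sorted by |rho| descending, then ids) importable by
standard network viewers.

## Synthetic data

The generator defines the study conditions end to end:

- **Reference**: random ACGT genome (2 × 50 kb by default) with
  non-overlapping features placed uniformly with bounded retries —
  60 miRNA (19–25 nt), 20 tRNA (73–94 nt, anticodons cycling through 22
  families with Val/Gly/Glu/Lys/His first), 15 snoRNA, 10 snRNA, 8 yRNA,
  4 7SK, 4 7SL. Features sit on the + strand by default
  (`plus_strand_only=False` alternates strands for strand-handling tests).
- **Design**: 26 samples — BL1 × 7, BL2 × 5, M × 7, LAR × 7 — mirroring a
  26-cell-line panel; 200,000 usable reads per sample; 1 × 50 nt reads.
- **Expression**: per-feature log-normal baseline (log2 mean 6, sd 1.5)
  shared across samples, with category offsets (+2 miRNA, +1 tRNA) so
  miRNA dominates the library as in size-selected small-RNA data. Spiked
  features multiply their expectation by 2^lfc in the named subtype only;
  the default spike table gives LAR the most subtype-specific features and
  BL2 the fewest (LAR 10, M 6, BL1 3, BL2 1, |lfc| = 3), echoing the
  relative subtype exclusivity of TNBC lines. Realized counts are one
  multinomial draw per sample, so column sums are exact.
- **Reads**: insert (miRNA 5' offset 0/+1/+2 with probabilities
  0.7/0.2/0.1; tRNA 5'-half fragments ending at L/2 ± 5 with probability
  `trna_half_bias` = 0.85, else uniformly positioned fragments; other
  species full-length) + NTA bases (miRNA only — 3' tailing is a miRNA
  phenomenon — lengths 0–3 with probabilities 0.6/0.25/0.1/0.05) + adapter,
  truncated to 50 nt, then per-base substitution errors at rate 0.001.
  Every read has exactly one provenance row (source feature, offset, NTA
  length, error count, fragment span).
- **Paired matrices**: Gaussian copula; each designated (sRNA, mRNA, ρs)
  pair shares a latent bivariate normal with Pearson r = 2·sin(π·ρs/6)
  (the exact Gaussian Spearman↔Pearson map, giving analytically controlled
  targets), pushed through a strictly monotone exponential to count-like
  positive values. In the end-to-end pipeline the mRNA matrix is generated
  *after* quantification, conditioned on the quantified miRNA matrix's
  normal scores, so designated correlations are recoverable from actual
  pipeline output; 70% of designated pairs are positive, giving the
  expected positive directional bias, and spiked miRNAs are wired to
  anti-correlated class-listed genes so the subtype target table has
  ground-truthed rows.

What the generator does **not** emulate: ligation bias, PCR duplication
structure, realistic quality scores, indels, novel (unannotated) sRNAs,
overlapping loci, and real genomic repeat structure. Passing recovery tests
therefore demonstrates correctness of the pipeline's bookkeeping and
statistics under its stated model, not robustness to those artifacts.

## Determinism and numerics

Every stochastic step derives its generator from a single seed via
`SeedSequence((seed, salt))`; identical config + seed reproduce every
output byte-for-byte (the pipeline writes a sha256 manifest and the test
suite asserts two full runs match). Fraction normalizations carry a 1e-9
tolerance; bias-profile binning adds 1e-9 before flooring to absorb float
quotients (0.6/0.1 = 5.999…); ranks use the "min" method so aggregate
ranks are integers; all row orders in outputs are explicitly sorted.

## Problem sizes used in tests

The default end-to-end run is 26 samples × 200,000 reads (≈ 60 s); the
clean-recovery check uses 4 samples × 200,000 zero-error reads; aligner
oracle equivalence uses 1,000 tags against 50 kb; DE calibration/power use
500-feature panels at 7 vs 7 over 50 rounds/seeds, and the exclusivity
scenario a 2000-feature panel (see the compositional caveat); copula
recovery uses n = 26 with 20 seeds and the bias profile 500 designated
pairs at n = 1000. These sizes were chosen so each check has clear
statistical resolution at interactive runtimes.

## Known limitations

- One mismatch and no gaps is a hard contract; indel-bearing reads are
  unmappable by design.
- The rank aggregation stands in for multi-method consensus callers; it
  does not model negative-binomial dispersion, and `de_test` accepts
  externally supplied per-method p-value columns only in the sense that
  any matrix of statistics can be ranked the same way upstream.
- CPM is the only built-in normalization; compositional effects under
  heavy spiking are documented above rather than corrected.
- Exclusivity is one-vs-rest only; pairwise-consistent definitions would
  give different (smaller) sets.
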