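# Methods

This note documents the statistical models and procedures implemented in
`exonhancer`, the assumptions behind them, the parameters that matter, what
the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## The calling model

### Data model

The unit of data is a binary embryo × anatomy matrix: one row per surviving
embryo of a construct's injections, one 0/1 column per scored anatomy, plus
an injection-batch label per embryo. Denominators are always *surviving*
embryos, not expressing embryos; embryos scored with no expression anywhere
are retained as all-zero rows. Scoring transcripts (the text output of
voice dictation) are parsed into this matrix: a delimiter token (default
`new`, configurable) opens each embryo's record and subsequent tokens name
anatomies by numeric code, canonical name or synonym. The code→anatomy
assignment is a package convention (codes 1–10 in the order the anatomies
are conventionally tabulated, forebrain → tail region) and is configurable
through a vocabulary TSV; within an embryo record token order is irrelevant
and repeated anatomies are idempotent.

### Dual significance criterion

An anatomy is called for a construct only when two tests both give
p ≤ α against the minimal-promoter control:

* **Proportion test.** One-sided two-sample binomial proportion test with
  Yates continuity correction, alternative "construct fraction greater".
  The statistic is the signed continuity-corrected pooled z; its square is
  the Yates chi-squared of the 2×2 table, so the two-sided variant is the
  familiar corrected chi-squared test. One-sidedness matters: a construct
  far *below* the control background correctly yields p ≈ 1. At exact
  equality of proportions the statistic is 0 and the one-sided p is 0.5;
  degenerate pooled proportions (all zeros or all ones) are handled the
  same way rather than erroring.
* **Partition rank-sum test.** The construct's embryos are shuffled and
  split into `n_partitions` = 5 near-equal groups (sizes differ by at most
  one; the first *n* mod 5 groups take the extra embryo), and each group's
  expressing fraction is computed; the control embryos are shuffled and
  partitioned identically, giving a 5-vs-5 comparison. Group fractions are
  compared with a one-sided rank-sum test and the p-value is averaged over
  `n_runs` = 3 independent shuffles. The control group count equals the
  construct group count by default for symmetry; both are configurable.
  This criterion demands that the construct's excess be robust to how the
  cohort is partitioned — signal concentrated in one injection round
  produces groups that straddle the control groups and a weak rank-sum.

Group fractions at these sample sizes are heavily tied, so the rank-sum
p-value is computed by **exact enumeration**: mid-ranks are assigned to the
pooled 10 values and the rank-sum null is enumerated over all C(10,5) = 252
splits of the observed (tied) rank vector, counting splits with rank-sum ≥
observed (a 1e-9 slack absorbs floating-point rank sums). Enumeration is
used up to 16 pooled observations; beyond that the tie-corrected normal
approximation of `scipy.stats.mannwhitneyu` takes over. The exact path
removes all approximation ambiguity from the calling rule: its minimum
attainable one-sided p for 5-vs-5 is 1/252 ≈ 0.004.

Because the conjunction of two level-α tests cannot exceed the level of
either, the dual rule is conservative: simulated under a global null at the
control rates (construct n = 120, control n = 161) its per-anatomy false
-call rate at α = 0.05 is about 0.02 (each criterion alone sits at
0.03–0.04, reflecting the discreteness of both tests). At the effect sizes
seen in practice (e.g. 0.60 vs 0.16 expressing fraction at n = 53/161) the
rule recovers the planted anatomy essentially always.

### Randomness and reproducibility

Every stochastic step draws from a `numpy.random.SeedSequence` substream
keyed by (pipeline seed, construct-id CRC, anatomy column, run index), so a
study rerun with the same config is byte-identical, results do not depend
on the order constructs are processed, and per-anatomy streams are
independent. The binary activity column is sorted before the seeded
shuffle — embryos within a cohort are exchangeable, so this is
distributionally null but makes the statistic exactly invariant to embryo
input order at a fixed seed.

### Classification

A construct is classified from its calls and its whole-embryo expressing
fraction (share of embryos with ≥ 1 active anatomy): **none** below
`none_threshold` = 0.05, otherwise **significant** with ≥ 1 called anatomy
or **weak** with none; significant constructs are **specific** with
≤ `specific_max` = 4 called anatomies, else **nonspecific**. The 5%
floor replaces a visual "clear expression" judgement with an explicit
threshold; it is deliberately exposed rather than hard-coded. Fold ratios
p̂₁/p̂₀ accompany called anatomies (undefined where the control fraction is
0) and are displayed rounded half-up to one decimal.

### Count reconstruction

Published summary tables print expressing *fractions*, not counts. The
reconstructor inverts a printed 4-decimal proportion to the nearest integer
count k = round(p̂·n) and flags cells where no integer reproduces the print
to 4 decimals (|k/n − p̂| ≥ 5·10⁻⁵). Construct columns invert exactly;
control columns in such tables may not (they are consistent with fractions
averaged over injection rounds before printing), which is why the flag
exists instead of an error.

## Concurrency statistic

For an anatomy pair, embryos are tabulated into joint patterns 00/01/10/11
and compared to a null of equal pattern probabilities:
z = (N₁₁ − 0.25N)/√(0.1875·N), with a one-sided upper-tail normal p
(co-activity enrichment only; avoidance is not tested) and a z > 3
highlight threshold. All 45 pairs of the 10-anatomy vocabulary are
evaluated by default regardless of per-anatomy significance (an option
restricts to called anatomies), without multiple-testing correction (a
Bonferroni option exists, off by default).

This statistic is a *descriptive screen*, not a calibrated independence
test: under the stated four-equal-patterns null the p < 0.05 flag rate
converges to nominal (≈ 0.047 at N = 400), but under independence with
marginals far from 0.5 it is badly miscalibrated — two independent
Bernoulli(0.9) anatomies give z ≫ 3. A regression test asserts this known
behaviour so it cannot be "fixed" silently; users should read large z as
"joint activity far above the equal-patterns baseline", not as evidence
against independence.

## Annotation overlap

Each scored anatomy maps to one or more ontology seed terms; the match set
is the seeds plus their **immediate children only** (one sub-level, never
grandchildren), absorbing resolution differences in curated annotations
(e.g. a record on a forebrain subdivision matches a forebrain call). A gene
matches an anatomy when it has ≥ 1 record whose term is in the expanded set
and whose stage span intersects the scoring window; stage order is an
explicit configurable list of named stages and intersection is
closed-interval on that order. The default window covers 22–30 hpf (late
segmentation to mid-pharyngula). A probe-quality filter (records with
quality ≥ 3) is available but off by default — it belongs to gene-set
construction for the chromatin analyses, not to the overlap comparison.
Genes absent from the annotation table are "no data" and leave the
denominator rather than counting as mismatches.

The permutation null replaces each construct's host gene with genes drawn
uniformly **without replacement within an iteration** (distinct genes per
iteration; iterations independent) from the table minus host, neighbour
and miRNA-type exclusions, counting constructs with ≥ 1 matched anatomy;
100 iterations of 20 genes give the reported mean ± sample sd. When
matches are iid across genes with probability q the count is
Binomial(20, q): at q = 0.18 the null reproduces mean 3.6, sd ≈ 1.72,
which the simulation recovers within Monte-Carlo error. Host-vs-neighbour
comparisons use the same two-proportion machinery, two-sided by default.

## Sequence conservation

Percent identity is computed over alignment columns where neither sequence
has a gap; columns containing N in either sequence are also excluded from
the denominator (ambiguity is not divergence) and matching is
case-insensitive. Columns gapped in both sequences are tolerated and
uninformative.

A third codon position qualifies as an aligned four-fold degenerate site
iff both sequences carry gap-free, N-free codons at the same in-frame
alignment columns **and the two codons agree at positions 1–2 with that
prefix belonging to a four-fold family** (GC, GG, CC, AC, GT, CT, TC, CG —
derived from, and tested against, the standard genetic code). Requiring
prefix identity guarantees the third position is synonymous in both
species; without it the site's degeneracy class could differ between the
two codons. The conserved-site fraction over qualifying positions is
reported only when ≥ 5 codons qualify; below that the statistic is
undefined — a flagged value, not an error. Frame is carried as the codon
phase of the first ungapped base (`frame_offset` ∈ {0,1,2}); whole-codon
gap-freedom is required rather than third-position-only.

Candidate exon filtering for testability: identity > 0.60, length in the
closed interval [100, 1000] bp, no XhoI (CTCGAG) or BglII (AGATCT) site in
the unaligned exon (both sites are reverse-complement palindromes, so a
forward-strand scan is complete), and a developmental-gene flag; all
violated criteria are reported, not just the first.

## Interval analyses

Coordinates are BED-style 0-based half-open throughout; overlap means
shared chromosome and ≥ 1 shared base (abutting intervals never overlap);
strand is ignored. Feature-level and gene-level marked fractions
(a gene counts once if any exon overlaps any peak) are reported as
k/n ± √(p̂(1−p̂)/n), the plug-in binomial standard error with n (not n−1).
TFBS-cluster "full coverage" requires a **single** cluster with score ≥ 500
to contain the exon boundary-inclusively — a union of partial clusters
does not count (configurable). Exon preprocessing for peak overlap:
exact duplicate records collapse to one retained copy, records overlapping
another distinct record are removed entirely, and exons < 3 bp or
> 16 kbp are dropped. EST adjacency around a region counts ESTs
intersecting the ±1 kb window but not completely spanning it (a spanning
transcript is not evidence of one *beginning* adjacent to the region).
Size-matched intronic controls pick a hosting intron uniformly among those
long enough, then a uniform start; drawn per target length (per-exon
matching, not distribution matching).

All tree-backed overlap operations are verified against a brute-force
all-pairs oracle on random fixtures.

## Synthetic data: what it emulates, and what it does not

The generators stand in for the study's raw inputs with known ground truth:

* **Embryo cohorts** — independent per-anatomy Bernoulli bits at specified
  rates (presets copy the published per-anatomy fractions, e.g. the
  161-embryo control across 4 injection rounds), batch effects applied on
  the odds scale (probabilities stay in range), and pairwise co-activity
  injected by OR-ing a shared latent Bernoulli(boost) into both anatomies.
  The joint law is closed-form — P(11) = boost + (1−boost)p_a p_b — so
  concurrency behaviour is analytically checkable. Not emulated: spatial
  structure within an embryo, scorer error, batch effects correlated
  across anatomies, or overdispersion beyond the batch mechanism; passing
  tests therefore certify the statistics under independence-plus-batch
  sampling, not robustness to scorer behaviour.
* **Transcripts** — rendered from a matrix with optional noise consisting
  of unrecognized filler tokens and synonym substitutions; clean
  transcripts round-trip exactly, and noised ones parse identically under
  the skip policy (the noise model stresses the parser, not the scoring).
* **Annotations** — a two/three-level ontology per anatomy, gene records
  annotated to each anatomy's term neighbourhood independently with a
  specified match probability (using seeds or children, so one-level
  expansion is exercised), out-of-window and background-term decoys, and
  deterministic planted matches for designated genes. Real curated data
  has correlated anatomies per gene and heterogeneous per-gene record
  counts; the iid structure is what makes the binomial closed form an
  exact oracle for the permutation null.
* **CDS pairs** — in-frame codon pairs with divergence placed per site
  class (four-fold third positions at a target identity; two-fold third
  positions diverging silently; prefix divergence only on non-qualifying
  codons, so the ground-truth count of qualifying sites is exact),
  whole-codon gaps. No realistic substitution process, codon usage or
  indel model is attempted.
* **Interval fixtures** — features in disjoint slots with a planted
  fraction receiving one overlapping peak and all other peaks in reserved
  empty slots, so expected overlap counts are exact by construction.

Every generator is byte-deterministic under its seed.

## Default parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `alpha` | 0.05 | level applied to both calling criteria |
| `n_partitions` | 5 | embryo groups per cohort in the rank-sum criterion |
| `n_runs` | 3 | shuffling runs averaged into the rank-sum p |
| `none_threshold` | 0.05 | whole-embryo fraction below which a construct is inactive |
| `specific_max` | 4 | most called anatomies still "anatomy-specific" |
| highlight z | 3 | concurrency highlight threshold |
| `min_score` | 500 | TFBS cluster score floor (of 1000) |
| `min_codons` | 5 | qualifying codons required for the 4-fold statistic |
| identity / length bounds | 0.60 / [100, 1000] bp | candidate exon filter |
| `flank` | 1000 bp | EST adjacency window |
| null size | 100 × 20 | permutation-null iterations × genes |

## Problem sizes used in verification

Simulation-based checks use: 1000 replicates for null calibration of the
dual rule (construct n = 120 vs control n = 161 at the control rates), 200
seeds for planted-effect recovery (n = 53/161), 2000 replicates at
N = 400 for concurrency flag-rate calibration, 100 random interval
fixtures (up to 2000 intervals) for oracle equivalence, 50 seeded
200-codon alignments for conservation recovery, and 100-iteration
permutation nulls over a 2000-gene simulated annotation pool.

## Known limitations

* The calling rule's two criteria are dependent (both consume the same
  counts); the conjunction is conservative rather than exactly level-α.
* The rank-sum criterion's run-averaged p-value is a heuristic summary,
  not a p-value with uniform null distribution; its calibration is
  established by simulation, not theory.
* The concurrency z is miscalibrated away from 0.25-ish marginals (see
  above) and is reported uncorrected across 45 pairs.
* Ontology expansion is exactly one level; deeply nested curation
  practices would need a depth parameter.
* Printed control-column proportions need not invert to integer counts
  (round-averaged before printing); reconstruction flags such cells.
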