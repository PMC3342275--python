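# exonhancer

Statistics for calling transcriptional **enhancer activity in conserved
protein-coding exons** from zebrafish GFP reporter screens.

In a transient Tol2 reporter assay, a candidate sequence is cloned upstream
of an E1B minimal promoter driving EGFP, injected into 1-cell zebrafish
embryos, and each surviving embryo is scored at 22–30 hpf for GFP in ten
anatomical regions (forebrain, midbrain/hindbrain, eye, ear, heart,
notochord, yolk, mid-trunk, muscle, tail). Transient transgenesis is mosaic,
so hundreds of embryos are scored per construct — in practice by dictating
anatomy codes into a voice-recognition app — and enhancer activity must be
separated statistically from the minimal-promoter background. This package
implements that pipeline for analysts running such screens: transcript
ingest, per-anatomy enhancer calling, co-activity statistics, overlap of
activity with curated gene-expression annotations, sequence-conservation
metrics, and ChIP-peak/exon overlap summaries, with seeded synthetic-data
generators for every input.

## The statistics

For construct *c* versus the promoter-only control, each anatomy *a* is
tested twice, and called **significant** only when both criteria give
*p* ≤ α (default 0.05):

1. **Proportion criterion.** One-sided two-sample proportion test with
   continuity correction on the expressing fractions
   p̂₁ = k₁/n₁ (construct) vs p̂₀ = k₀/n₀ (control), alternative p₁ > p₀
   (`prop.test` semantics; the squared statistic is the Yates-corrected
   chi-squared of the 2×2 table).
2. **Partition rank-sum criterion.** The construct's embryos are shuffled
   and split into 5 near-equal groups; the control's embryos likewise; the
   5-vs-5 group expressing-fractions are compared with a one-sided exact
   rank-sum test (mid-ranks, full enumeration of the 252 splits), and the
   p-value is averaged over 3 independent shuffling runs. This criterion
   penalises signal carried by a single injection batch.

Called anatomies get a fold ratio p̂₁/p̂₀. A construct is classified
**none** (< 5% of embryos express anywhere), **significant** (≥ 1 called
anatomy) or **weak**; significant constructs are **specific** when they
have ≤ 4 called anatomies.

Concurrent activity of an anatomy pair is measured per embryo against a
null of equal probability for the four joint patterns 00/01/10/11:

    z = (N₁₁ − 0.25·N) / √(N·0.25·0.75),  p = upper normal tail,

with pairs at z > 3 highlighted. Downstream analyses match called
anatomies against annotation records (ontology seed terms plus their
immediate children, stage window intersection), compare host genes to
neighbours and to a 100×20 random-gene permutation null, compute gap-free
percent identity and the conserved fraction at aligned four-fold degenerate
third codon positions (≥ 5 qualifying codons required), and summarise
peak/exon interval overlap with binomial standard errors √(p̂(1−p̂)/n).

## Worked example

Simulate a cohort at the published per-anatomy rates of one construct
(53 embryos, two injection batches) and the 161-embryo control, then fit
the calling model:

```python
from exonhancer import EnhancerActivityModel, simulate_embryos, table1_spec

cce, _ = simulate_embryos(table1_spec("rab11fip4a", seed=8))
control, _ = simulate_embryos(table1_spec("control", seed=8))
res = EnhancerActivityModel(cce, control).fit(seed=8)
print(res.summary())
```

```
Enhancer Activity Results
==========================================================================
Construct: rab11fip4a                   Control: control
Embryos scored: 53                      Control embryos: 161
alpha: 0.05   partitions: 5   runs: 3   seed: 8
--------------------------------------------------------------------------
                    p_cce  p_control  p_prop  p_ranksum significant ratio
anatomy
Forebrain          0.3585     0.3540  0.5000     0.6931
Midbrain/Hindbrain 0.2453     0.2795  0.6210     0.7116
Eye                0.1698     0.1304  0.3127     0.2976
Ear/AboveHeart     0.0189     0.0559  0.7682     0.9458
Heart              0.3019     0.3478  0.6723     0.6839
Notochord          0.5283     0.1366  0.0000     0.0053           X   3.9
Yolk/YolkExtension 0.1509     0.1988  0.7161     0.8757
MidTrunk/AboveYolk 0.1887     0.1304  0.2061     0.1878
Muscle             0.1698     0.1615  0.5000     0.5013
TailRegion         0.1887     0.1242  0.1725     0.2196
--------------------------------------------------------------------------
Whole-embryo expressing fraction: 0.925
Activity class: significant   Specificity: specific
Significant anatomies: Notochord
```

The construct expresses in 52.8% of embryos in the notochord against a
13.7% control background; both criteria reject (p_prop < 10⁻⁴, mean
rank-sum p = 0.0053), so notochord is called with a 3.9× fold ratio — the
published analysis of the real cohort at these rates calls the same single
anatomy at 3.8×. All other anatomies track the control and are rejected.
`res.concurrency()` returns the 45 pairwise co-activity z-scores, and
`exonhancer run --config study.yaml` orchestrates many constructs at once
(see `exonhancer --help` for all subcommands).

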