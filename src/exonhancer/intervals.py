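"""Interval arithmetic and binomial proportion summaries for peak/exon analyses.

All coordinates are BED-style 0-based half-open; strand is ignored for
overlap (two intervals overlap iff they share a chromosome and at least one
base, i.e. ``max(starts) < min(ends)``, so abutting intervals never overlap).
Fractions are reported with the plug-in binomial standard error
``sqrt(p(1-p)/n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .calling import proportions_test

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = ""
    score: int | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and max(self.start, other.start) < min(self.end, other.end)

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


class IntervalSet:
    """Named collection of genomic intervals, queryable per chromosome."""

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "") -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals sharing >=1 bp with ``iv``."""
        return [hit.data for hit in self._tree(iv.chrom).overlap(iv.start, iv.end)]

    def any_overlap(self, iv: GenomicInterval) -> bool:
        return bool(self._tree(iv.chrom).overlaps(iv.start, iv.end))

    @classmethod
    def from_bed(cls, path: str | Path, label: str = "") -> "IntervalSet":
        """Read BED3/BED6 (TSV, no header). Score column '.' maps to None."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 3:
            raise ValueError("BED file needs at least 3 columns")
        df.columns = list(BED_COLUMNS[: df.shape[1]])
        ivs = []
        for row in df.itertuples(index=False):
            score = getattr(row, "score", None)
            score = None if score in (None, ".", "") or pd.isna(score) else int(float(score))
            ivs.append(
                GenomicInterval(
                    row.chrom,
                    int(row.start),
                    int(row.end),
                    name=str(getattr(row, "name", "") or ""),
                    score=score,
                    strand=str(getattr(row, "strand", ".") or "."),
                )
            )
        return cls(ivs, label=label or Path(path).stem)

    def to_bed(self, path: str | Path) -> None:
        rows = [
            (iv.chrom, iv.start, iv.end, iv.name or ".", "." if iv.score is None else iv.score, iv.strand)
            for iv in self.intervals
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class ProportionSummary:
    """k successes out of n with the binomial standard error of the fraction."""

    k: int
    n: int
    fraction: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"invalid counts k={self.k}, n={self.n}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "fraction", self.k / self.n)
        object.__setattr__(self, "sem", binomial_sem(self.k, self.n))

    def __str__(self) -> str:
        return f"{self.k}/{self.n} ({100 * self.fraction:.1f}%±{100 * self.sem:.1f}% s.e.m.)"


def binomial_sem(k: int, n: int) -> float:
    """Standard error of a binomial mean: sqrt((k/n)(1-k/n)/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"invalid count k={k} for n={n}")
    p = k / n
    return math.sqrt(p * (1.0 - p) / n)


def intersect_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """For each interval of ``a``, whether it overlaps >=1 bp of any interval of ``b``."""
    return np.array([b.any_overlap(iv) for iv in a.intervals], dtype=bool)


def marked_fraction(features: IntervalSet, peaks: IntervalSet) -> ProportionSummary:
    """Fraction of features overlapping at least one peak, with s.e.m."""
    if len(features) == 0:
        raise ValueError("empty feature set")
    flags = intersect_any(features, peaks)
    return ProportionSummary(int(flags.sum()), len(features))


def genes_with_marked_exon(
    gene_exons: Mapping[str, Sequence[GenomicInterval]] | IntervalSet, peaks: IntervalSet
) -> ProportionSummary:
    """Per-gene summary: a gene counts once iff any of its exons overlaps a peak.

    Accepts either a mapping gene id -> exon intervals, or an IntervalSet
    whose interval names carry the gene id.
    """
    if isinstance(gene_exons, IntervalSet):
        grouped: dict[str, list[GenomicInterval]] = {}
        for iv in gene_exons:
            if not iv.name:
                raise ValueError("gene-exon BED requires gene ids in the name field")
            grouped.setdefault(iv.name, []).append(iv)
        gene_exons = grouped
    if not gene_exons:
        raise ValueError("no genes supplied")
    k = sum(1 for exons in gene_exons.values() if any(peaks.any_overlap(e) for e in exons))
    return ProportionSummary(k, len(gene_exons))


def intronic_controls(
    introns: IntervalSet, target_lengths: Sequence[int], seed: int = 0
) -> IntervalSet:
    """Size-matched control regions placed uniformly at random within introns.

    For each target length a hosting intron is chosen uniformly among
    introns long enough, then the start is uniform over the valid range.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0x1C,)))
    lengths = np.array([iv.length for iv in introns.intervals])
    out = []
    for i, L in enumerate(target_lengths):
        if L < 1:
            raise ValueError(f"target length must be positive, got {L}")
        eligible = np.flatnonzero(lengths >= L)
        if eligible.size == 0:
            raise ValueError(f"no intron long enough for target length {L}")
        host = introns.intervals[int(rng.choice(eligible))]
        start = int(rng.integers(host.start, host.end - L + 1))
        out.append(GenomicInterval(host.chrom, start, start + L, name=f"control_{i}"))
    return IntervalSet(out, label="intronic_controls")


def tfbs_full_coverage(
    exons: IntervalSet, clusters: IntervalSet, min_score: int = 500
) -> ProportionSummary:
    """Exons fully contained in a single TFBS cluster of score >= min_score.

    Containment is boundary-inclusive; a union of weaker/partial clusters
    does not count.
    """
    if len(exons) == 0:
        raise ValueError("empty exon set")
    k = 0
    for exon in exons:
        for cl in clusters.overlapping(exon):
            if cl.score is not None and cl.score >= min_score and cl.contains(exon):
                k += 1
                break
    return ProportionSummary(k, len(exons))


def preprocess_ccds_exons(exons: IntervalSet, min_len: int = 3, max_len: int = 16000) -> IntervalSet:
    """Clean a CCDS exon annotation set before peak overlap.

    Exact duplicate records collapse to a single retained copy; records that
    (after collapsing) overlap another distinct record are removed entirely;
    exons shorter than ``min_len`` or longer than ``max_len`` are dropped.
    """
    seen: dict[tuple, GenomicInterval] = {}
    for iv in exons:
        seen.setdefault((iv.chrom, iv.start, iv.end), iv)
    unique = list(seen.values())
    uniq_set = IntervalSet(unique)
    retained = []
    for iv in unique:
        others = [o for o in uniq_set.overlapping(iv) if o is not iv]
        if others:
            continue
        if min_len <= iv.length <= max_len:
            retained.append(iv)
    return IntervalSet(retained, label=exons.label + "_clean" if exons.label else "ccds_clean")


def p300_exon_overlap(peaks: IntervalSet, ccds_exons: IntervalSet) -> ProportionSummary:
    """Fraction of p300 peaks overlapping a retained CCDS coding exon."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    clean = preprocess_ccds_exons(ccds_exons)
    flags = intersect_any(peaks, clean)
    return ProportionSummary(int(flags.sum()), len(peaks))


def est_adjacency(region: GenomicInterval, ests: IntervalSet, flank: int = 1000) -> int:
    """ESTs intersecting — but not completely spanning — the flanked window.

    The window is ``[start - flank, end + flank)`` clipped at 0. An EST that
    fully contains the window is excluded (it is not evidence of a transcript
    *beginning* adjacent to the region).
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    win = GenomicInterval(region.chrom, max(0, region.start - flank), region.end + flank)
    count = 0
    for est in ests.overlapping(win):
        if not est.contains(win):
            count += 1
    return count


def two_proportion_compare(k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided") -> float:
    """Continuity-corrected two-proportion comparison (two-sided by default)."""
    return proportions_test(k1, n1, k2, n2, alternative=alternative)
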