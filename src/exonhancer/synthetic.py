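"""Synthetic data with known ground truth for every pipeline input.

The study's raw inputs — embryo scoring transcripts, curated expression
annotations, CDS alignments, peak/exon interval sets — are emulated here by
seeded generators that return the generated artifact together with the
ground truth needed to compute expected pipeline outputs exactly or within
a stated Monte-Carlo tolerance. Every generator is deterministic under its
seed.

Embryo cohorts are drawn per anatomy as independent Bernoulli bits, with
injection-batch effects applied on the odds scale (so probabilities stay in
range) and optional pairwise co-activity injected through a shared latent
Bernoulli indicator OR'd into both anatomies — a construction whose joint
law is closed-form, making the concurrency statistic analytically
checkable: P(11) = boost + (1 - boost) * p_a * p_b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .annotation import (
    DEFAULT_STAGES,
    DEFAULT_WINDOW,
    AnnotationTable,
    Ontology,
    StageOrder,
    StageWindow,
)
from .conservation import FOURFOLD_PREFIXES, AlignedCdsPair
from .intervals import GenomicInterval, IntervalSet
from .matrix import ExpressionMatrix
from .vocab import DEFAULT_VOCABULARY, AnatomyVocabulary


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


# ---------------------------------------------------------------------------
# embryo cohorts
# ---------------------------------------------------------------------------

@dataclass
class EmbryoSimSpec:
    """Generative spec for one construct's embryo cohort."""

    n_embryos: int
    anatomy_probs: Sequence[float]
    construct_id: str = "sim"
    batch_effects: Mapping[str, float] = field(default_factory=lambda: {"b1": 1.0, "b2": 1.0})
    coactive_pairs: Sequence[tuple[int | str, int | str, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.anatomy_probs, dtype=float)
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("anatomy_probs must lie in [0, 1]")
        for _, _, boost in self.coactive_pairs:
            if not 0 <= boost <= 1:
                raise ValueError("joint_boost must lie in [0, 1]")
        if any(m < 0 for m in self.batch_effects.values()):
            raise ValueError("batch odds shifts must be nonnegative")


def _odds_shift(p: np.ndarray, mult: float) -> np.ndarray:
    out = np.where((p > 0) & (p < 1), (p * mult) / (1 - p + p * mult), p)
    return out


def simulate_embryos(
    spec: EmbryoSimSpec, vocabulary: AnatomyVocabulary = DEFAULT_VOCABULARY
) -> tuple[ExpressionMatrix, dict]:
    """Draw a binary embryo x anatomy matrix plus its ground truth.

    Embryos are split near-equally across the declared batches (in key
    order); each batch's activity probabilities are the base probabilities
    odds-shifted by the batch effect; co-active pairs then OR a shared
    latent Bernoulli(boost) bit into both member anatomies.
    """
    probs = np.asarray(spec.anatomy_probs, dtype=float)
    if len(probs) != vocabulary.size:
        raise ValueError("anatomy_probs length must equal vocabulary size")
    batches = list(spec.batch_effects)
    sizes = np.full(len(batches), spec.n_embryos // len(batches), dtype=int)
    sizes[: spec.n_embryos % len(batches)] += 1
    rng = _rng(spec.seed, 0xE0)
    rows, batch_ids = [], []
    batch_probs = {}
    pair_idx = [
        (vocabulary.index(a), vocabulary.index(b), boost) for a, b, boost in spec.coactive_pairs
    ]
    for batch, size in zip(batches, sizes):
        p = _odds_shift(probs, spec.batch_effects[batch])
        batch_probs[batch] = p
        bits = (rng.random((size, vocabulary.size)) < p).astype(np.uint8)
        for ia, ib, boost in pair_idx:
            latent = rng.random(size) < boost
            bits[latent, ia] = 1
            bits[latent, ib] = 1
        rows.append(bits)
        batch_ids.extend([batch] * size)
    data = np.concatenate(rows) if rows else np.empty((0, vocabulary.size), dtype=np.uint8)
    matrix = ExpressionMatrix(spec.construct_id, data, vocabulary, batch_ids=batch_ids)
    # expected marginals after batch shifts and co-activity boosts
    marginal = np.zeros(vocabulary.size)
    for batch, size in zip(batches, sizes):
        p = batch_probs[batch].copy()
        for ia, ib, boost in pair_idx:
            p[ia] = boost + (1 - boost) * p[ia]
            p[ib] = boost + (1 - boost) * p[ib]
        marginal += (size / max(spec.n_embryos, 1)) * p
    truth = {
        "marginal_probs": marginal,
        "batch_probs": batch_probs,
        "coactive_pairs": [
            (vocabulary.names[ia], vocabulary.names[ib], boost) for ia, ib, boost in pair_idx
        ],
        "expected_joint11": {
            (vocabulary.names[ia], vocabulary.names[ib]): float(
                np.mean(
                    [
                        boost + (1 - boost) * batch_probs[b][ia] * batch_probs[b][ib]
                        for b in batches
                    ]
                )
            )
            for ia, ib, boost in pair_idx
        },
    }
    return matrix, truth


def table1_spec(construct: str, seed: int = 0) -> EmbryoSimSpec:
    """Preset cohort spec with probabilities copied from the bundled example
    expression table (``"control"`` or one of its construct columns)."""
    if construct == "control":
        col, n = datasets.CONTROL_PROPORTIONS, datasets.CONTROL_N
        batches = {f"r{i}": 1.0 for i in range(1, 5)}  # 4 control injection rounds
    else:
        entry = datasets.CCES[construct]
        col, n = entry["proportions"], entry["n"]
        batches = {"b1": 1.0, "b2": 1.0}
    probs = [col[a] for a in datasets.ANATOMIES]
    return EmbryoSimSpec(
        n_embryos=n, anatomy_probs=probs, construct_id=construct, batch_effects=batches, seed=seed
    )


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

_JUNK_TOKENS = ("um", "uh", "nudge", "blip", "7up")


def render_transcript(
    matrix: ExpressionMatrix,
    vocab: AnatomyVocabulary | None = None,
    noise_rate: float = 0.0,
    seed: int = 0,
    delimiter: str = "new",
) -> str:
    """Render a matrix as a controlled-vocabulary scoring transcript.

    With ``noise_rate`` 0 the transcript parses back to the input matrix
    exactly. Noise injects parser hazards that leave the scored content
    intact: unrecognized filler tokens (ignored under the "skip" policy)
    and synonym substitutions for anatomy tokens.
    """
    vocab = vocab or matrix.vocabulary
    rng = _rng(seed, 0x7A)
    parts: list[str] = []
    for row in matrix.data:
        parts.append(delimiter)
        for code0 in np.flatnonzero(row):
            token = str(code0 + 1)
            if noise_rate and rng.random() < noise_rate:
                syns = sorted(vocab.entries[code0].synonyms)
                if syns:
                    token = syns[int(rng.integers(len(syns)))]
            parts.append(token)
            if noise_rate and rng.random() < noise_rate:
                parts.append(_JUNK_TOKENS[int(rng.integers(len(_JUNK_TOKENS)))])
    return " ".join(parts)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSimSpec:
    """Generative spec for an ontology + wildtype-expression annotation table."""

    n_genes: int = 300
    children_per_term: int = 3
    ontology_depth: int = 2  # 1: seeds only, 2: + children, 3: + grandchildren
    match_prob: float = 0.18  # per (gene, anatomy) in-window annotation probability
    out_of_window_rate: float = 0.2
    background_records_per_gene: int = 1
    anatomies: Sequence[str] = DEFAULT_VOCABULARY.names
    stages: Sequence[str] = DEFAULT_STAGES
    window: StageWindow = DEFAULT_WINDOW
    planted: Mapping[str, Iterable[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.match_prob <= 1:
            raise ValueError("match_prob must lie in [0, 1]")
        if self.ontology_depth not in (1, 2, 3):
            raise ValueError("ontology_depth must be 1, 2 or 3")


def simulate_annotations(
    spec: AnnotationSimSpec,
) -> tuple[Ontology, AnnotationTable, dict[str, frozenset[str]], dict]:
    """Random ontology, annotation table and anatomy map with planted matches.

    Each simulated gene is annotated to each anatomy's term neighbourhood
    independently with probability ``match_prob``, using either the seed
    term or one of its children (so matches exercise the one-level
    expansion), with a stage span inside the scoring window. Out-of-window
    and background-term records are decoys. ``spec.planted`` maps gene ids
    to anatomies annotated with certainty; planted genes always receive at
    least a background record so they count as having data.

    Returns ``(ontology, table, anatomy_map, truth)`` where truth maps each
    gene to the set of anatomies it genuinely matches in-window.
    """
    rng = _rng(spec.seed, 0xA1)
    stages = StageOrder(spec.stages)
    terms: dict[str, str] = {}
    parents: dict[str, list[str]] = {}
    amap: dict[str, frozenset[str]] = {}
    match_terms: dict[str, list[str]] = {}
    for i, anatomy in enumerate(spec.anatomies):
        seed_term = f"ZFA:S{i:02d}"
        terms[seed_term] = anatomy
        amap[anatomy] = frozenset({seed_term})
        pool = [seed_term]
        if spec.ontology_depth >= 2:
            for j in range(spec.children_per_term):
                child = f"{seed_term}C{j}"
                terms[child] = f"{anatomy} subregion {j}"
                parents[child] = [seed_term]
                pool.append(child)
                if spec.ontology_depth >= 3:
                    grand = f"{child}G0"
                    terms[grand] = f"{anatomy} sub-subregion {j}"
                    parents[grand] = [child]
        match_terms[anatomy] = pool
    background = [f"ZFA:BG{j:02d}" for j in range(8)]
    for j, term in enumerate(background):
        terms[term] = f"background structure {j}"
    ontology = Ontology(terms, parents)

    win_lo = stages.index(spec.window.start_stage)
    win_hi = stages.index(spec.window.end_stage)
    n_stages = len(stages.stages)
    records = []
    truth: dict[str, set[str]] = {}

    def in_window_span() -> tuple[str, str]:
        s = int(rng.integers(max(0, win_lo - 2), win_hi + 1))
        e = int(rng.integers(max(s, win_lo), min(n_stages, win_hi + 3)))
        return stages.stages[s], stages.stages[e]

    def after_window_span() -> tuple[str, str]:
        if win_hi + 1 >= n_stages:
            raise ValueError("no stage after the window to place decoys")
        s = int(rng.integers(win_hi + 1, n_stages))
        return stages.stages[s], stages.stages[int(rng.integers(s, n_stages))]

    def add(gene: str, term: str, span: tuple[str, str]) -> None:
        records.append(
            (gene, term, span[0], span[1], "mRNA in situ hybridization", int(rng.integers(1, 6)))
        )

    for g in range(spec.n_genes):
        gene = f"gene{g:04d}"
        truth.setdefault(gene, set())
        for anatomy in spec.anatomies:
            if rng.random() < spec.match_prob:
                term = match_terms[anatomy][int(rng.integers(len(match_terms[anatomy])))]
                add(gene, term, in_window_span())
                truth[gene].add(anatomy)
            elif spec.out_of_window_rate and rng.random() < spec.out_of_window_rate:
                term = match_terms[anatomy][int(rng.integers(len(match_terms[anatomy])))]
                add(gene, term, after_window_span())
        for _ in range(spec.background_records_per_gene):
            add(gene, background[int(rng.integers(len(background)))], in_window_span())
    for gene, anatomies in spec.planted.items():
        truth.setdefault(gene, set())
        add(gene, background[0], in_window_span())
        for anatomy in anatomies:
            term = match_terms[anatomy][int(rng.integers(len(match_terms[anatomy])))]
            add(gene, term, in_window_span())
            truth[gene].add(anatomy)
    table = AnnotationTable(
        pd.DataFrame(
            records,
            columns=["gene_id", "term_id", "start_stage", "end_stage", "assay", "probe_quality"],
        ),
        stages,
    )
    return ontology, table, amap, {g: frozenset(v) for g, v in truth.items()}


# ---------------------------------------------------------------------------
# aligned CDS pairs
# ---------------------------------------------------------------------------

_TWOFOLD_PREFIXES = ("TT", "AA", "GA", "CA")  # third-position purine keeps the amino acid
_BASES = "ACGT"


@dataclass
class SequenceSimSpec:
    """Generative spec for an in-frame aligned CDS pair."""

    n_codons: int = 200
    fourfold_fraction: float = 0.5
    identity_fourfold: float = 0.5  # conservation at qualifying third positions
    identity_twofold: float = 0.9  # silent purine swaps at 2-fold third positions
    identity_prefix: float = 0.98  # prefix divergence on non-4-fold codons only
    gap_rate: float = 0.0  # whole-codon gaps, alternating sequences
    frame_offset: int = 0
    seed: int = 0


def simulate_cds_pair(spec: SequenceSimSpec) -> tuple[AlignedCdsPair, dict]:
    """Generate an aligned codon pair with mutations placed per site class.

    Four-fold codons keep their prefix identical across species (so the
    ground-truth count of qualifying codons is exact) and diverge at the
    third position with probability ``1 - identity_fourfold``. Two-fold
    codons diverge silently (purine swap) with ``1 - identity_twofold`` and
    nonsynonymously at the prefix with ``1 - identity_prefix``; they never
    qualify as four-fold sites. Gaps remove whole codons from one sequence.
    """
    prefixes4 = sorted(FOURFOLD_PREFIXES)
    rng = _rng(spec.seed, 0xCD)
    cols_a: list[str] = []
    cols_b: list[str] = []
    n4 = conserved4 = 0
    lead = "".join(rng.choice(list(_BASES), size=spec.frame_offset))
    cols_a.append(lead)
    cols_b.append(lead)
    for c in range(spec.n_codons):
        fourfold = rng.random() < spec.fourfold_fraction
        if fourfold:
            prefix = prefixes4[int(rng.integers(len(prefixes4)))]
            third_a = _BASES[int(rng.integers(4))]
            prefix_b = prefix
            if rng.random() < spec.identity_fourfold:
                third_b = third_a
            else:
                others = [b for b in _BASES if b != third_a]
                third_b = others[int(rng.integers(3))]
        else:
            prefix = _TWOFOLD_PREFIXES[int(rng.integers(len(_TWOFOLD_PREFIXES)))]
            third_a = "AG"[int(rng.integers(2))]
            third_b = third_a if rng.random() < spec.identity_twofold else {"A": "G", "G": "A"}[third_a]
            prefix_b = prefix
            if rng.random() >= spec.identity_prefix:
                pos = int(rng.integers(2))
                repl = [b for b in _BASES if b != prefix[pos]][int(rng.integers(3))]
                prefix_b = prefix[:pos] + repl + prefix[pos + 1 :]
        codon_a, codon_b = prefix + third_a, prefix_b + third_b
        if spec.gap_rate and rng.random() < spec.gap_rate:
            if c % 2 == 0:
                codon_a = "---"
            else:
                codon_b = "---"
        else:
            if fourfold:
                n4 += 1
                conserved4 += third_a == third_b
        cols_a.append(codon_a)
        cols_b.append(codon_b)
    pair = AlignedCdsPair("".join(cols_a), "".join(cols_b), frame_offset=spec.frame_offset)
    truth = {
        "n_fourfold": n4,
        "fourfold_conserved_fraction": conserved4 / n4 if n4 else None,
        "target_identity_fourfold": spec.identity_fourfold,
    }
    return pair, truth


# ---------------------------------------------------------------------------
# interval fixtures
# ---------------------------------------------------------------------------

def simulate_intervals(
    n_features: int = 24,
    planted_fraction: float = 0.375,
    n_peaks: int | None = None,
    feature_length: int = 200,
    peak_length: int = 300,
    chrom: str = "chr1",
    spacing: int = 2000,
    seed: int = 0,
) -> tuple[IntervalSet, IntervalSet, dict]:
    """Feature and peak interval sets with a planted overlap fraction.

    Features occupy disjoint slots along the chromosome; a planted subset
    (``round(planted_fraction * n_features)``) receives one overlapping
    peak each; all remaining peaks are placed in reserved peak-only slots,
    guaranteed clear of every feature. Truth records the planted indices.
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in [0, 1]")
    rng = _rng(seed, 0xBE)
    n_planted = round(planted_fraction * n_features)
    n_peaks = n_peaks if n_peaks is not None else max(n_features, n_planted)
    if n_peaks < n_planted:
        raise ValueError("n_peaks smaller than the planted overlap count")
    slot = feature_length + peak_length + 2 * spacing
    features = []
    for i in range(n_features):
        start = i * slot + spacing + int(rng.integers(0, spacing // 2))
        features.append(GenomicInterval(chrom, start, start + feature_length, name=f"feat_{i}"))
    planted = sorted(rng.choice(n_features, size=n_planted, replace=False).tolist())
    peaks = []
    for j, i in enumerate(planted):
        f = features[i]
        # overlap of at least 1 bp: peak start uniform in a window straddling the feature
        lo, hi = f.start - peak_length + 1, f.end - 1
        start = int(rng.integers(lo, hi + 1))
        peaks.append(GenomicInterval(chrom, start, start + peak_length, name=f"peak_{j}"))
    decoy_base = n_features * slot + spacing
    for j in range(n_peaks - n_planted):
        start = decoy_base + j * slot + int(rng.integers(0, spacing // 2))
        peaks.append(GenomicInterval(chrom, start, start + peak_length, name=f"peak_d{j}"))
    truth = {"planted_indices": planted, "n_planted": n_planted}
    return (
        IntervalSet(features, label="features"),
        IntervalSet(peaks, label="peaks"),
        truth,
    )
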