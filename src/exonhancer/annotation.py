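"""Matching enhancer activity against gene expression annotations.

Emulates the comparison of reporter activity to curated wildtype expression
data: each scored anatomy maps to one or more anatomy-ontology terms, the
match set is expanded exactly one sub-level down the ontology (children of
the seed terms, never grandchildren), and a gene "matches" an anatomy when it
carries at least one annotation record whose term falls in the expanded set
and whose developmental-stage interval intersects the scoring window.

The permutation null replaces each construct's host gene with genes drawn at
random from the annotation table (hosts, neighbors and miRNA genes excluded)
and counts constructs with at least one matched anatomy, repeated over
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .calling import proportions_test

# An ordered ZFIN-like developmental staging series. The reporter scoring
# window (22-30 hpf) corresponds to late segmentation through mid pharyngula.
DEFAULT_STAGES: tuple[str, ...] = (
    "Zygote:1-cell",
    "Cleavage:2-cell",
    "Blastula:128-cell",
    "Blastula:Dome",
    "Gastrula:50%-epiboly",
    "Gastrula:Shield",
    "Gastrula:Bud",
    "Segmentation:1-4 somites",
    "Segmentation:5-9 somites",
    "Segmentation:10-13 somites",
    "Segmentation:14-19 somites",
    "Segmentation:20-25 somites",
    "Segmentation:26+ somites",
    "Pharyngula:Prim-5",
    "Pharyngula:Prim-15",
    "Pharyngula:Prim-25",
    "Hatching:Long-pec",
    "Hatching:Pec-fin",
    "Larval:Protruding-mouth",
    "Adult",
)

ANNOTATION_COLUMNS = ("gene_id", "term_id", "start_stage", "end_stage", "assay", "probe_quality")


@dataclass(frozen=True)
class StageWindow:
    """Closed interval of ordered stage labels."""

    start_stage: str
    end_stage: str


#: Scoring window for 22-30 hpf embryos.
DEFAULT_WINDOW = StageWindow("Segmentation:26+ somites", "Pharyngula:Prim-15")


class StageOrder:
    """Explicit ordered stage list; stage comparisons are index comparisons."""

    def __init__(self, stages: Sequence[str] = DEFAULT_STAGES) -> None:
        self.stages = tuple(stages)
        self._index = {s: i for i, s in enumerate(self.stages)}
        if len(self._index) != len(self.stages):
            raise ValueError("duplicate stage names")

    def index(self, stage: str) -> int:
        try:
            return self._index[stage]
        except KeyError:
            raise KeyError(f"unknown stage {stage!r}") from None

    def intersects(self, a: tuple[str, str], b: StageWindow) -> bool:
        """Closed-interval intersection of a record's stage span with a window."""
        s0, e0 = self.index(a[0]), self.index(a[1])
        s1, e1 = self.index(b.start_stage), self.index(b.end_stage)
        if s0 > e0 or s1 > e1:
            raise ValueError("stage interval start must not follow its end")
        return max(s0, s1) <= min(e0, e1)


class Ontology:
    """Anatomy term graph: term id, name, parent links (multiple allowed)."""

    def __init__(self, terms: Mapping[str, str], parents: Mapping[str, Iterable[str]]) -> None:
        self.graph = nx.DiGraph()
        for tid, name in terms.items():
            self.graph.add_node(tid, name=name)
        for tid, ps in parents.items():
            for p in ps:
                if p == tid:
                    raise ValueError(f"term {tid!r} is its own parent")
                if p not in terms or tid not in terms:
                    raise ValueError(f"parent link {p!r} -> {tid!r} references an unknown term")
                self.graph.add_edge(p, tid)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id]["name"]

    def children(self, term_id: str) -> frozenset[str]:
        """Immediate children only."""
        if term_id not in self.graph:
            raise KeyError(f"unknown term {term_id!r}")
        return frozenset(self.graph.successors(term_id))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Ontology":
        """Build from rows (term_id, name, parent_id); empty parent marks a root."""
        terms: dict[str, str] = {}
        parents: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            terms.setdefault(row.term_id, row.name)
            p = getattr(row, "parent_id", None)
            if isinstance(p, str) and p:
                parents.setdefault(row.term_id, set()).add(p)
        return cls(terms, parents)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Ontology":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls.from_frame(df)


def read_anatomy_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an anatomy -> seed-term map from TSV columns (anatomy, term_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.anatomy, set()).add(row.term_id)
    return {k: frozenset(v) for k, v in out.items()}


class AnnotationTable:
    """Gene -> anatomy-term -> stage-span expression records.

    Thin validated wrapper over a DataFrame with columns
    ``gene_id, term_id, start_stage, end_stage, assay, probe_quality``
    (probe_quality may be missing; when present it must be 1-5).
    """

    def __init__(self, records: pd.DataFrame, stages: StageOrder | None = None) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        self.stages = stages or StageOrder()
        for col in ("start_stage", "end_stage"):
            bad = set(records[col]) - set(self.stages.stages)
            if bad:
                raise ValueError(f"unknown stages in {col}: {sorted(bad)[:5]}")
        q = records["probe_quality"].dropna()
        if len(q) and not q.between(1, 5).all():
            raise ValueError("probe_quality must lie in [1, 5]")
        self.records = records.reset_index(drop=True)
        self._by_gene = dict(tuple(self.records.groupby("gene_id", sort=False)))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._by_gene)

    def records_for(self, gene_id: str) -> pd.DataFrame:
        return self._by_gene.get(gene_id, self.records.iloc[0:0])

    @classmethod
    def from_tsv(cls, path: str | Path, stages: StageOrder | None = None) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "term_id": str})
        return cls(df, stages)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def expand_terms(
    anatomy: str, anatomy_map: Mapping[str, frozenset[str]], ontology: Ontology
) -> frozenset[str]:
    """Seed terms for an anatomy plus their immediate children (one level only)."""
    if anatomy not in anatomy_map:
        raise KeyError(f"anatomy {anatomy!r} has no ontology mapping")
    seeds = anatomy_map[anatomy]
    out = set(seeds)
    for t in seeds:
        out |= ontology.children(t)
    return frozenset(out)


def gene_matches(
    anatomies: Iterable[str],
    gene_id: str,
    table: AnnotationTable,
    window: StageWindow,
    anatomy_map: Mapping[str, frozenset[str]],
    ontology: Ontology,
    min_probe_quality: int | None = None,
) -> frozenset[str]:
    """Anatomies of a call matched by a gene's annotation within the window.

    A gene absent from the table yields the empty set (callers should treat
    the gene as having no data, not as a mismatch).
    """
    recs = table.records_for(gene_id)
    if min_probe_quality is not None:
        recs = recs[recs["probe_quality"].notna() & (recs["probe_quality"] >= min_probe_quality)]
    if not len(recs):
        return frozenset()
    matched = set()
    for anatomy in anatomies:
        terms = expand_terms(anatomy, anatomy_map, ontology)
        hits = recs[recs["term_id"].isin(terms)]
        for row in hits.itertuples(index=False):
            if table.stages.intersects((row.start_stage, row.end_stage), window):
                matched.add(anatomy)
                break
    return frozenset(matched)


@dataclass(frozen=True)
class NeighborComparison:
    """Host vs neighbor gene overlap counts and comparison p-values."""

    counts: pd.DataFrame  # index gene_class, columns k, n
    p_values: dict[str, float]  # neighbor class -> p vs host
    matched: dict[str, dict[str, frozenset[str]]]


def neighbor_comparison(
    calls: Mapping[str, Iterable[str]],
    genes: pd.DataFrame,
    table: AnnotationTable,
    window: StageWindow,
    anatomy_map: Mapping[str, frozenset[str]],
    ontology: Ontology,
    alternative: str = "two-sided",
) -> NeighborComparison:
    """Count constructs whose activity overlaps host / upstream / downstream genes.

    ``calls`` maps construct id to its significant-anatomy set; ``genes`` is
    indexed by construct with columns ``host``, ``upstream``, ``downstream``.
    A construct enters a gene class's denominator only when that gene has
    annotation data. Each neighbor class is compared to the host class with
    the continuity-corrected two-proportion test.
    """
    classes = [c for c in ("host", "upstream", "downstream") if c in genes.columns]
    counts: dict[str, tuple[int, int]] = {}
    matched: dict[str, dict[str, frozenset[str]]] = {}
    for cls in classes:
        k = n = 0
        per: dict[str, frozenset[str]] = {}
        for construct, anatomies in calls.items():
            if construct not in genes.index:
                continue
            gene = genes.loc[construct, cls]
            if not isinstance(gene, str) or not gene or gene not in table.genes:
                continue  # no data for this gene: excluded from the denominator
            n += 1
            m = gene_matches(anatomies, gene, table, window, anatomy_map, ontology)
            per[construct] = m
            if m:
                k += 1
        counts[cls] = (k, n)
        matched[cls] = per
    frame = pd.DataFrame(
        {"k": {c: counts[c][0] for c in classes}, "n": {c: counts[c][1] for c in classes}}
    )
    p_values = {}
    if "host" in counts and counts["host"][1] > 0:
        kh, nh = counts["host"]
        for cls in classes:
            if cls == "host" or counts[cls][1] == 0:
                continue
            p_values[cls] = proportions_test(kh, nh, *counts[cls], alternative=alternative)
    return NeighborComparison(frame, p_values, matched)


@dataclass(frozen=True)
class RandomGeneNull:
    mean: float
    sd: float
    counts: np.ndarray

    def __iter__(self):  # allow tuple unpacking (mean, sd)
        return iter((self.mean, self.sd))


def random_gene_null(
    calls: Sequence[Iterable[str]],
    table: AnnotationTable,
    exclusions: Iterable[str],
    window: StageWindow,
    anatomy_map: Mapping[str, frozenset[str]],
    ontology: Ontology,
    n_genes: int | None = None,
    n_iter: int = 100,
    seed: int = 0,
) -> RandomGeneNull:
    """Permutation null: overlap counts when hosts are replaced by random genes.

    Each iteration samples ``n_genes`` distinct genes (default: one per call)
    uniformly without replacement from the table minus ``exclusions``
    (host/neighbor/miRNA genes), assigns one to each call, and counts calls
    with at least one matched anatomy. Returns the mean and sample standard
    deviation of the per-iteration counts.
    """
    n_genes = n_genes if n_genes is not None else len(calls)
    if n_genes < len(calls):
        raise ValueError("need at least one gene per call")
    pool = sorted(table.genes - set(exclusions))
    if len(pool) < n_genes:
        raise ValueError(f"only {len(pool)} genes available after exclusions, need {n_genes}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0x6E75,)))
    counts = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        picked = rng.choice(len(pool), size=n_genes, replace=False)
        c = 0
        for call, gi in zip(calls, picked):
            if gene_matches(call, pool[gi], table, window, anatomy_map, ontology):
                c += 1
        counts[it] = c
    sd = float(counts.std(ddof=1)) if n_iter > 1 else 0.0
    return RandomGeneNull(float(counts.mean()), sd, counts)
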