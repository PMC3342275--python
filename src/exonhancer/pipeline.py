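"""End-to-end study orchestration: ingest -> call -> concurrency -> report.

A study is one control cohort plus any number of construct cohorts, all
sharing a vocabulary. :func:`run_study` fits the dual-criterion activity
model per construct, evaluates pairwise concurrency, assembles a wide
significance table (one column block per construct), and writes every stage
as TSV together with a run log echoing parameters and seeds. All stochastic
substreams derive from the single config seed, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calling import EnhancerActivityModel, EnhancerActivityResults, round_half_up
from .concurrency import all_pairs
from .intervals import binomial_sem
from .matrix import ExpressionMatrix, read_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    control: str
    cces: list[str]
    alpha: float = 0.05
    n_partitions: int = 5
    n_runs: int = 3
    none_threshold: float = 0.05
    specific_max: int = 4
    concurrency_alpha: float = 0.05
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name in ("alpha", "none_threshold", "concurrency_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_partitions < 2 or self.n_runs < 1 or self.specific_max < 1:
            raise ValueError("n_partitions >= 2, n_runs >= 1, specific_max >= 1 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class StudyReport:
    """Per-construct results plus global summary counts."""

    results: dict[str, EnhancerActivityResults]
    concurrency: pd.DataFrame
    config: PipelineConfig = field(repr=False)

    @property
    def counts(self) -> dict[str, int]:
        calls = [r.call for r in self.results.values()]
        c = {
            "total": len(calls),
            "significant": sum(x.activity_class == "significant" for x in calls),
            "weak": sum(x.activity_class == "weak" for x in calls),
            "none": sum(x.activity_class == "none" for x in calls),
            "specific": sum(x.specificity == "specific" for x in calls),
            "nonspecific": sum(x.specificity == "nonspecific" for x in calls),
        }
        assert c["specific"] + c["nonspecific"] == c["significant"]
        assert c["significant"] + c["weak"] + c["none"] == c["total"]
        return c

    @property
    def active(self) -> tuple[int, int]:
        """Constructs driving any clear expression: significant or weak, over total."""
        c = self.counts
        return c["significant"] + c["weak"], c["total"]

    @property
    def specific(self) -> tuple[int, int]:
        """Anatomy-specific constructs over active constructs."""
        c = self.counts
        return c["specific"], c["significant"] + c["weak"]

    def significance_table(self) -> pd.DataFrame:
        """Wide per-anatomy table: one column block per construct with its
        proportion, fold ratio where significant, both p-values and flag."""
        blocks = []
        for cid, res in self.results.items():
            t = res.table[["p_cce", "ratio", "p_prop", "p_ranksum", "significant"]].copy()
            t.columns = pd.MultiIndex.from_product([[cid], t.columns])
            blocks.append(t)
        return pd.concat(blocks, axis=1)

    def call_summary(self) -> pd.DataFrame:
        rows = []
        for cid, res in self.results.items():
            c = res.call
            rows.append(
                {
                    "construct_id": cid,
                    "n_embryos": res.model.cce.n_embryos,
                    "whole_embryo_fraction": c.whole_embryo_fraction,
                    "activity_class": c.activity_class,
                    "specificity": c.specificity,
                    "n_significant": len(c.significant_anatomies),
                    "significant_anatomies": ";".join(c.significant_anatomies),
                }
            )
        return pd.DataFrame(rows).set_index("construct_id")


def run_study(config: PipelineConfig) -> StudyReport:
    """Execute the full pipeline and write per-stage TSVs plus a run log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        control = read_matrix(config.control)
    except Exception as exc:
        raise RuntimeError(f"calling stage: cannot load control matrix {config.control!r}: {exc}") from exc
    results: dict[str, EnhancerActivityResults] = {}
    conc_frames = []
    for path in config.cces:
        try:
            cce = read_matrix(path)
        except Exception as exc:
            raise RuntimeError(f"ingest stage: cannot load construct matrix {path!r}: {exc}") from exc
        model = EnhancerActivityModel(
            cce,
            control,
            alpha=config.alpha,
            n_partitions=config.n_partitions,
            n_runs=config.n_runs,
            none_threshold=config.none_threshold,
            specific_max=config.specific_max,
        )
        res = model.fit(seed=config.seed)
        results[cce.construct_id] = res
        conc_frames.append(all_pairs(cce, alpha=config.concurrency_alpha))
        logger.info(
            "%s: class=%s specificity=%s significant=%s",
            cce.construct_id,
            res.call.activity_class,
            res.call.specificity,
            res.call.significant_anatomies,
        )
    concurrency = pd.concat(conc_frames, ignore_index=True) if conc_frames else pd.DataFrame()
    report = StudyReport(results, concurrency, config)
    report.significance_table().to_csv(outdir / "significance.tsv", sep="\t")
    report.call_summary().to_csv(outdir / "calls.tsv", sep="\t")
    if len(concurrency):
        concurrency.to_csv(outdir / "concurrency.tsv", sep="\t", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(
            {"version": __version__, "config": asdict(config), "counts": report.counts},
            fh,
            indent=2,
            sort_keys=True,
        )
    return report


@dataclass(frozen=True)
class CohortComparison:
    """Activity and specificity fractions of two cohorts with comparison p-values."""

    activity_a: tuple[int, int]
    activity_b: tuple[int, int]
    specificity_a: tuple[int, int]
    specificity_b: tuple[int, int]
    p_activity: float
    p_specificity: float

    def summary(self) -> str:
        def frac(kn):
            k, n = kn
            return f"{k}/{n} ({100 * k / n:.1f}%±{100 * binomial_sem(k, n):.1f}%)"

        return "\n".join(
            [
                "Cohort comparison",
                f"  activity:    {frac(self.activity_a)} vs {frac(self.activity_b)}  p = {round_half_up(self.p_activity, 3):.3f}",
                f"  specificity: {frac(self.specificity_a)} vs {frac(self.specificity_b)}  p = {round_half_up(self.p_specificity, 3):.3f}",
            ]
        )


def compare_cohort_counts(
    activity_a: tuple[int, int],
    activity_b: tuple[int, int],
    specificity_a: tuple[int, int],
    specificity_b: tuple[int, int],
    alternative: str = "two-sided",
) -> CohortComparison:
    """Compare two cohorts (e.g. coding vs noncoding elements) from raw counts."""
    from .calling import proportions_test

    for k, n in (activity_a, activity_b, specificity_a, specificity_b):
        if n < 1:
            raise ValueError("empty cohort")
    return CohortComparison(
        activity_a,
        activity_b,
        specificity_a,
        specificity_b,
        proportions_test(*activity_a, *activity_b, alternative=alternative),
        proportions_test(*specificity_a, *specificity_b, alternative=alternative),
    )


def compare_cohorts(
    report_a: StudyReport, report_b: StudyReport, alternative: str = "two-sided"
) -> CohortComparison:
    """Compare the activity and specificity fractions of two study reports."""
    return compare_cohort_counts(
        report_a.active, report_b.active, report_a.specific, report_b.specific, alternative
    )
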