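"""Per-anatomy enhancer calling: the dual proportions / rank-sum rule.

An anatomy is called as showing significant enhancer activity for a construct
when BOTH of two criteria reach ``p <= alpha`` (default 0.05) against the
minimal-promoter control:

1. a one-sided two-sample proportion test with continuity correction
   (``prop.test`` semantics, alternative: construct fraction > control
   fraction) over all scored embryos, and
2. a one-sided rank-sum test on expressing fractions of shuffled, randomly
   partitioned embryo groups (default 5 construct groups vs 5 control
   groups), averaged over 3 independent shuffling runs. This criterion
   absorbs injection-round variability.

The statistical surface is wrapped statsmodels-style: build an
:class:`EnhancerActivityModel` from a construct matrix and a control matrix,
call :meth:`~EnhancerActivityModel.fit`, and read estimates, p-values, the
per-anatomy decisions, fold ratios and the activity classification off the
returned :class:`EnhancerActivityResults`.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = [
    "expression_proportions",
    "proportions_test",
    "rank_sum_greater",
    "partition_ranksum",
    "call_anatomies",
    "fold_ratio",
    "round_half_up",
    "classify",
    "reconstruct_count",
    "EnhancerCall",
    "EnhancerActivityModel",
    "EnhancerActivityResults",
]


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def expression_proportions(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Raw expression proportion per anatomy.

    Returns a frame indexed by anatomy with columns ``k`` (expressing
    embryos), ``n`` (all surviving embryos) and ``p_hat = k/n``.
    """
    if matrix.n_embryos < 1:
        raise ValueError("empty matrix")
    k = matrix.column_counts()
    n = matrix.n_embryos
    return pd.DataFrame(
        {"k": k, "n": n, "p_hat": k / n}, index=pd.Index(matrix.anatomy_names, name="anatomy")
    )


def proportions_test(
    k1: int, n1: int, k0: int, n0: int, *, alternative: str = "greater", correction: bool = True
) -> float:
    """Two-sample binomial proportion test with Yates continuity correction.

    ``alternative="greater"`` tests whether the first proportion exceeds the
    second (the enhancer-calling direction); ``"two-sided"`` gives the
    chi-squared p-value. The statistic is the continuity-corrected pooled
    z; its square equals the Yates-corrected chi-squared of the 2x2 table.
    Degenerate pooled proportions (0 or 1) give z = 0, hence p = 0.5
    one-sided and p = 1 two-sided.
    """
    for k, n in ((k1, n1), (k0, n0)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"invalid count k={k} for n={n}")
    p1, p0 = k1 / n1, k0 / n0
    pooled = (k1 + k0) / (n1 + n0)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n0)
    diff = p1 - p0
    corr = min(0.5 * (1.0 / n1 + 1.0 / n0), abs(diff)) if correction else 0.0
    if var <= 0.0 or diff == 0.0:
        z = 0.0
    else:
        z = math.copysign(math.sqrt((abs(diff) - corr) ** 2 / var), diff)
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "less":
        return float(stats.norm.cdf(z))
    if alternative == "two-sided":
        return float(stats.chi2.sf(z * z, df=1))
    raise ValueError(f"unknown alternative {alternative!r}")


@lru_cache(maxsize=None)
def _split_index_matrix(n: int, m: int) -> np.ndarray:
    """All C(n+m, n) index choices for the first sample, as an array."""
    return np.array(list(combinations(range(n + m), n)), dtype=np.intp)


def rank_sum_greater(x, y, *, exact_max_total: int = 16) -> float:
    """One-sided rank-sum p-value: are values of ``x`` larger than ``y``?

    Tied observations take mid-ranks. For ``len(x)+len(y) <= exact_max_total``
    the null is enumerated exactly over all label permutations of the
    observed (possibly tied) rank vector, so the heavily discrete 5-vs-5
    group-fraction comparison carries no normal-approximation ambiguity.
    Larger samples fall back to the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n].sum()
    if n + m <= exact_max_total:
        sums = ranks[_split_index_matrix(n, m)].sum(axis=1)
        return float(np.mean(sums >= w_obs - 1e-9))
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def partition_ranksum(
    cce: ExpressionMatrix,
    control: ExpressionMatrix,
    anatomy: int | str,
    n_partitions: int = 5,
    n_runs: int = 3,
    seed: int = 0,
) -> float:
    """Mean rank-sum p-value over shuffling runs for one anatomy.

    Each run shuffles the construct's embryos, splits them into
    ``n_partitions`` near-equal groups (sizes differ by at most one), and
    takes each group's expressing fraction; the control embryos are shuffled
    and partitioned the same way. The run's p-value is the one-sided
    rank-sum comparison (construct group fractions greater); the returned
    statistic is the arithmetic mean over ``n_runs`` runs.

    Substream seeds are derived deterministically from ``seed``, the
    construct id, the anatomy column and the run index, so results are
    reproducible and independent of embryo input order given a fixed seed.
    """
    if cce.n_embryos < 1 or control.n_embryos < 1:
        raise ValueError("matrices must be nonempty")
    if n_partitions > min(cce.n_embryos, control.n_embryos):
        raise ValueError(
            f"n_partitions={n_partitions} exceeds the smaller embryo count; a partition would be empty"
        )
    # embryos are exchangeable within a cohort: sorting the binary column
    # before the seeded shuffle makes the result exactly invariant to embryo
    # input order at a fixed seed, without changing its distribution
    col_c = np.sort(cce.column(anatomy))
    col_0 = np.sort(control.column(anatomy))
    col_idx = cce.vocabulary.index(anatomy)
    tag = zlib.crc32(cce.construct_id.encode())
    ps = []
    for run in range(n_runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(tag, col_idx, run))
        )
        fx = _group_fractions(col_c, n_partitions, rng)
        fy = _group_fractions(col_0, n_partitions, rng)
        ps.append(rank_sum_greater(fx, fy))
    return float(np.mean(ps))


def _group_fractions(column: np.ndarray, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(len(column))
    # near-equal split: the first (n mod k) groups get one extra embryo
    sizes = np.full(n_groups, len(column) // n_groups, dtype=int)
    sizes[: len(column) % n_groups] += 1
    out = np.empty(n_groups)
    start = 0
    for g, s in enumerate(sizes):
        if s == 0:
            raise ValueError("empty partition")
        out[g] = column[perm[start : start + s]].mean()
        start += s
    return out


# ---------------------------------------------------------------------------
# decisions and classification
# ---------------------------------------------------------------------------

def call_anatomies(
    p_prop: pd.Series | dict, p_ranksum: pd.Series | dict, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the dual rule: significant iff both p-values are <= alpha."""
    p_prop = pd.Series(p_prop, dtype=float)
    p_ranksum = pd.Series(p_ranksum, dtype=float)
    if set(p_prop.index) != set(p_ranksum.index):
        raise ValueError("the two p-value tables must cover the same anatomies")
    p_ranksum = p_ranksum.reindex(p_prop.index)
    return pd.DataFrame(
        {
            "p_prop": p_prop,
            "p_ranksum": p_ranksum,
            "significant": (p_prop <= alpha) & (p_ranksum <= alpha),
        }
    )


def fold_ratio(p_cce: float, p_control: float) -> float:
    """Expression-fraction ratio construct/control; NaN when the control is 0."""
    if p_control == 0:
        return float("nan")
    return p_cce / p_control


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the convention used for displayed fold ratios."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EnhancerCall:
    """Per-construct classification of enhancer activity.

    ``activity_class`` is ``"none"`` when fewer than ``none_threshold`` of
    embryos express anywhere, ``"significant"`` when at least one anatomy
    passes the dual rule, and ``"weak"`` otherwise. ``specificity`` is
    ``"specific"`` for 1-4 significant anatomies, ``"nonspecific"`` for 5 or
    more, and ``"not-applicable"`` for weak/none constructs.
    """

    construct_id: str
    significant_anatomies: tuple[str, ...]
    specificity: str
    activity_class: str
    whole_embryo_fraction: float


def classify(
    construct_id: str,
    significant_anatomies,
    whole_embryo_fraction: float,
    none_threshold: float = 0.05,
    specific_max: int = 4,
) -> EnhancerCall:
    """Classify a construct from its significant-anatomy set and overall activity."""
    sig = tuple(significant_anatomies)
    if whole_embryo_fraction < none_threshold:
        activity = "none"
    elif sig:
        activity = "significant"
    else:
        activity = "weak"
    if activity == "significant":
        specificity = "specific" if len(sig) <= specific_max else "nonspecific"
    else:
        specificity = "not-applicable"
    return EnhancerCall(construct_id, sig, specificity, activity, whole_embryo_fraction)


def reconstruct_count(p_hat: float, n: int, tol: float = 5e-5) -> tuple[int, float, bool]:
    """Recover the integer count behind a printed proportion.

    Published tables print ``p_hat`` to four decimals, not counts. Returns
    ``(k, residual, exact)`` where ``k = round(p_hat * n)`` clipped to
    ``[0, n]``, ``residual = k/n - p_hat``, and ``exact`` flags whether the
    nearest count reproduces the printed value within ``tol``. Cells where no
    integer count reproduces the printed proportion (e.g. values that were
    averaged over injection rounds before printing) come back flagged
    ``exact=False`` for the caller to report.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = int(min(n, max(0, round(p_hat * n))))
    residual = k / n - p_hat
    return k, residual, abs(residual) < tol


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class EnhancerActivityModel:
    """Dual-criterion enhancer-activity model for one construct vs control.

    Parameters
    ----------
    cce, control
        Expression matrices sharing one vocabulary. The control is the
        minimal-promoter-only injection cohort.
    alpha
        Significance level applied to both criteria.
    n_partitions, n_runs
        Group count and run count of the rank-sum criterion.
    none_threshold
        Whole-embryo expressing fraction below which the construct is
        classified as having no activity.
    specific_max
        Largest significant-anatomy count still called anatomy-specific.
    """

    def __init__(
        self,
        cce: ExpressionMatrix,
        control: ExpressionMatrix,
        *,
        alpha: float = 0.05,
        n_partitions: int = 5,
        n_runs: int = 3,
        none_threshold: float = 0.05,
        specific_max: int = 4,
    ) -> None:
        if cce.vocabulary != control.vocabulary:
            raise ValueError("construct and control must share a vocabulary")
        if cce.n_embryos < 1 or control.n_embryos < 1:
            raise ValueError("matrices must be nonempty")
        self.cce = cce
        self.control = control
        self.alpha = alpha
        self.n_partitions = n_partitions
        self.n_runs = n_runs
        self.none_threshold = none_threshold
        self.specific_max = specific_max

    def fit(self, seed: int = 0) -> "EnhancerActivityResults":
        """Run both criteria for every anatomy and classify the construct."""
        props_c = expression_proportions(self.cce)
        props_0 = expression_proportions(self.control)
        rows = []
        for anatomy in self.cce.anatomy_names:
            k1, n1 = int(props_c.loc[anatomy, "k"]), int(props_c.loc[anatomy, "n"])
            k0, n0 = int(props_0.loc[anatomy, "k"]), int(props_0.loc[anatomy, "n"])
            p_prop = proportions_test(k1, n1, k0, n0, alternative="greater")
            p_rank = partition_ranksum(
                self.cce, self.control, anatomy, self.n_partitions, self.n_runs, seed
            )
            rows.append((anatomy, k1 / n1, k0 / n0, p_prop, p_rank))
        table = pd.DataFrame(
            rows, columns=["anatomy", "p_cce", "p_control", "p_prop", "p_ranksum"]
        ).set_index("anatomy")
        table["significant"] = (table["p_prop"] <= self.alpha) & (table["p_ranksum"] <= self.alpha)
        table["ratio"] = np.where(
            table["significant"] & (table["p_control"] > 0),
            table["p_cce"] / table["p_control"],
            np.nan,
        )
        whole = self.cce.whole_embryo_fraction()
        call = classify(
            self.cce.construct_id,
            tuple(table.index[table["significant"]]),
            whole,
            self.none_threshold,
            self.specific_max,
        )
        return EnhancerActivityResults(self, table, call, seed)


class EnhancerActivityResults:
    """Fitted per-anatomy significance table plus the construct-level call."""

    def __init__(
        self, model: EnhancerActivityModel, table: pd.DataFrame, call: EnhancerCall, seed: int
    ) -> None:
        self.model = model
        self.table = table
        self.call = call
        self.seed = seed

    @property
    def significant_anatomies(self) -> tuple[str, ...]:
        return self.call.significant_anatomies

    def summary(self) -> str:
        """Plain-text summary table in the style of a fitted-model report."""
        m = self.model
        head = [
            "Enhancer Activity Results",
            "=" * 74,
            f"Construct: {m.cce.construct_id:<28} Control: {m.control.construct_id}",
            f"Embryos scored: {m.cce.n_embryos:<23} Control embryos: {m.control.n_embryos}",
            f"alpha: {m.alpha}   partitions: {m.n_partitions}   runs: {m.n_runs}   seed: {self.seed}",
            "-" * 74,
        ]
        body = self.table.copy()
        body["ratio"] = body["ratio"].map(lambda r: "" if np.isnan(r) else f"{round_half_up(r, 1):.1f}")
        body["significant"] = body["significant"].map(lambda s: "X" if s else "")
        txt = body.to_string(float_format=lambda v: f"{v:.4f}")
        tail = [
            "-" * 74,
            f"Whole-embryo expressing fraction: {self.call.whole_embryo_fraction:.3f}",
            f"Activity class: {self.call.activity_class}   Specificity: {self.call.specificity}",
            f"Significant anatomies: {', '.join(self.call.significant_anatomies) or '(none)'}",
        ]
        return "\n".join(head + [txt] + tail)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    def concurrency(self, alpha: float = 0.05, restrict_to_significant: bool = False) -> pd.DataFrame:
        """Pairwise concurrent-activity table for this construct's matrix."""
        from .concurrency import all_pairs

        restrict = self.significant_anatomies if restrict_to_significant else None
        return all_pairs(self.model.cce, alpha=alpha, restrict=restrict)

    def plot_proportions(self, ax=None):
        """Bar plot of construct proportions with the control overlaid (cosmetic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.2))
        x = np.arange(len(self.table))
        ax.bar(x - 0.2, self.table["p_cce"], width=0.4, label=self.model.cce.construct_id)
        ax.bar(x + 0.2, self.table["p_control"], width=0.4, label="control", color="0.6")
        ax.set_xticks(x, self.table.index, rotation=45, ha="right")
        ax.set_ylabel("expressing fraction")
        ax.legend(frameon=False)
        return ax
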