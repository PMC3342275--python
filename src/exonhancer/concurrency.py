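"""Concurrent multi-anatomy activity versus mosaicism.

Transient transgenesis is mosaic: two anatomies can each be active across a
cohort without ever being active in the same embryo. Because every embryo is
scored in all anatomies, joint activity can be tabulated per embryo pair of
anatomies and compared to a null in which the four joint patterns 00, 01, 10
and 11 are equally likely:

    z = (N11 - 0.25 * N_total) / sqrt(N_total * 0.25 * 0.75)

with a one-sided upper-tail normal p-value (co-activity enrichment only).
Pairs with z > 3 are additionally highlighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

HIGHLIGHT_Z = 3.0


@dataclass(frozen=True)
class PairCounts:
    """Embryo counts by joint activity pattern for one anatomy pair."""

    anatomy_a: str
    anatomy_b: str
    n00: int
    n01: int
    n10: int
    n11: int

    @property
    def n_total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11


@dataclass(frozen=True)
class ConcurrencyResult:
    pair: tuple[str, str]
    z: float
    p: float


def pair_counts(matrix: ExpressionMatrix, a: int | str, b: int | str) -> PairCounts:
    """Tabulate the 2x2 joint activity counts for anatomies ``a`` and ``b``."""
    ia, ib = matrix.vocabulary.index(a), matrix.vocabulary.index(b)
    if ia == ib:
        raise ValueError("anatomy pair must be two distinct anatomies")
    ca, cb = matrix.data[:, ia].astype(bool), matrix.data[:, ib].astype(bool)
    return PairCounts(
        matrix.anatomy_names[ia],
        matrix.anatomy_names[ib],
        n00=int((~ca & ~cb).sum()),
        n01=int((~ca & cb).sum()),
        n10=int((ca & ~cb).sum()),
        n11=int((ca & cb).sum()),
    )


def concurrency_z(counts: PairCounts) -> ConcurrencyResult:
    """Co-activity z-score against the four-equal-patterns null."""
    n = counts.n_total
    if n < 1:
        raise ValueError("no embryos tabulated")
    z = (counts.n11 - 0.25 * n) / np.sqrt(n * 0.25 * 0.75)
    return ConcurrencyResult((counts.anatomy_a, counts.anatomy_b), float(z), float(stats.norm.sf(z)))


def all_pairs(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    restrict=None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Evaluate every unordered anatomy pair (45 for the 10-anatomy vocabulary).

    Results are ordered lexicographically by anatomy code. ``restrict``
    limits the evaluated anatomies (e.g. to the significant set);
    ``bonferroni`` divides alpha by the number of evaluated pairs (off by
    default — flags are reported uncorrected).
    """
    if matrix.n_embryos < 1:
        raise ValueError("empty matrix")
    names = list(matrix.anatomy_names)
    if restrict is not None:
        keep = set(restrict)
        names = [n for n in names if n in keep]
    pairs = list(combinations(names, 2))
    threshold = alpha / len(pairs) if (bonferroni and pairs) else alpha
    rows = []
    for a, b in pairs:
        c = pair_counts(matrix, a, b)
        r = concurrency_z(c)
        rows.append(
            {
                "construct_id": matrix.construct_id,
                "anatomy_a": a,
                "anatomy_b": b,
                "n00": c.n00,
                "n01": c.n01,
                "n10": c.n10,
                "n11": c.n11,
                "z": r.z,
                "p": r.p,
                "flagged": r.p < threshold,
                "highlighted": r.z > HIGHLIGHT_Z,
            }
        )
    return pd.DataFrame(rows)
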