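"""Binary embryo x anatomy expression matrices.

An :class:`ExpressionMatrix` is the atom of every calling statistic: one row
per surviving embryo, one 0/1 column per scored anatomy, plus the injection
batch each embryo came from. Matrices round-trip losslessly through a TSV
format (one embryo per row, header of anatomy names).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .vocab import DEFAULT_VOCABULARY, AnatomyVocabulary

_META_COLS = ("construct_id", "batch_id", "embryo_id")


@dataclass(frozen=True)
class EmbryoRecord:
    """Scored activity of a single embryo across all anatomies."""

    embryo_id: int
    batch_id: str
    activity: tuple[int, ...]


class ExpressionMatrix:
    """Per-construct binary embryo x anatomy table with batch labels."""

    def __init__(
        self,
        construct_id: str,
        data: np.ndarray | Sequence[Sequence[int]],
        vocabulary: AnatomyVocabulary = DEFAULT_VOCABULARY,
        batch_ids: Sequence[str] | None = None,
        embryo_ids: Sequence[int] | None = None,
    ) -> None:
        arr = np.asarray(data)
        if arr.ndim != 2 or arr.shape[1] != vocabulary.size:
            raise ValueError(
                f"data must be (n_embryos, {vocabulary.size}), got shape {arr.shape}"
            )
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("activity entries must be 0 or 1")
        self.construct_id = construct_id
        self.vocabulary = vocabulary
        self.data = arr.astype(np.uint8)
        n = arr.shape[0]
        self.batch_ids = list(batch_ids) if batch_ids is not None else ["b1"] * n
        if len(self.batch_ids) != n:
            raise ValueError("batch_ids length must equal n_embryos")
        self.embryo_ids = list(embryo_ids) if embryo_ids is not None else list(range(1, n + 1))
        if len(self.embryo_ids) != n:
            raise ValueError("embryo_ids length must equal n_embryos")

    @property
    def n_embryos(self) -> int:
        return int(self.data.shape[0])

    @property
    def anatomy_names(self) -> tuple[str, ...]:
        return self.vocabulary.names

    def column(self, anatomy: int | str) -> np.ndarray:
        return self.data[:, self.vocabulary.index(anatomy)]

    def column_counts(self) -> np.ndarray:
        """Expressing-embryo count per anatomy."""
        return self.data.sum(axis=0).astype(int)

    def whole_embryo_fraction(self) -> float:
        """Fraction of embryos expressing in at least one anatomy."""
        if self.n_embryos == 0:
            raise ValueError("empty matrix")
        return float((self.data.any(axis=1)).mean())

    def embryos(self) -> Iterator[EmbryoRecord]:
        for i in range(self.n_embryos):
            yield EmbryoRecord(self.embryo_ids[i], self.batch_ids[i], tuple(int(v) for v in self.data[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.anatomy_names))
        df.insert(0, "embryo_id", self.embryo_ids)
        df.insert(0, "batch_id", self.batch_ids)
        df.insert(0, "construct_id", self.construct_id)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.construct_id == other.construct_id
            and self.vocabulary == other.vocabulary
            and np.array_equal(self.data, other.data)
            and self.batch_ids == other.batch_ids
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.construct_id!r}, n_embryos={self.n_embryos}, anatomies={self.vocabulary.size})"


def merge_batches(matrices: Iterable[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate matrices from separate injection rounds of one construct.

    All inputs must share construct_id and vocabulary; per-record batch
    labels are preserved and n_embryos is the sum.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("nothing to merge")
    first = mats[0]
    for m in mats[1:]:
        if m.construct_id != first.construct_id:
            raise ValueError(f"construct mismatch: {m.construct_id!r} != {first.construct_id!r}")
        if m.vocabulary != first.vocabulary:
            raise ValueError("vocabulary mismatch")
    data = np.concatenate([m.data for m in mats]) if mats else np.empty((0, first.vocabulary.size))
    batches = [b for m in mats for b in m.batch_ids]
    return ExpressionMatrix(
        first.construct_id,
        data,
        first.vocabulary,
        batch_ids=batches,
        embryo_ids=list(range(1, len(batches) + 1)),
    )


def write_matrix(path: str | Path, matrix: ExpressionMatrix) -> None:
    """Write a matrix as TSV: construct_id, batch_id, embryo_id, one column per anatomy."""
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, vocabulary: AnatomyVocabulary | None = None) -> ExpressionMatrix:
    """Read a matrix TSV written by :func:`write_matrix` (lossless round trip).

    If no vocabulary is given, one is built from the header (codes in column
    order). Non-binary cells and malformed headers raise ``ValueError``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"batch_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty matrix file: {path}") from exc
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header, missing columns: {missing}")
    anat_cols = [c for c in df.columns if c not in _META_COLS]
    if vocabulary is None:
        if set(anat_cols) == set(DEFAULT_VOCABULARY.names):
            vocabulary = DEFAULT_VOCABULARY
        else:
            from .vocab import VocabEntry

            vocabulary = AnatomyVocabulary(
                tuple(VocabEntry(i + 1, name) for i, name in enumerate(anat_cols))
            )
    if set(anat_cols) != set(vocabulary.names):
        raise ValueError("header anatomies do not match vocabulary")
    vals = df[list(vocabulary.names)].to_numpy()
    if vals.size and not np.isin(vals, (0, 1)).all():
        raise ValueError("non-binary cell values in matrix file")
    construct = str(df["construct_id"].iloc[0]) if len(df) else Path(path).stem
    if len(df) and df["construct_id"].nunique() > 1:
        raise ValueError("multiple construct_ids in one matrix file")
    return ExpressionMatrix(
        construct,
        vals,
        vocabulary,
        batch_ids=[str(b) for b in df["batch_id"]],
        embryo_ids=[int(e) for e in df["embryo_id"]],
    )
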