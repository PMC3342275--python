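"""Parse controlled-vocabulary scoring transcripts into expression matrices.

A transcript is the text output of voice-recognition scoring: a stream of
whitespace-separated tokens in which a delimiter token (default ``"new"``)
starts the record of the next embryo and subsequent tokens name the anatomies
that embryo expressed in, either as numeric codes or as names/synonyms.
Embryos with no listed anatomy are retained as all-zero rows — the
denominators of all downstream proportions are *surviving* embryos, not
expressing embryos.
"""

from __future__ import annotations

import logging

import numpy as np

from .matrix import ExpressionMatrix
from .vocab import DEFAULT_VOCABULARY, AnatomyVocabulary

logger = logging.getLogger(__name__)

DELIMITER = "new"


class TranscriptError(ValueError):
    """Raised for unparseable transcripts under the strict error policy."""


def parse_transcript(
    text: str,
    vocab: AnatomyVocabulary = DEFAULT_VOCABULARY,
    policy: str = "strict",
    delimiter: str = DELIMITER,
    construct_id: str = "construct",
    batch_id: str = "b1",
) -> ExpressionMatrix:
    """Convert a scoring transcript to a binary embryo x anatomy matrix.

    Parameters
    ----------
    policy
        ``"strict"`` aborts on the first unrecognized token, reporting its
        position; ``"skip"`` logs and ignores it.

    Within one embryo segment token order is irrelevant and a repeated
    anatomy is idempotent (the bit is simply already set).
    """
    if policy not in ("strict", "skip"):
        raise ValueError(f"unknown policy {policy!r}")
    tokens = text.split()
    if not tokens:
        raise TranscriptError("empty transcript")
    delim = delimiter.lower()
    rows: list[np.ndarray] = []
    current: np.ndarray | None = None
    for pos, tok in enumerate(tokens):
        if tok.lower() == delim:
            if current is not None:
                rows.append(current)
            current = np.zeros(vocab.size, dtype=np.uint8)
            continue
        code = vocab.resolve(tok)
        if code is None:
            if policy == "strict":
                raise TranscriptError(f"unrecognized token {tok!r} at position {pos}")
            logger.info("skipping unrecognized token %r at position %d", tok, pos)
            continue
        if current is None:
            if policy == "strict":
                raise TranscriptError(
                    f"token {tok!r} at position {pos} before first {delimiter!r} delimiter"
                )
            logger.info("skipping token %r before first delimiter", tok)
            continue
        if current[code - 1]:
            logger.debug("duplicate anatomy token %r at position %d", tok, pos)
        current[code - 1] = 1
    if current is not None:
        rows.append(current)
    if not rows:
        raise TranscriptError("transcript contains no embryo segments")
    return ExpressionMatrix(construct_id, np.stack(rows), vocab, batch_ids=[batch_id] * len(rows))
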