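"""Controlled anatomy vocabulary for embryo GFP scoring.

Scoring transcripts refer to anatomies either by small numeric codes or by
name/synonym. The default vocabulary covers the ten anatomical regions scored
in a 22-30 hpf zebrafish embryo (forebrain through tail region), coded 1-10.
Custom vocabularies can be loaded from a TSV file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class VocabEntry:
    """One scored anatomy: numeric code, canonical name, spoken synonyms."""

    code: int
    name: str
    synonyms: frozenset[str] = frozenset()


def _norm(token: str) -> str:
    return re.sub(r"[^a-z0-9/+]", "", token.lower())


@dataclass(frozen=True)
class AnatomyVocabulary:
    """Ordered, validated set of scoreable anatomies.

    Codes must be unique and contiguous from 1; canonical names unique.
    """

    entries: tuple[VocabEntry, ...]
    _lookup: dict[str, int] = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if codes != list(range(1, len(codes) + 1)):
            raise ValueError(f"codes must be contiguous from 1, got {codes}")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("canonical names must be unique")
        lookup: dict[str, int] = {}
        for e in self.entries:
            lookup[str(e.code)] = e.code
            lookup[_norm(e.name)] = e.code
            for s in e.synonyms:
                lookup.setdefault(_norm(s), e.code)
        object.__setattr__(self, "_lookup", lookup)

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def index(self, anatomy: int | str) -> int:
        """0-based column index for a code, canonical name, or synonym."""
        code = self.resolve(anatomy)
        if code is None:
            raise KeyError(f"unknown anatomy: {anatomy!r}")
        return code - 1

    def resolve(self, token: int | str) -> int | None:
        """Map a token to its anatomy code, or None if unrecognized."""
        if isinstance(token, int):
            return token if 1 <= token <= self.size else None
        return self._lookup.get(_norm(str(token)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnatomyVocabulary":
        """Load from TSV columns: code, canonical_name, comma-separated synonyms."""
        entries = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed vocabulary line: {line!r}")
            syn = frozenset(s.strip() for s in parts[2].split(",") if s.strip()) if len(parts) > 2 else frozenset()
            entries.append(VocabEntry(int(parts[0]), parts[1], syn))
        entries.sort(key=lambda e: e.code)
        return cls(tuple(entries))

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{e.code}\t{e.name}\t{','.join(sorted(e.synonyms))}" for e in self.entries]
        Path(path).write_text("\n".join(lines) + "\n")


#: The ten anatomies scored in the reporter assay, coded 1-10 in the order
#: they appear in the study's summary table.
DEFAULT_VOCABULARY = AnatomyVocabulary(
    (
        VocabEntry(1, "Forebrain", frozenset({"fb"})),
        VocabEntry(2, "Midbrain/Hindbrain", frozenset({"midbrain", "hindbrain", "mhb"})),
        VocabEntry(3, "Eye", frozenset({"eyes"})),
        VocabEntry(4, "Ear/AboveHeart", frozenset({"ear"})),
        VocabEntry(5, "Heart", frozenset()),
        VocabEntry(6, "Notochord", frozenset({"noto"})),
        VocabEntry(7, "Yolk/YolkExtension", frozenset({"yolk"})),
        VocabEntry(8, "MidTrunk/AboveYolk", frozenset({"midtrunk", "trunk"})),
        VocabEntry(9, "Muscle", frozenset({"somite", "muscles"})),
        VocabEntry(10, "TailRegion", frozenset({"tail"})),
    )
)
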