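"""Sequence-conservation statistics for candidate coding enhancers.

Two statistics drive candidate selection and characterization of conserved
coding exons:

* gap-free percent identity over an aligned zebrafish/human CDS pair, and
* the conserved fraction at four-fold degenerate third codon positions
  ("4-fold p-distance"), which measures constraint invisible to the protein.

A third codon position is four-fold degenerate when its codon's first two
bases fix the amino acid regardless of the third base (families GC*, GG*,
CC*, AC*, GT*, CT*, TC*, CG* in the standard genetic code). A site enters
the statistic only when both species carry gap-free, N-free codons aligned
in frame with an *identical* four-fold-family dinucleotide prefix, so the
third position is guaranteed synonymous in both species. At least five such
codons are required; otherwise the statistic is undefined (a flagged value,
not an error).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

GAP = "-"
ALPHABET = set("ACGTN-")

#: Dinucleotide prefixes whose codon family is four-fold degenerate.
FOURFOLD_PREFIXES = frozenset({"GC", "GG", "CC", "AC", "GT", "CT", "TC", "CG"})

XHOI_SITE = "CTCGAG"
BGLII_SITE = "AGATCT"

MIN_FOURFOLD_CODONS = 5


@dataclass(frozen=True)
class AlignedCdsPair:
    """Pairwise-aligned CDS sequences of equal aligned length.

    ``frame_offset`` gives the codon phase of the first *ungapped* base of
    each sequence (0 means the alignment starts on a codon boundary).
    Columns gapped in both sequences are tolerated but uninformative.
    """

    seq_a: str
    seq_b: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        if not len(a):
            raise ValueError("empty alignment")
        bad = (set(a) | set(b)) - ALPHABET
        if bad:
            raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")
        # columns gapped in both sequences carry no information; they are
        # tolerated and excluded from every statistic
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")


def percent_identity(pair: AlignedCdsPair) -> tuple[float, int]:
    """Identity over columns where neither species has a gap.

    Columns containing N in either sequence are excluded from the
    denominator (sequencing ambiguity is not counted as divergence);
    matching is case-insensitive. Raises if no comparable column remains.
    """
    compared = matches = 0
    for x, y in zip(pair.seq_a, pair.seq_b):
        if GAP in (x, y) or "N" in (x, y):
            continue
        compared += 1
        matches += x == y
    if compared == 0:
        raise ValueError("no gap-free comparable columns in alignment")
    return matches / compared, compared


@dataclass(frozen=True)
class FourfoldSite:
    """One aligned four-fold degenerate third-position column."""

    column: int  # alignment column of the third codon position
    prefix: str
    third_a: str
    third_b: str

    @property
    def conserved(self) -> bool:
        return self.third_a == self.third_b


def _codon_starts(pair: AlignedCdsPair):
    """Alignment columns where both sequences begin an in-frame, gap-free codon."""
    a, b = pair.seq_a, pair.seq_b
    ia = ib = 0  # ungapped indices
    for col in range(len(a) - 2):
        xa, xb = a[col], b[col]
        ok_phase = (
            xa != GAP
            and xb != GAP
            and (ia - pair.frame_offset) % 3 == 0
            and (ib - pair.frame_offset) % 3 == 0
            and ia >= pair.frame_offset
            and ib >= pair.frame_offset
        )
        if ok_phase:
            cod_a = a[col : col + 3]
            cod_b = b[col : col + 3]
            if GAP not in cod_a and GAP not in cod_b and "N" not in cod_a and "N" not in cod_b:
                yield col, cod_a, cod_b
        ia += xa != GAP
        ib += xb != GAP


def fourfold_sites(pair: AlignedCdsPair) -> list[FourfoldSite]:
    """Aligned four-fold degenerate third-position columns.

    A codon qualifies iff both species have a gap-free, N-free codon at the
    same in-frame alignment columns, the two codons agree at positions 1-2,
    and that dinucleotide prefix is a four-fold degenerate family.
    """
    sites = []
    for col, cod_a, cod_b in _codon_starts(pair):
        if cod_a[:2] == cod_b[:2] and cod_a[:2] in FOURFOLD_PREFIXES:
            sites.append(FourfoldSite(col + 2, cod_a[:2], cod_a[2], cod_b[2]))
    return sites


def fourfold_p_distance(pair: AlignedCdsPair, min_codons: int = MIN_FOURFOLD_CODONS):
    """Conserved fraction at qualifying four-fold sites, or None if too few.

    Returns ``(fraction_or_None, n_qualifying_codons)``. Fewer than
    ``min_codons`` qualifying codons makes the statistic undefined.
    """
    sites = fourfold_sites(pair)
    if len(sites) < min_codons:
        return None, len(sites)
    conserved = sum(s.conserved for s in sites)
    return conserved / len(sites), len(sites)


@dataclass(frozen=True)
class ConservationStats:
    pct_identity: float
    n_compared_columns: int
    fourfold_p_distance: float | None
    n_fourfold_codons: int


def conservation_stats(pair: AlignedCdsPair) -> ConservationStats:
    ident, ncols = percent_identity(pair)
    p4, n4 = fourfold_p_distance(pair)
    return ConservationStats(ident, ncols, p4, n4)


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...]


def cce_candidate_filter(
    exon_seq: str,
    identity: float,
    developmental: bool,
    length: int | None = None,
    min_identity: float = 0.60,
    length_bounds: tuple[int, int] = (100, 1000),
    restriction_sites: tuple[str, ...] = (XHOI_SITE, BGLII_SITE),
) -> FilterResult:
    """Candidate filter for testable conserved coding exons.

    Pass requires cross-species identity above ``min_identity``, length in
    the closed interval ``length_bounds``, no XhoI (CTCGAG) or BglII
    (AGATCT) site in the unaligned exon sequence (both sites are their own
    reverse complements, so a forward-strand scan suffices), and a
    developmental-gene flag. All violated criteria are listed.
    """
    seq = exon_seq.upper().replace(GAP, "")
    length = length if length is not None else len(seq)
    reasons = []
    if not identity > min_identity:
        reasons.append("identity")
    if not length_bounds[0] <= length <= length_bounds[1]:
        reasons.append("length")
    if any(site in seq for site in restriction_sites):
        reasons.append("restriction-site")
    if not developmental:
        reasons.append("not-developmental")
    return FilterResult(not reasons, tuple(reasons))


def read_alignment(path: str | Path) -> AlignedCdsPair:
    """Read a two-record aligned FASTA; frame taken from a ``frame=N`` tag
    in the first record's description (default 0)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned records, found {len(records)}")
    frame = 0
    for token in records[0].description.split():
        if token.startswith("frame="):
            frame = int(token.split("=", 1)[1])
    return AlignedCdsPair(str(records[0].seq), str(records[1].seq), frame_offset=frame)
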