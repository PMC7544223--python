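"""Shared domain types for bitome construction.

Coordinates are 0-based, half-open throughout the library; GenBank and TSV
inputs (1-based, inclusive) are converted at the parsing boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

FORWARD = "+"
REVERSE = "-"
UNSTRANDED = "."

STRANDS = (FORWARD, REVERSE, UNSTRANDED)

#: categories split into six rows: three frames x two strands
SIX_ROW_CATEGORIES = frozenset(
    {
        "cds",
        "pseudogene",
        "rna_gene",
        "codon",
        "protein",
        "amino_acid",
        "secondary_structure",
        "exposure",
        "cog",
    }
)

#: categories kept as a single row (no strand information available)
SINGLE_ROW_CATEGORIES = frozenset({"regulon", "sigmulon", "imodulon", "tfbs"})

#: categories with no coordinates of their own; bits come from linked genes
LINKED_CATEGORIES = frozenset({"regulon", "sigmulon", "imodulon", "cog"})

#: two-row (strand-split) categories: everything positional that is not six-row
TWO_ROW_CATEGORIES = frozenset(
    {
        "insertion_element",
        "repeat_region",
        "origin",
        "operon",
        "transcription_unit",
        "promoter",
        "minus10",
        "minus35",
        "tss",
        "terminator",
        "attenuator",
        "shine_dalgarno",
        "riboswitch",
        "nucleobase",
    }
)

KNOWN_CATEGORIES = SIX_ROW_CATEGORIES | SINGLE_ROW_CATEGORIES | TWO_ROW_CATEGORIES


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open positional range ``[start, end)`` with a strand.

    ``wraps=True`` marks an origin-spanning interval on a circular genome, in
    which case ``start > end`` is permitted and the effective length is
    ``(genome_length - start) + end``.
    """

    start: int
    end: int
    strand: str = UNSTRANDED
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.wraps and not self.start < self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.start < 0 or self.end < 0:
            raise ValueError("negative coordinate")

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping interval needs genome_length")
            return (genome_length - self.start) + self.end
        return self.end - self.start

    def positions(self, genome_length: int | None = None) -> np.ndarray:
        """All genomic positions covered, in ascending genomic order."""
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping interval needs genome_length")
            return np.concatenate(
                [np.arange(self.start, genome_length), np.arange(0, self.end)]
            )
        return np.arange(self.start, self.end)

    def contains(self, position: int, genome_length: int | None = None) -> bool:
        if self.wraps:
            return position >= self.start or position < self.end
        return self.start <= position < self.end

    def validate(self, genome_length: int, circular: bool = False) -> None:
        if self.wraps and not circular:
            raise ValueError("wrapping interval on a linear genome")
        limit = genome_length
        if self.end > limit or self.start >= limit:
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds genome length {genome_length}"
            )


@dataclass
class FeatureRecord:
    """One annotated feature from any input source.

    ``links`` holds locus tags of genes the feature is associated with (used
    by linked categories such as regulons and COGs, and by TU/operon
    filtering). ``attributes`` is a free key-value map, e.g. ``translation``
    for CDS records or ``tss``/``minus10``/``minus35`` for promoters.
    """

    id: str
    category: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    strand: str = UNSTRANDED
    subtype: str | None = None
    links: set[str] = field(default_factory=set)
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in KNOWN_CATEGORIES and self.category != "structural_track":
            raise ValueError(f"unknown feature category {self.category!r}")
        for iv in self.intervals:
            if iv.strand != UNSTRANDED and iv.strand != self.strand:
                raise ValueError(
                    f"interval strand {iv.strand!r} disagrees with feature strand"
                )

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate across intervals."""
        return min(iv.start for iv in self.intervals)

    @property
    def end(self) -> int:
        return max(iv.end for iv in self.intervals)

    def length(self, genome_length: int | None = None) -> int:
        return sum(iv.length(genome_length) for iv in self.intervals)

    def positions(self, genome_length: int | None = None) -> np.ndarray:
        if not self.intervals:
            return np.empty(0, dtype=np.int64)
        return np.unique(
            np.concatenate([iv.positions(genome_length) for iv in self.intervals])
        )


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide substitution at a 0-based genomic position."""

    position: int
    ref: str
    alt: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("ref and alt must be single nucleotides")
        if self.ref.upper() == self.alt.upper():
            raise ValueError("ref equals alt")
        if self.position < 0:
            raise ValueError("negative position")


class RowKey(NamedTuple):
    """Identity of one bitome row: (category, subtype, strand class, frame).

    ``strand`` is ``'+'``/``'-'`` for stranded rows and ``None`` for
    single-row categories; ``frame`` is 0/1/2 for six-row categories and
    ``None`` otherwise.
    """

    category: str
    subtype: str | None
    strand: str | None
    frame: int | None

    def __str__(self) -> str:
        sub = self.subtype if self.subtype is not None else "-"
        strand = self.strand if self.strand is not None else "."
        frame = str(self.frame) if self.frame is not None else "."
        return f"{self.category}|{sub}|{strand}|{frame}"
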