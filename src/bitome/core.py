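"""Construction of the sparse binary position-by-feature matrix.

The matrix (a "bitome") has one row per distinct :class:`RowKey` and one
column per genomic position. Element values are strictly 0/1; overlapping
features with the same row key OR their bits rather than stacking them.
Row-splitting rules:

* gene-like features, codons, proteins, amino acids, structural tracks and
  COG categories occupy six rows each: three frames (mod-3 of the start
  coordinate) x two strands;
* positional regulatory features occupy two rows (forward/reverse);
* regulons, sigmulons, i-modulons and TF binding sites are single rows, as
  no strand information is available for them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.io import mmread, mmwrite

from .types import (
    FORWARD,
    LINKED_CATEGORIES,
    REVERSE,
    SINGLE_ROW_CATEGORIES,
    SIX_ROW_CATEGORIES,
    UNSTRANDED,
    FeatureRecord,
    GenomicInterval,
    RowKey,
)

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_AA_1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "U": "Sec",
}

_STOP_CODONS = {"TAA", "TAG", "TGA"}

# bacterial genetic code (translation table 11), standard assignments
_CODON_TABLE = {}


def _init_codon_table():
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]
    _CODON_TABLE.update(table.forward_table)
    for stop in table.stop_codons:
        _CODON_TABLE[stop] = "*"


_init_codon_table()


@dataclass
class BuildConfig:
    """Options controlling bitome assembly.

    ``frame_anchor`` selects the coordinate whose mod-3 defines a feature's
    frame: ``"left"`` (leftmost genomic coordinate, both strands; default)
    or ``"coding"`` (first coding base: leftmost on the forward strand,
    rightmost on the reverse strand).
    """

    include_categories: set[str] | None = None  # None = everything provided
    include_nucleobase: bool = True
    include_codon_tracks: bool = True
    include_protein_tracks: bool = True
    frame_anchor: str = "left"
    circular: bool = False
    ambiguous_base_policy: str = "skip"  # or "error"

    def __post_init__(self):
        if self.frame_anchor not in ("left", "coding"):
            raise ValueError(f"unknown frame anchor {self.frame_anchor!r}")
        if self.ambiguous_base_policy not in ("skip", "error"):
            raise ValueError("ambiguous_base_policy must be 'skip' or 'error'")


def frame_of(coding_start: int, strand: str = FORWARD) -> int:
    """Frame of a coding feature: mod-3 of its start coordinate."""
    return coding_start % 3


def coding_start_of(feature: FeatureRecord, anchor: str = "left") -> int:
    """The coordinate anchoring a feature's frame under the chosen policy."""
    if anchor == "coding" and feature.strand == REVERSE:
        return feature.end - 1
    return feature.start


def assign_row_keys(feature, genes_by_tag=None, frame_anchor="left"):
    """Row keys a feature's bits belong to.

    Positional features map to a single key; linked categories (regulon,
    sigmulon, i-modulon: single row; COG: six rows) derive strand/frame from
    their linked genes, which must be supplied via ``genes_by_tag``.
    Returns a list of ``(RowKey, positions_source)`` pairs where
    ``positions_source`` is the feature itself or a linked gene.
    """
    category = feature.category
    if category in LINKED_CATEGORIES:
        if genes_by_tag is None:
            raise ValueError(f"category {category!r} needs linked genes to resolve rows")
        pairs = []
        for tag in sorted(feature.links):
            gene = genes_by_tag.get(tag)
            if gene is None:
                continue
            if category == "cog":
                key = RowKey(
                    category,
                    feature.subtype,
                    gene.strand,
                    frame_of(coding_start_of(gene, frame_anchor)),
                )
            else:
                key = RowKey(category, feature.subtype, None, None)
            pairs.append((key, gene))
        return pairs
    if category in SINGLE_ROW_CATEGORIES:
        return [(RowKey(category, feature.subtype, None, None), feature)]
    if category in SIX_ROW_CATEGORIES:
        frame = feature.attributes.get("frame")
        if frame is None:
            frame = frame_of(coding_start_of(feature, frame_anchor))
        strand = feature.strand if feature.strand != UNSTRANDED else FORWARD
        return [(RowKey(category, feature.subtype, strand, frame), feature)]
    # two-row (strand-split) positional categories
    strand = feature.strand if feature.strand != UNSTRANDED else FORWARD
    return [(RowKey(category, feature.subtype, strand, None), feature)]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _runs(positions: np.ndarray, strand: str) -> list[GenomicInterval]:
    """Maximal contiguous intervals from a sorted position array."""
    positions = np.sort(np.asarray(positions, dtype=np.int64))
    if positions.size == 0:
        return []
    breaks = np.where(np.diff(positions) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [positions.size - 1]])
    return [
        GenomicInterval(int(positions[s]), int(positions[e]) + 1, strand)
        for s, e in zip(starts, ends)
    ]


def derive_sequence_tracks(sequence, ambiguous_base_policy="skip"):
    """Per-base nucleobase tracks: 8 rows (4 bases x 2 strands).

    The reverse-strand rows hold the complement, so every unambiguous
    position carries exactly two nucleobase bits (one per strand).
    """
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    known = np.isin(seq, [b"A", b"C", b"G", b"T"])
    if not known.all():
        if ambiguous_base_policy == "error":
            bad = int(np.argmin(known))
            raise ValueError(f"ambiguous base {sequence[bad]!r} at position {bad}")
        log.info("skipping %d ambiguous bases", int((~known).sum()))
    records = []
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for base in "ACGT":
        fwd_pos = np.flatnonzero(seq == base.encode())
        rev_pos = np.flatnonzero(seq == complement[base].encode())
        for strand, pos in ((FORWARD, fwd_pos), (REVERSE, rev_pos)):
            if pos.size == 0:
                continue
            records.append(
                FeatureRecord(
                    id=f"nucleobase_{base}_{'fwd' if strand == FORWARD else 'rev'}",
                    category="nucleobase",
                    subtype=base,
                    intervals=_runs(pos, strand),
                    strand=strand,
                )
            )
    return records


def coding_positions(cds: FeatureRecord) -> np.ndarray:
    """Genomic positions of a CDS in coding (5'->3') order, splicing
    compound locations in genomic order before reversing for the minus
    strand."""
    parts = sorted(cds.intervals, key=lambda iv: iv.start)
    pos = np.concatenate([iv.positions() for iv in parts])
    if cds.strand == REVERSE:
        pos = pos[::-1]
    return pos


def coding_sequence(cds: FeatureRecord, sequence: str) -> str:
    parts = sorted(cds.intervals, key=lambda iv: iv.start)
    spliced = "".join(sequence[iv.start : iv.end] for iv in parts)
    if cds.strand == REVERSE:
        return reverse_complement(spliced)
    return spliced


def translate_codon(codon: str) -> str:
    return _CODON_TABLE.get(codon.upper(), "X")


def derive_codon_and_aa_tracks(cds_features, sequence, frame_anchor="left",
                               include_protein=True):
    """Codon, amino-acid and protein-presence records for every CDS.

    Each codon yields a 3-bp record whose subtype is the codon read 5'->3'
    on the coding strand. Each non-stop residue yields an amino-acid record
    over the same positions; stop codons produce codon records only, so
    amino-acid coverage matches protein length while codon coverage matches
    CDS coverage. When the annotation carries a ``translation`` it is
    trusted over naive translation (this is how selenocysteine residues at
    recoded UGA codons are represented).
    """
    records = []
    for cds in cds_features:
        if cds.category != "cds":
            continue
        pos = coding_positions(cds)
        cseq = coding_sequence(cds, sequence)
        n_codons = len(pos) // 3
        if len(pos) % 3:
            log.warning("CDS %s length %d not divisible by 3; trailing bases ignored",
                        cds.id, len(pos))
        translation = cds.attributes.get("translation")
        frame = frame_of(coding_start_of(cds, frame_anchor))
        aa_positions = []
        for i in range(n_codons):
            codon_pos = pos[3 * i : 3 * i + 3]
            codon = cseq[3 * i : 3 * i + 3].upper()
            records.append(
                FeatureRecord(
                    id=f"{cds.id}_codon{i}",
                    category="codon",
                    subtype=codon,
                    intervals=_runs(codon_pos, cds.strand),
                    strand=cds.strand,
                    links={cds.id},
                    attributes={"frame": frame},
                )
            )
            if translation is not None and i < len(translation):
                letter = translation[i].upper()
            else:
                letter = translate_codon(codon)
            if letter == "*" or (translation is not None and i >= len(translation)
                                 and codon in _STOP_CODONS):
                continue
            aa3 = _AA_1TO3.get(letter)
            if aa3 is None:
                continue
            records.append(
                FeatureRecord(
                    id=f"{cds.id}_aa{i}",
                    category="amino_acid",
                    subtype=aa3,
                    intervals=_runs(codon_pos, cds.strand),
                    strand=cds.strand,
                    links={cds.id},
                    attributes={"frame": frame},
                )
            )
            aa_positions.append(codon_pos)
        if include_protein and aa_positions:
            records.append(
                FeatureRecord(
                    id=f"{cds.id}_protein",
                    category="protein",
                    subtype=None,
                    intervals=_runs(np.concatenate(aa_positions), cds.strand),
                    strand=cds.strand,
                    links={cds.id},
                    attributes={"frame": frame},
                )
            )
    return records


@dataclass
class Bitome:
    """Sparse binary matrix with labeled row keys over genomic positions."""

    matrix: sparse.csr_matrix
    row_keys: list[RowKey]
    sequence: str | None = None
    circular: bool = False
    overlap_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.row_keys):
            raise ValueError("row_keys length disagrees with matrix rows")
        if len(set(self.row_keys)) != len(self.row_keys):
            raise ValueError("duplicate row keys")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def total_bits(self) -> int:
        return int(self.matrix.nnz)

    def row_index(self, key: RowKey) -> int:
        return self.row_keys.index(key)

    def column_bit_counts(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel().astype(np.int64)

    def row_bit_counts(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(np.int64)

    def select_rows(self, predicate) -> "Bitome":
        """Row-filtered copy; ``predicate`` takes a RowKey."""
        mask = [predicate(k) for k in self.row_keys]
        if not any(mask):
            log.warning("row predicate matched no rows")
        idx = np.flatnonzero(mask)
        return Bitome(
            matrix=self.matrix[idx],
            row_keys=[self.row_keys[i] for i in idx],
            sequence=self.sequence,
            circular=self.circular,
        )

    def extract(self, interval: GenomicInterval) -> "Bitome":
        """Column sub-matrix over a genomic range, columns re-based to 0."""
        if not interval.wraps and interval.start >= interval.end:
            raise ValueError("empty interval")
        if interval.wraps:
            if not self.circular:
                raise ValueError("wrapping extract on a linear bitome")
            mat = sparse.hstack(
                [self.matrix[:, interval.start :], self.matrix[:, : interval.end]]
            ).tocsr()
            seq = (
                self.sequence[interval.start :] + self.sequence[: interval.end]
                if self.sequence is not None
                else None
            )
        else:
            if interval.end > self.n_cols:
                raise ValueError("interval beyond genome end")
            mat = self.matrix[:, interval.start : interval.end]
            seq = (
                self.sequence[interval.start : interval.end]
                if self.sequence is not None
                else None
            )
        return Bitome(matrix=mat.tocsr(), row_keys=list(self.row_keys),
                      sequence=seq, circular=False)

    # -- serialization ----------------------------------------------------

    def save(self, directory) -> None:
        """Write MatrixMarket matrix + row-key TSV + JSON header (+ FASTA)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "matrix.mtx"), self.matrix.tocoo())
        with open(directory / "row_keys.tsv", "w") as fh:
            fh.write("index\tcategory\tsubtype\tstrand\tframe\n")
            for i, key in enumerate(self.row_keys):
                fh.write(
                    f"{i}\t{key.category}\t{key.subtype if key.subtype is not None else ''}"
                    f"\t{key.strand if key.strand is not None else '.'}"
                    f"\t{key.frame if key.frame is not None else '.'}\n"
                )
        header = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "total_bits": self.total_bits,
            "circular": self.circular,
        }
        with open(directory / "header.json", "w") as fh:
            json.dump(header, fh, indent=1, sort_keys=True)
        if self.sequence is not None:
            with open(directory / "sequence.fa", "w") as fh:
                fh.write(">genome\n")
                for i in range(0, len(self.sequence), 70):
                    fh.write(self.sequence[i : i + 70] + "\n")

    @classmethod
    def load(cls, directory) -> "Bitome":
        directory = Path(directory)
        matrix = sparse.csr_matrix(mmread(str(directory / "matrix.mtx")))
        matrix.data[:] = 1
        row_keys = []
        with open(directory / "row_keys.tsv") as fh:
            next(fh)
            for line in fh:
                _, category, subtype, strand, frame = line.rstrip("\n").split("\t")
                row_keys.append(
                    RowKey(
                        category,
                        subtype if subtype else None,
                        strand if strand != "." else None,
                        int(frame) if frame != "." else None,
                    )
                )
        with open(directory / "header.json") as fh:
            header = json.load(fh)
        sequence = None
        fasta = directory / "sequence.fa"
        if fasta.exists():
            with open(fasta) as fh:
                sequence = "".join(l.strip() for l in fh if not l.startswith(">"))
        return cls(matrix=matrix.astype(np.int8), row_keys=row_keys,
                   sequence=sequence, circular=header.get("circular", False))

    def to_bed(self, path) -> None:
        """One BED line (0-based half-open) per contiguous bit run per row."""
        with open(path, "w") as fh:
            csr = self.matrix.tocsr()
            for i, key in enumerate(self.row_keys):
                cols = csr.indices[csr.indptr[i] : csr.indptr[i + 1]]
                strand = key.strand if key.strand is not None else "."
                for iv in _runs(cols, FORWARD):
                    fh.write(f"genome\t{iv.start}\t{iv.end}\t{key}\t0\t{strand}\n")


def _row_sort_key(key: RowKey):
    return (
        key.category,
        key.subtype if key.subtype is not None else "",
        key.strand if key.strand is not None else "",
        key.frame if key.frame is not None else -1,
    )


def build(sequence, features, config: BuildConfig | None = None) -> Bitome:
    """Assemble feature records into a bitome.

    Derived sequence tracks (nucleobases, codons, amino acids, proteins)
    are generated here from the sequence and the CDS records, so callers
    pass only annotated features. Rows are ordered lexicographically by
    (category, subtype, strand, frame); building twice from the same inputs
    yields identical matrices.
    """
    config = config or BuildConfig()
    genome_length = len(sequence)
    features = list(features)
    if config.include_categories is not None:
        features = [f for f in features if f.category in config.include_categories]

    genes_by_tag = {
        f.id: f for f in features if f.category in ("cds", "pseudogene", "rna_gene")
    }

    derived: list[FeatureRecord] = []
    if config.include_nucleobase:
        derived.extend(derive_sequence_tracks(sequence, config.ambiguous_base_policy))
    if config.include_codon_tracks:
        derived.extend(
            derive_codon_and_aa_tracks(
                features, sequence, config.frame_anchor, config.include_protein_tracks
            )
        )

    placements: dict[RowKey, list[np.ndarray]] = {}
    for feature in features + derived:
        for iv in feature.intervals:
            iv.validate(genome_length, circular=config.circular)
        for key, source in assign_row_keys(feature, genes_by_tag, config.frame_anchor):
            pos = source.positions(genome_length)
            if pos.size == 0:
                continue
            if pos[-1] >= genome_length:
                raise ValueError(
                    f"feature {feature.id} exceeds genome length {genome_length}"
                )
            placements.setdefault(key, []).append(pos)

    row_keys = sorted(placements, key=_row_sort_key)
    key_index = {k: i for i, k in enumerate(row_keys)}
    rows, cols = [], []
    for key, pos_lists in placements.items():
        all_pos = np.concatenate(pos_lists)
        rows.append(np.full(all_pos.size, key_index[key], dtype=np.int64))
        cols.append(all_pos)
    if rows:
        coo = sparse.coo_matrix(
            (
                np.ones(sum(r.size for r in rows), dtype=np.int64),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(len(row_keys), genome_length),
        )
        coo.sum_duplicates()
        overlap_counts = {
            row_keys[i]: int(c)
            for i, c in zip(*_overlaps(coo))
        }
        coo.data = np.ones_like(coo.data, dtype=np.int8)
        matrix = coo.tocsr()
    else:
        matrix = sparse.csr_matrix((0, genome_length), dtype=np.int8)
        overlap_counts = {}
    return Bitome(
        matrix=matrix,
        row_keys=row_keys,
        sequence=sequence,
        circular=config.circular,
        overlap_counts=overlap_counts,
    )


def _overlaps(coo):
    """Per-row count of positions set more than once (diagnostic only)."""
    dup = coo.data > 1
    if not dup.any():
        return [], []
    rows = coo.row[dup]
    uniq, counts = np.unique(rows, return_counts=True)
    return uniq, counts
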