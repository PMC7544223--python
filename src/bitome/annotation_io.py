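"""Readers and writers for all external inputs.

Supported formats:

* single-record GenBank flat files (genome sequence + core features),
* a regulatory TSV dialect, one file per feature class, with columns
  ``id``, ``left``, ``right`` (1-based inclusive), ``strand`` (+/-/.),
  ``linked_locus_tags`` (comma-separated); promoter files add ``tss``,
  ``minus10_left``/``minus10_right``, ``minus35_left``/``minus35_right``;
  regulon/sigmulon/imodulon/COG files carry only ``id`` and
  ``linked_locus_tags`` (no coordinates),
* SNP tables as TSV (``position``, ``ref``, ``alt``, ``experiment``) or
  minimal VCF 4.x,
* binary gene-label tables (``locus_tag``, ``label``),
* per-residue structural-track TSVs (``locus_tag``, ``residue_index``,
  ``value``).

All external coordinates are 1-based inclusive and are converted to the
library's 0-based half-open convention here, at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .types import (
    FORWARD,
    LINKED_CATEGORIES,
    REVERSE,
    UNSTRANDED,
    FeatureRecord,
    GenomicInterval,
    SNPRecord,
)

log = logging.getLogger(__name__)

#: GenBank feature keys mapped to bitome categories
_GENBANK_CATEGORY = {
    "CDS": "cds",
    "rRNA": "rna_gene",
    "tRNA": "rna_gene",
    "ncRNA": "rna_gene",
    "tmRNA": "rna_gene",
    "misc_RNA": "rna_gene",
    "mobile_element": "insertion_element",
    "repeat_region": "repeat_region",
    "rep_origin": "origin",
}

#: regulatory table names accepted by :func:`parse_regulatory_tables`
REGULATORY_TABLES = (
    "operon",
    "transcription_unit",
    "promoter",
    "terminator",
    "attenuator",
    "shine_dalgarno",
    "riboswitch",
    "tfbs",
    "regulon",
    "sigmulon",
    "imodulon",
    "cog",
)


def _strand_of(biopython_strand) -> str:
    if biopython_strand == 1:
        return FORWARD
    if biopython_strand == -1:
        return REVERSE
    return UNSTRANDED


def parse_genbank(path):
    """Parse a single-record GenBank file.

    Returns ``(sequence, features, genome_length)``. CDS, pseudogenes,
    RNA genes, mobile elements, repeat regions and the replication origin
    become :class:`FeatureRecord` objects; 1-based inclusive GenBank
    coordinates become 0-based half-open.

    Raises ``ValueError`` for multi-record files and for features extending
    beyond the sequence end of a non-circular record.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected a single GenBank record, found {len(records)}")
    record = records[0]
    sequence = str(record.seq).upper()
    genome_length = len(sequence)
    circular = record.annotations.get("topology", "linear") == "circular"

    features: list[FeatureRecord] = []
    counters: dict[str, int] = {}
    for feat in record.features:
        if feat.type == "gene":
            # pseudogenes are annotated on the gene feature; CDS carries the rest
            if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
                rec = _genbank_feature_record(
                    feat, "pseudogene", genome_length, circular, counters
                )
                features.append(rec)
            continue
        category = _GENBANK_CATEGORY.get(feat.type)
        if category is None:
            continue
        rec = _genbank_feature_record(feat, category, genome_length, circular, counters)
        features.append(rec)
    return sequence, features, genome_length


def _genbank_feature_record(feat, category, genome_length, circular, counters):
    strand = _strand_of(feat.location.strand)
    intervals = []
    for part in sorted(feat.location.parts, key=lambda p: int(p.start)):
        start, end = int(part.start), int(part.end)
        if end > genome_length:
            if not circular:
                raise ValueError(
                    f"feature at [{start}, {end}) extends beyond sequence end "
                    f"{genome_length} on a non-circular record"
                )
            intervals.append(
                GenomicInterval(start, end - genome_length, strand, wraps=True)
            )
        else:
            intervals.append(GenomicInterval(start, end, strand))
    quals = feat.qualifiers
    locus_tag = quals.get("locus_tag", [None])[0]
    if locus_tag is None:
        counters[category] = counters.get(category, 0) + 1
        locus_tag = f"{category}_{counters[category]}"
    attributes = {}
    if "translation" in quals:
        attributes["translation"] = quals["translation"][0]
    if "transl_except" in quals:
        attributes["transl_except"] = quals["transl_except"][0]
    if "product" in quals:
        attributes["product"] = quals["product"][0]
    return FeatureRecord(
        id=locus_tag,
        category=category,
        intervals=intervals,
        strand=strand,
        attributes=attributes,
    )


def _parse_strand(value: str) -> str:
    value = str(value).strip()
    if value in ("+", "1", "forward"):
        return FORWARD
    if value in ("-", "-1", "reverse"):
        return REVERSE
    if value in (".", "", "none", "nan"):
        return UNSTRANDED
    raise ValueError(f"unparseable strand {value!r}")


def _interval_from_row(row, line_no, strand, left_col="left", right_col="right"):
    try:
        left = int(row[left_col])
        right = int(row[right_col])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"line {line_no}: malformed coordinates") from exc
    if left < 1 or right < left:
        raise ValueError(f"line {line_no}: malformed coordinates ({left}, {right})")
    return GenomicInterval(left - 1, right, strand)


def parse_regulatory_tables(paths, genes):
    """Read regulatory feature tables and apply linking/exclusion filters.

    ``paths`` maps a table name (one of :data:`REGULATORY_TABLES`) to a TSV
    path. ``genes`` supplies the reference-genome locus tags used for
    linking. Filters applied:

    * promoters without a transcription-unit link are dropped,
    * operons and transcription units linked to no reference-genome gene are
      dropped,
    * links naming unknown locus tags are warned about and removed.

    Genes left with no surviving operon/TU link can be listed with
    :func:`orphan_locus_tags`.
    """
    known_tags = {g.id for g in genes}
    out: list[FeatureRecord] = []
    tu_ids: set[str] = set()

    # first pass: everything except promoters, so TU ids exist for filtering
    deferred_promoters = []
    for name, path in paths.items():
        if name not in REGULATORY_TABLES:
            raise ValueError(f"unknown regulatory table {name!r}")
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for idx, row in df.iterrows():
            line_no = idx + 2  # header is line 1
            if name == "promoter":
                deferred_promoters.append((row, line_no))
                continue
            out.extend(_regulatory_records(name, row, line_no, known_tags))

    tu_ids = {r.id for r in out if r.category == "transcription_unit"}
    for row, line_no in deferred_promoters:
        out.extend(_promoter_records(row, line_no, known_tags, tu_ids))

    # drop operons/TUs with no gene link
    out = [
        r
        for r in out
        if r.category not in ("operon", "transcription_unit") or r.links
    ]
    return out


def orphan_locus_tags(genes, regulatory):
    """Locus tags of genes linked to no surviving operon or TU."""
    linked = set()
    for rec in regulatory:
        if rec.category in ("operon", "transcription_unit"):
            linked |= rec.links
    return sorted({g.id for g in genes} - linked)


def _split_links(value, line_no, known_tags, record_desc):
    links = set()
    for tag in str(value).split(","):
        tag = tag.strip()
        if not tag:
            continue
        if tag not in known_tags:
            log.warning("line %d: %s links unknown locus tag %r; link dropped",
                        line_no, record_desc, tag)
            continue
        links.add(tag)
    return links


def _regulatory_records(name, row, line_no, known_tags):
    rec_id = str(row["id"]).strip()
    links = _split_links(row.get("linked_locus_tags", ""), line_no, known_tags, rec_id)
    if name in LINKED_CATEGORIES:
        return [
            FeatureRecord(
                id=rec_id,
                category=name,
                subtype=str(row["subtype"]).strip() if "subtype" in row and str(row["subtype"]).strip() else rec_id,
                links=links,
            )
        ]
    strand = _parse_strand(row.get("strand", "."))
    interval = _interval_from_row(row, line_no, strand)
    subtype = str(row["subtype"]).strip() if "subtype" in row and str(row["subtype"]).strip() else None
    return [
        FeatureRecord(
            id=rec_id,
            category=name,
            intervals=[interval],
            strand=strand,
            subtype=subtype,
            links=links,
        )
    ]


def _promoter_records(row, line_no, known_tags, tu_ids):
    """Build a promoter record plus its -10/-35/TSS sub-element records.

    Promoters must link to at least one known transcription unit; the TU ids
    go in ``attributes['tu_links']`` (links proper are reserved for locus
    tags). Sub-elements that are present in the row become their own records
    so they can occupy their own matrix rows.
    """
    rec_id = str(row["id"]).strip()
    tu_links = {
        t.strip()
        for t in str(row.get("tu_links", row.get("linked_locus_tags", ""))).split(",")
        if t.strip()
    }
    tu_links &= tu_ids
    if not tu_links:
        return []  # promoters not linked to a TU are excluded
    strand = _parse_strand(row.get("strand", "."))
    records = []
    attributes = {"tu_links": sorted(tu_links)}

    tss_val = str(row.get("tss", "")).strip()
    elements = []
    if tss_val:
        tss = int(tss_val) - 1
        attributes["tss"] = tss
        elements.append(
            FeatureRecord(
                id=f"{rec_id}_tss",
                category="tss",
                intervals=[GenomicInterval(tss, tss + 1, strand)],
                strand=strand,
                attributes={"promoter": rec_id},
            )
        )
    for box in ("minus10", "minus35"):
        left = str(row.get(f"{box}_left", "")).strip()
        right = str(row.get(f"{box}_right", "")).strip()
        if left and right:
            iv = _interval_from_row(
                row, line_no, strand, f"{box}_left", f"{box}_right"
            )
            attributes[box] = iv
            elements.append(
                FeatureRecord(
                    id=f"{rec_id}_{box}",
                    category=box,
                    intervals=[iv],
                    strand=strand,
                    attributes={"promoter": rec_id},
                )
            )

    spans = [attributes[k] for k in ("minus10", "minus35") if k in attributes]
    left = min([iv.start for iv in spans] + ([attributes["tss"]] if "tss" in attributes else []))
    right = max([iv.end for iv in spans] + ([attributes["tss"] + 1] if "tss" in attributes else []))
    if "left" in row and str(row["left"]).strip():
        iv = _interval_from_row(row, line_no, strand)
        left, right = iv.start, iv.end
    records.append(
        FeatureRecord(
            id=rec_id,
            category="promoter",
            intervals=[GenomicInterval(left, right, strand)],
            strand=strand,
            attributes=attributes,
        )
    )
    records.extend(elements)
    return records


def write_regulatory_table(records, path, name):
    """Write records of one regulatory class back to the TSV dialect."""
    rows = []
    for rec in records:
        if rec.category != name:
            continue
        row = {"id": rec.id, "linked_locus_tags": ",".join(sorted(rec.links))}
        if rec.intervals:
            row["left"] = rec.start + 1
            row["right"] = rec.end
            row["strand"] = rec.strand
        if rec.subtype and rec.subtype != rec.id:
            row["subtype"] = rec.subtype
        if name == "promoter":
            row["tu_links"] = ",".join(rec.attributes.get("tu_links", []))
            if "tss" in rec.attributes:
                row["tss"] = rec.attributes["tss"] + 1
            for box in ("minus10", "minus35"):
                if box in rec.attributes:
                    iv = rec.attributes[box]
                    row[f"{box}_left"] = iv.start + 1
                    row[f"{box}_right"] = iv.end
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_snp_table(path, genome_length=None):
    """Read SNPs from a TSV (``position``/``ref``/``alt``/``experiment``) or
    a minimal VCF. Only single-nucleotide substitutions are kept; skipped
    indel rows are counted in the log. 1-based input positions become
    0-based."""
    path = Path(path)
    snps: list[SNPRecord] = []
    skipped = 0
    if path.suffix.lower() == ".vcf":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, pos, _id, ref, alt = fields[:5]
                for alt_allele in alt.split(","):
                    if len(ref) != 1 or len(alt_allele) != 1 or ref == alt_allele:
                        skipped += 1
                        continue
                    snps.append(
                        SNPRecord(int(pos) - 1, ref.upper(), alt_allele.upper(), chrom)
                    )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for _, row in df.iterrows():
            ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                skipped += 1
                continue
            snps.append(
                SNPRecord(int(row["position"]) - 1, ref, alt, str(row.get("experiment", "")))
            )
    if skipped:
        log.info("%s: skipped %d non-SNP rows", path, skipped)
    if genome_length is not None:
        for snp in snps:
            if snp.position >= genome_length:
                raise ValueError(
                    f"SNP position {snp.position + 1} beyond genome length {genome_length}"
                )
    return snps


def parse_label_table(path, genes, default=0):
    """Read a binary gene-label TSV. Genes absent from the table receive
    ``default`` (essentiality-style tables typically list one class only).
    Conflicting duplicate rows raise ``ValueError``."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": str})
    labels: dict[str, int] = {}
    if len(df):
        for _, row in df.iterrows():
            tag = str(row["locus_tag"])
            label = int(row["label"])
            if label not in (0, 1):
                raise ValueError(f"non-binary label {label} for {tag}")
            if tag in labels and labels[tag] != label:
                raise ValueError(f"conflicting duplicate labels for locus tag {tag}")
            labels[tag] = label
    return {g.id: labels.get(g.id, default) for g in genes}


def parse_structural_table(path, cds_features):
    """Read per-residue structural annotations into codon-space features.

    TSV columns: ``locus_tag``, ``residue_index`` (0-based), ``track``
    (``secondary_structure`` or ``exposure``), ``value`` (e.g. helix, sheet,
    loop, exposed, buried). Each residue maps to the three genomic positions
    of its codon on the linked CDS.
    """
    cds_by_tag = {c.id: c for c in cds_features if c.category == "cds"}
    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": str, "value": str})
    records = []
    for (tag, track, value), group in df.groupby(["locus_tag", "track", "value"]):
        cds = cds_by_tag.get(tag)
        if cds is None:
            log.warning("structural table references unknown locus tag %r", tag)
            continue
        if track not in ("secondary_structure", "exposure"):
            raise ValueError(f"unknown structural track {track!r}")
        coding = _coding_positions(cds)
        intervals = []
        for residue in sorted(int(r) for r in group["residue_index"]):
            pos = coding[3 * residue : 3 * residue + 3]
            if len(pos) < 3:
                raise ValueError(f"residue {residue} outside CDS {tag}")
            intervals.extend(_runs_to_intervals(pos, cds.strand))
        records.append(
            FeatureRecord(
                id=f"{tag}_{track}_{value}",
                category=track,
                subtype=str(value),
                intervals=_merge_intervals(intervals, cds.strand),
                strand=cds.strand,
                links={tag},
            )
        )
    return records


def _coding_positions(cds):
    """Genomic positions of a CDS in coding (5'->3') order."""
    import numpy as np

    parts = sorted(cds.intervals, key=lambda iv: iv.start)
    pos = np.concatenate([iv.positions() for iv in parts])
    if cds.strand == REVERSE:
        pos = pos[::-1]
    return pos


def _runs_to_intervals(positions, strand):
    import numpy as np

    positions = np.sort(np.asarray(positions))
    breaks = np.where(np.diff(positions) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(positions) - 1]])
    return [
        GenomicInterval(int(positions[s]), int(positions[e]) + 1, strand)
        for s, e in zip(starts, ends)
    ]


def _merge_intervals(intervals, strand):
    if not intervals:
        return []
    intervals = sorted(intervals, key=lambda iv: iv.start)
    merged = [intervals[0]]
    for iv in intervals[1:]:
        if iv.start <= merged[-1].end:
            merged[-1] = GenomicInterval(
                merged[-1].start, max(merged[-1].end, iv.end), strand
            )
        else:
            merged.append(iv)
    return merged


def interval_to_genbank(interval: GenomicInterval) -> str:
    """Render an interval back to GenBank 1-based inclusive location text."""
    base = f"{interval.start + 1}..{interval.end}"
    if interval.strand == REVERSE:
        return f"complement({base})"
    return base
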