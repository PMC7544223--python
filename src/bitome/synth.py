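"""Synthetic genome + annotation generator.

Emulates the geometry the analyses consume — operons/transcription units
with 5'/3' UTRs, promoters with -10/-35 boxes at canonical offsets from
the TSS, TF binding sites in inter-TU gaps, regulon/sigmulon/i-modulon
gene sets, COG assignments, SNP tables with a configurable bit-count bias,
and label vectors driven by planted informative features — without any
attempt to match real codon usage or GC skew.

Every planted quantity is recorded in a truth dictionary so tests compare
analysis output to the generator's ground truth rather than to constants.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .core import _CODON_TABLE, reverse_complement
from .types import FORWARD, REVERSE, FeatureRecord, GenomicInterval, SNPRecord

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")
_COG_LETTERS = "CEGHJKLMOPT"
_TF_NAMES = ("ArcA", "Crp", "Fnr", "Fis", "Lrp", "GadX", "Fur", "HNS")


@dataclass
class SNPModel:
    """How SNP positions are drawn.

    ``odds_ratio`` multiplies the sampling odds of positions whose column
    bit count is strictly below the median of the candidate positions
    (odds_ratio > 1 biases SNPs toward feature-poor positions, as observed
    for adaptive mutations). ``aa_enrichment`` maps amino-acid subtype
    (three-letter code) to an extra multiplicative weight on its codon
    positions.
    """

    count: int = 800
    odds_ratio: float = 2.0
    aa_enrichment: dict = field(default_factory=dict)


@dataclass
class LabelModel:
    """Gene labels from a logistic model over collapsed gene features.

    ``informative`` maps row-key strings (``category|subtype|strand|frame``
    or just ``category|subtype`` to match all strand/frame variants) to
    effect sizes on min/max-normalized gene features. ``noise_rate`` flips
    labels independently after sampling.
    """

    informative: dict = field(default_factory=dict)
    intercept: float | None = None  # None = auto-center for ~balanced classes
    noise_rate: float = 0.05


@dataclass
class SyntheticConfig:
    genome_length: int | None = None  # None: sized to fit the layout
    n_operons: int = 30
    mean_extra_genes: float = 0.7  # genes/operon = 1 + Poisson(this)
    gene_length_mean: int = 900  # bp, rounded to codons
    gene_length_sd: int = 250
    gene_length_min: int = 150
    utr5_mean: float = 50.0  # geometric-ish, matching ~50 bp medians
    utr3_mean: float = 50.0
    intergenic_in_tu: tuple = (0, 40)  # uniform spacer between genes in a TU
    gap_range: tuple = (50, 300)  # inter-TU gap ahead of each operon
    minus10_offset: int = 11  # TSS to -10 center
    minus35_offset: int = 33  # TSS to -35 center
    offset_jitter: int = 1
    box_length: int = 6
    tfbs_probability: float = 0.5  # per inter-TU gap
    tfbs_length: int = 16
    terminator_length: int = 12
    n_regulons: int = 4
    regulon_membership_p: float = 0.2
    n_sigmulons: int = 2
    n_imodulons: int = 3
    include_selenocysteine: bool = True
    n_pseudogenes: int = 1
    n_rna_genes: int = 2
    snp_model: SNPModel = field(default_factory=SNPModel)
    label_model: LabelModel = field(default_factory=LabelModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_operons < 0 or self.gene_length_min < 9:
            raise ValueError("invalid synthetic config")
        if not 0 <= self.regulon_membership_p <= 1:
            raise ValueError("membership probability outside [0, 1]")


def _random_orf(rng, n_codons, sec_index=None):
    """Coding sequence with start, non-stop body, terminal stop; optionally
    one internal UGA recoded as selenocysteine."""
    codons = ["ATG"]
    translation = ["M"]
    for i in range(1, n_codons - 1):
        if sec_index is not None and i == sec_index:
            codons.append("TGA")
            translation.append("U")
        else:
            codon = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
            codons.append(codon)
            translation.append(_CODON_TABLE[codon])
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons), "".join(translation)


def _geometric_len(rng, mean):
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def generate_annotation(config: SyntheticConfig):
    """Lay out operons, genes, promoters and regulatory sets.

    Returns ``(sequence, features, truth)``. The layout walks left to
    right: an inter-TU gap (holding the promoter and possibly a TFBS), then
    the TU (5' UTR, genes with small spacers, 3' UTR), alternating strands
    at random. Miscellaneous non-TU features (pseudogene, RNA genes, repeat
    region, insertion element, origin) occupy a tail region.
    """
    rng = np.random.default_rng(config.seed)
    truth = {
        "utr5": [], "utr3": [], "minus10_distances": [], "minus35_distances": [],
        "spacers": [], "genes": [], "tu_intervals": [], "regulons": {},
    }
    features: list[FeatureRecord] = []
    segments = []  # (position, sequence) to paste over the random background
    cursor = 0
    gene_counter = 0
    sec_gene_assigned = not config.include_selenocysteine

    for op_i in range(config.n_operons):
        gap = int(rng.integers(*config.gap_range))
        gap = max(gap, config.minus35_offset + config.box_length + 5)
        tu_left = cursor + gap
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        n_genes = 1 + int(rng.poisson(config.mean_extra_genes))
        utr5 = max(1, _geometric_len(rng, config.utr5_mean))
        utr3 = max(1, _geometric_len(rng, config.utr3_mean))

        gene_lengths, spacers = [], []
        for g in range(n_genes):
            n_codons = max(
                config.gene_length_min // 3,
                int(rng.normal(config.gene_length_mean, config.gene_length_sd)) // 3,
            )
            gene_lengths.append(3 * n_codons)
            spacers.append(0 if g == 0 else int(rng.integers(*config.intergenic_in_tu)))

        body = sum(gene_lengths) + sum(spacers)
        left_pad, right_pad = (utr5, utr3) if strand == FORWARD else (utr3, utr5)
        tu_right = tu_left + left_pad + body + right_pad

        gene_ids = []
        offset = tu_left + left_pad
        ordered = list(range(n_genes))
        for g in ordered:
            offset += spacers[g]
            length = gene_lengths[g]
            sec_index = None
            if not sec_gene_assigned and length // 3 > 4:
                sec_index = int(rng.integers(2, length // 3 - 2))
                sec_gene_assigned = True
            cds_seq, translation = _random_orf(rng, length // 3, sec_index)
            gene_counter += 1
            tag = f"b{gene_counter:04d}"
            gene_ids.append(tag)
            genomic_seq = cds_seq if strand == FORWARD else reverse_complement(cds_seq)
            segments.append((offset, genomic_seq))
            attrs = {"translation": translation}
            if sec_index is not None:
                attrs["transl_except"] = f"(pos:{sec_index},aa:Sec)"
            features.append(
                FeatureRecord(
                    id=tag, category="cds",
                    intervals=[GenomicInterval(offset, offset + length, strand)],
                    strand=strand, attributes=attrs,
                )
            )
            truth["genes"].append(
                {"id": tag, "start": offset, "end": offset + length,
                 "strand": strand, "frame": offset % 3}
            )
            offset += length

        tu_id = f"TU{op_i + 1:03d}"
        tu_iv = GenomicInterval(tu_left, tu_right, strand)
        features.append(
            FeatureRecord(id=tu_id, category="transcription_unit",
                          intervals=[tu_iv], strand=strand, links=set(gene_ids))
        )
        features.append(
            FeatureRecord(id=f"OP{op_i + 1:03d}", category="operon",
                          intervals=[tu_iv], strand=strand, links=set(gene_ids))
        )
        truth["tu_intervals"].append([tu_left, tu_right, strand])
        truth["utr5"].append(utr5)
        truth["utr3"].append(utr3)

        # promoter upstream of the TSS (TU 5' end)
        d10 = config.minus10_offset + int(rng.integers(-config.offset_jitter,
                                                       config.offset_jitter + 1))
        d35 = config.minus35_offset + int(rng.integers(-config.offset_jitter,
                                                       config.offset_jitter + 1))
        half = config.box_length // 2
        if strand == FORWARD:
            tss = tu_left
            b10 = GenomicInterval(tss - d10 - half, tss - d10 + half, strand)
            b35 = GenomicInterval(tss - d35 - half, tss - d35 + half, strand)
            spacer = b10.start - b35.end
        else:
            tss = tu_right - 1
            b10 = GenomicInterval(tss + d10 - half, tss + d10 + half, strand)
            b35 = GenomicInterval(tss + d35 - half, tss + d35 + half, strand)
            spacer = b35.start - b10.end
        features.append(
            FeatureRecord(
                id=f"P{op_i + 1:03d}", category="promoter",
                intervals=[GenomicInterval(
                    min(b35.start, b10.start, tss), max(b35.end, b10.end, tss + 1), strand)],
                strand=strand,
                attributes={"tss": tss, "minus10": b10, "minus35": b35,
                            "tu_links": [tu_id]},
            )
        )
        for box_name, box in (("minus10", b10), ("minus35", b35)):
            features.append(
                FeatureRecord(id=f"P{op_i + 1:03d}_{box_name}", category=box_name,
                              intervals=[box], strand=strand,
                              attributes={"promoter": f"P{op_i + 1:03d}"})
            )
        features.append(
            FeatureRecord(id=f"P{op_i + 1:03d}_tss", category="tss",
                          intervals=[GenomicInterval(tss, tss + 1, strand)],
                          strand=strand, attributes={"promoter": f"P{op_i + 1:03d}"})
        )
        truth["minus10_distances"].append(d10)
        truth["minus35_distances"].append(d35)
        truth["spacers"].append(spacer)

        # terminator at the TU 3' end
        term_iv = (
            GenomicInterval(tu_right - config.terminator_length, tu_right, strand)
            if strand == FORWARD
            else GenomicInterval(tu_left, tu_left + config.terminator_length, strand)
        )
        features.append(
            FeatureRecord(id=f"T{op_i + 1:03d}", category="terminator",
                          intervals=[term_iv], strand=strand, links=set(gene_ids))
        )

        # occasional TFBS in the preceding inter-TU gap
        if rng.random() < config.tfbs_probability and gap > config.tfbs_length + 45:
            site_start = cursor + int(rng.integers(0, gap - config.tfbs_length - 40))
            tf = _TF_NAMES[rng.integers(len(_TF_NAMES))]
            features.append(
                FeatureRecord(
                    id=f"TFBS{op_i + 1:03d}", category="tfbs", subtype=tf,
                    intervals=[GenomicInterval(site_start,
                                               site_start + config.tfbs_length)],
                    links=set(gene_ids),
                )
            )
        cursor = tu_right

    # tail with miscellaneous non-TU features
    tail_start = cursor + 100
    offset = tail_start
    misc = []
    for i in range(config.n_pseudogenes):
        misc.append(("pseudogene", 450, f"psg{i + 1}"))
    for i in range(config.n_rna_genes):
        misc.append(("rna_gene", 76, f"rna{i + 1}"))
    misc += [("repeat_region", 200, "rep1"), ("insertion_element", 700, "ins1"),
             ("origin", 100, "oriC")]
    for category, length, name in misc:
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        if category == "origin":
            strand = FORWARD
        features.append(
            FeatureRecord(id=name, category=category,
                          intervals=[GenomicInterval(offset, offset + length, strand)],
                          strand=strand)
        )
        offset += length + int(rng.integers(30, 120))

    required = offset + 50
    if config.genome_length is None:
        genome_length = required
    else:
        genome_length = config.genome_length
        if required > genome_length:
            raise ValueError(
                f"layout needs {required} bp but genome_length is {genome_length}"
            )

    seq = rng.choice(list("ACGT"), size=genome_length)
    sequence = "".join(seq)
    for pos, sub in segments:
        sequence = sequence[:pos] + sub + sequence[pos + len(sub):]

    # gene-set features
    gene_tags = [g["id"] for g in truth["genes"]]
    for r in range(config.n_regulons):
        members = {t for t in gene_tags if rng.random() < config.regulon_membership_p}
        name = f"Reg{r + 1}"
        truth["regulons"][name] = sorted(members)
        if members:
            features.append(FeatureRecord(id=name, category="regulon",
                                          subtype=name, links=members))
    for s in range(config.n_sigmulons):
        p = 0.5 if s == 0 else 0.15
        members = {t for t in gene_tags if rng.random() < p}
        if members:
            features.append(FeatureRecord(id=f"Sig{s + 1}", category="sigmulon",
                                          subtype=f"Sig{s + 1}", links=members))
    for m in range(config.n_imodulons):
        members = {t for t in gene_tags if rng.random() < 0.15}
        if members:
            features.append(FeatureRecord(id=f"iM{m + 1}", category="imodulon",
                                          subtype=f"iM{m + 1}", links=members))
    cogs: dict[str, set] = {}
    for tag in gene_tags:
        cogs.setdefault(_COG_LETTERS[rng.integers(len(_COG_LETTERS))], set()).add(tag)
    for letter, members in sorted(cogs.items()):
        features.append(FeatureRecord(id=f"COG_{letter}", category="cog",
                                      subtype=letter, links=members))

    truth["genome_length"] = genome_length
    truth["n_genes"] = len(gene_tags)
    return sequence, features, truth


def generate_snps(bitome, config: SNPModel, rng=None, positions=None, sequence=None):
    """Draw SNP positions with odds biased by column bit count.

    Candidate positions (default: every genomic position) below the median
    bit count of the candidate set get sampling odds multiplied by
    ``config.odds_ratio``; amino-acid-specific enrichments multiply further.
    Positions are drawn without replacement. Returns
    ``(snps, truth)`` with realized per-stratum counts.
    """
    rng = np.random.default_rng() if rng is None else rng
    sequence = bitome.sequence if sequence is None else sequence
    counts = bitome.column_bit_counts()
    if positions is None:
        positions = np.arange(bitome.n_cols)
    positions = np.asarray(positions)
    sub_counts = counts[positions]
    median = np.median(sub_counts)
    low = sub_counts < median
    weights = np.where(low, config.odds_ratio, 1.0)
    for aa, factor in config.aa_enrichment.items():
        aa_rows = bitome.select_rows(
            lambda k, aa=aa: k.category == "amino_acid" and k.subtype == aa
        )
        covered = np.flatnonzero(aa_rows.column_bit_counts() > 0)
        weights[np.isin(positions, covered)] *= factor
    if config.count > positions.size:
        raise ValueError("more SNPs requested than candidate positions")
    probs = weights / weights.sum()
    chosen = rng.choice(positions, size=config.count, replace=False, p=probs)
    chosen.sort()
    bases = "ACGT"
    snps = []
    for pos in chosen:
        ref = sequence[pos].upper() if sequence else "A"
        if ref not in bases:
            ref = "A"
        alt = bases[rng.integers(4)]
        while alt == ref:
            alt = bases[rng.integers(4)]
        snps.append(SNPRecord(int(pos), ref, alt, f"exp{int(rng.integers(1, 6))}"))
    truth = {
        "n_snps": len(snps),
        "median_bit_count": float(median),
        "low_stratum_snps": int(np.isin(chosen, positions[low]).sum()),
        "low_stratum_positions": int(low.sum()),
        "odds_ratio": config.odds_ratio,
    }
    return snps, truth


def _sigmoid(x):
    from scipy.special import expit

    return expit(x)


def generate_labels(gene_matrix, config: LabelModel, rng=None):
    """Binary labels from a logistic model over the gene feature matrix.

    ``gene_matrix`` is a :class:`~bitome.ml.GeneFeatureMatrix`; informative
    effects act on min/max-normalized feature columns. Returns
    ``(labels, truth)``.
    """
    from .ml import minmax_normalize

    rng = np.random.default_rng() if rng is None else rng
    values = minmax_normalize(gene_matrix.values)
    z = np.zeros(values.shape[0])
    used = []
    for key_str, effect in config.informative.items():
        matched = [
            i for i, k in enumerate(gene_matrix.feature_keys)
            if str(k) == key_str or str(k).startswith(key_str + "|")
            or f"{k.category}|{k.subtype}" == key_str
        ]
        if not matched:
            raise ValueError(f"informative key {key_str!r} matches no feature")
        for i in matched:
            z += effect * values[:, i]
            used.append(str(gene_matrix.feature_keys[i]))
    intercept = config.intercept
    if intercept is None:
        intercept = -float(np.median(z))
    z = z + intercept
    labels = (rng.random(len(z)) < _sigmoid(z)).astype(int)
    flips = rng.random(len(z)) < config.noise_rate
    labels[flips] = 1 - labels[flips]
    truth = {
        "informative_features": used,
        "intercept": intercept,
        "n_flipped": int(flips.sum()),
        "positive_rate": float(labels.mean()),
    }
    return labels, truth


# -- fixture emission -----------------------------------------------------


def write_genbank(sequence, features, path, circular=False):
    """Emit the genome + core features as a standard GenBank record."""
    record = SeqRecord(
        Seq(sequence), id="SYNTH01", name="SYNTH01",
        description="synthetic genome fixture",
        annotations={"molecule_type": "DNA",
                     "topology": "circular" if circular else "linear"},
    )
    for feat in features:
        if feat.category not in ("cds", "pseudogene", "rna_gene",
                                 "insertion_element", "repeat_region", "origin"):
            continue
        strand = 1 if feat.strand == FORWARD else (-1 if feat.strand == REVERSE else None)
        loc = FeatureLocation(feat.start, feat.end, strand)
        if feat.category == "cds":
            qualifiers = {"locus_tag": [feat.id]}
            if "translation" in feat.attributes:
                qualifiers["translation"] = [feat.attributes["translation"]]
            if "transl_except" in feat.attributes:
                qualifiers["transl_except"] = [feat.attributes["transl_except"]]
            record.features.append(SeqFeature(loc, type="CDS", qualifiers=qualifiers))
            record.features.append(
                SeqFeature(loc, type="gene", qualifiers={"locus_tag": [feat.id]})
            )
        elif feat.category == "pseudogene":
            record.features.append(
                SeqFeature(loc, type="gene",
                           qualifiers={"locus_tag": [feat.id], "pseudo": [""]})
            )
        elif feat.category == "rna_gene":
            record.features.append(
                SeqFeature(loc, type="tRNA", qualifiers={"locus_tag": [feat.id]})
            )
        elif feat.category == "insertion_element":
            record.features.append(
                SeqFeature(loc, type="mobile_element",
                           qualifiers={"mobile_element_type": ["insertion sequence"]})
            )
        elif feat.category == "repeat_region":
            record.features.append(SeqFeature(loc, type="repeat_region"))
        elif feat.category == "origin":
            record.features.append(SeqFeature(loc, type="rep_origin"))
    SeqIO.write(record, str(path), "genbank")


def write_snp_table(snps, path):
    with open(path, "w") as fh:
        fh.write("position\tref\talt\texperiment\n")
        for s in snps:
            fh.write(f"{s.position + 1}\t{s.ref}\t{s.alt}\t{s.source_id}\n")


def write_label_table(labels_by_tag, path):
    with open(path, "w") as fh:
        fh.write("locus_tag\tlabel\n")
        for tag, label in labels_by_tag.items():
            fh.write(f"{tag}\t{label}\n")


def write_fixture(config: SyntheticConfig, outdir):
    """Generate a complete fixture directory.

    Writes ``genome.gb``, ``regulatory/*.tsv``, ``snps.tsv``,
    ``labels.tsv`` and ``truth.json``; returns the truth dictionary.
    """
    from . import annotation_io
    from .core import BuildConfig, build
    from .ml import gene_feature_vectors

    outdir = Path(outdir)
    (outdir / "regulatory").mkdir(parents=True, exist_ok=True)
    sequence, features, truth = generate_annotation(config)
    rng = np.random.default_rng(config.seed + 1)

    write_genbank(sequence, features, outdir / "genome.gb")
    for name in ("operon", "transcription_unit", "promoter", "terminator",
                 "tfbs", "regulon", "sigmulon", "imodulon", "cog"):
        annotation_io.write_regulatory_table(
            features, outdir / "regulatory" / f"{name}.tsv", name
        )

    bitome = build(sequence, features, BuildConfig())
    snps, snp_truth = generate_snps(bitome, config.snp_model, rng)
    write_snp_table(snps, outdir / "snps.tsv")
    truth["snps"] = snp_truth

    genes = [f for f in features if f.category == "cds"]
    label_cfg = config.label_model
    if not label_cfg.informative:
        regs = sorted({k.subtype for k in bitome.row_keys if k.category == "regulon"})
        label_cfg = LabelModel(
            informative={f"regulon|{r}": 6.0 for r in regs[:2]},
            noise_rate=label_cfg.noise_rate,
        )
    gm = gene_feature_vectors(bitome, genes, collapse="mean")
    labels, label_truth = generate_labels(gm, label_cfg, rng)
    write_label_table(dict(zip(gm.gene_ids, (int(x) for x in labels))),
                      outdir / "labels.tsv")
    truth["labels"] = label_truth

    truth["config"] = {
        k: v for k, v in asdict(config).items() if k not in ("snp_model", "label_model")
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
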