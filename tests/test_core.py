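"""Matrix assembly: row splitting, derived tracks, binarity, extraction."""

import numpy as np
import pytest

from bitome import core
from bitome.core import BuildConfig, Bitome, assign_row_keys, build, frame_of
from bitome.types import (
    FORWARD,
    REVERSE,
    FeatureRecord,
    GenomicInterval,
    RowKey,
)


def _cds(tag, start, end, strand=FORWARD, translation=None):
    attrs = {"translation": translation} if translation else {}
    return FeatureRecord(id=tag, category="cds",
                         intervals=[GenomicInterval(start, end, strand)],
                         strand=strand, attributes=attrs)


def test_frame_of_matches_mod_table():
    assert frame_of(0) == 0 and frame_of(7) == 1
    rng = np.random.default_rng(0)
    for start in rng.integers(0, 10_000, size=300):
        assert frame_of(int(start)) == int(start) % 3


def test_assign_row_keys_by_category():
    cds = _cds("b1", 99, 159)
    [(key, _)] = assign_row_keys(cds)
    assert key == RowKey("cds", None, FORWARD, 0)
    tfbs = FeatureRecord(id="s1", category="tfbs", subtype="GadX",
                         intervals=[GenomicInterval(5, 21)])
    [(key, _)] = assign_row_keys(tfbs)
    assert key == RowKey("tfbs", "GadX", None, None)
    prom = FeatureRecord(id="p1", category="promoter",
                         intervals=[GenomicInterval(10, 40, REVERSE)],
                         strand=REVERSE)
    [(key, _)] = assign_row_keys(prom)
    assert key == RowKey("promoter", None, REVERSE, None)
    with pytest.raises(ValueError, match="bogus"):
        FeatureRecord(id="x", category="bogus")


def test_reverse_frame_anchor_is_configurable():
    cds = _cds("b1", 10, 70, REVERSE)
    assert core.coding_start_of(cds, "left") == 10
    assert core.coding_start_of(cds, "coding") == 69


def test_sequence_tracks_complement_and_conservation():
    records = core.derive_sequence_tracks("A")
    placed = {(r.subtype, r.strand, r.intervals[0].start) for r in records}
    assert placed == {("A", FORWARD, 0), ("T", REVERSE, 0)}

    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=211))
    records = core.derive_sequence_tracks(seq)
    total = sum(r.length() for r in records)
    assert total == 2 * len(seq)

    b = build("ACGT", [], BuildConfig())
    assert b.column_bit_counts().tolist() == [2, 2, 2, 2]


def test_codon_and_aa_tracks_forward():
    cds = _cds("b1", 0, 9, FORWARD)
    records = core.derive_codon_and_aa_tracks([cds], "ATGGCTTAA")
    codons = [r for r in records if r.category == "codon"]
    aas = [r for r in records if r.category == "amino_acid"]
    assert [c.subtype for c in codons] == ["ATG", "GCT", "TAA"]
    assert [(a.subtype, a.intervals[0].start, a.intervals[0].end) for a in aas] == [
        ("Met", 0, 3), ("Ala", 3, 6)
    ]


def test_codon_and_aa_tracks_reverse_mirrored():
    # reverse-strand CDS occupying [0,9) whose coding-strand sequence is
    # ATGGCTTAA: the genome holds its reverse complement
    genome = core.reverse_complement("ATGGCTTAA")
    cds = _cds("b1", 0, 9, REVERSE)
    records = core.derive_codon_and_aa_tracks([cds], genome)
    codons = [r for r in records if r.category == "codon"]
    assert [c.subtype for c in codons] == ["ATG", "GCT", "TAA"]
    # first codon occupies the rightmost three genomic positions
    assert (codons[0].intervals[0].start, codons[0].intervals[0].end) == (6, 9)
    assert (codons[2].intervals[0].start, codons[2].intervals[0].end) == (0, 3)


def test_codon_census_matches_three_mer_scan(synth_data):
    """Distinct codon subtypes equal an independent 3-mer scan of CDSs."""
    sequence, features, _ = synth_data
    expected = set()
    for f in features:
        if f.category != "cds":
            continue
        sub = sequence[f.start : f.end]
        if f.strand == REVERSE:
            sub = core.reverse_complement(sub)
        expected |= {sub[i : i + 3] for i in range(0, len(sub) - 2, 3)}
    records = core.derive_codon_and_aa_tracks(features, sequence)
    observed = {r.subtype for r in records if r.category == "codon"}
    assert observed == expected


def test_translation_overrides_naive_code(synth_data):
    """A recoded internal UGA (selenocysteine) yields a Sec residue."""
    sequence, features, _ = synth_data
    records = core.derive_codon_and_aa_tracks(features, sequence)
    assert "Sec" in {r.subtype for r in records if r.category == "amino_acid"}


def test_build_small_cds_placement():
    seq = "ATGGCTTAAG"
    b = build(seq, [_cds("b1", 2, 8)], BuildConfig(include_codon_tracks=False))
    key = RowKey("cds", None, FORWARD, 2)
    row = b.matrix[b.row_index(key)].toarray().ravel()
    assert np.flatnonzero(row).tolist() == [2, 3, 4, 5, 6, 7]


def test_build_empty_features_nucleobase_only():
    seq = "ACGTACGTAC"
    b = build(seq, [], BuildConfig())
    assert b.total_bits == 2 * len(seq)
    assert all(k.category == "nucleobase" for k in b.row_keys)


def _paint_oracle(sequence, features):
    """Independent position-painting oracle: a dense boolean grid filled
    feature-by-feature under the row rules, plus derived tracks."""
    n = len(sequence)
    grid = {}

    def paint(key, positions):
        grid.setdefault(key, np.zeros(n, dtype=bool))[positions] = True

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, base in enumerate(sequence):
        paint(("nucleobase", base, FORWARD, None), [i])
        paint(("nucleobase", comp[base], REVERSE, None), [i])

    genes = {f.id: f for f in features if f.category in ("cds", "pseudogene", "rna_gene")}
    for f in features:
        if f.category in ("regulon", "sigmulon", "imodulon", "cog"):
            for tag in f.links:
                g = genes[tag]
                pos = np.concatenate([iv.positions() for iv in g.intervals])
                if f.category == "cog":
                    paint((f.category, f.subtype, g.strand, g.start % 3), pos)
                else:
                    paint((f.category, f.subtype, None, None), pos)
            continue
        pos = np.concatenate([iv.positions() for iv in f.intervals])
        if f.category in ("cds", "pseudogene", "rna_gene"):
            paint((f.category, f.subtype, f.strand, f.start % 3), pos)
        elif f.category == "tfbs":
            paint((f.category, f.subtype, None, None), pos)
        else:
            strand = f.strand if f.strand != "." else FORWARD
            paint((f.category, f.subtype, strand, None), pos)
    # codon / amino-acid / protein tracks
    for f in features:
        if f.category != "cds":
            continue
        pos = np.concatenate([iv.positions() for iv in sorted(f.intervals, key=lambda iv: iv.start)])
        sub = sequence[f.start : f.end]
        if f.strand == REVERSE:
            sub = core.reverse_complement(sub)
            pos = pos[::-1]
        frame = f.start % 3
        translation = f.attributes.get("translation", "")
        protein_pos = []
        for i in range(len(pos) // 3):
            codon = sub[3 * i : 3 * i + 3]
            cpos = pos[3 * i : 3 * i + 3]
            paint(("codon", codon, f.strand, frame), cpos)
            letter = translation[i] if i < len(translation) else core.translate_codon(codon)
            if letter == "*":
                continue
            paint(("amino_acid", core._AA_1TO3[letter], f.strand, frame), cpos)
            protein_pos.append(cpos)
        if protein_pos:
            paint(("protein", None, f.strand, frame), np.concatenate(protein_pos))
    return grid


def test_build_matches_painting_oracle(synth_data):
    sequence, features, _ = synth_data
    b = build(sequence, features, BuildConfig())
    grid = _paint_oracle(sequence, features)
    assert set(map(tuple, b.row_keys)) == set(grid)
    assert b.total_bits == sum(g.sum() for g in grid.values())
    # per-column counts must agree exactly
    expected_cols = np.zeros(len(sequence), dtype=np.int64)
    for g in grid.values():
        expected_cols += g
    assert np.array_equal(b.column_bit_counts(), expected_cols)
    # spot-check full rows
    rng = np.random.default_rng(2)
    for key in rng.choice(len(b.row_keys), size=25, replace=False):
        key = b.row_keys[int(key)]
        row = b.matrix[b.row_index(key)].toarray().ravel().astype(bool)
        assert np.array_equal(row, grid[tuple(key)]), key


def test_binarity_readding_features_is_idempotent(synth_data):
    sequence, features, _ = synth_data
    once = build(sequence, features, BuildConfig())
    twice = build(sequence, features + [f for f in features if f.category == "cds"],
                  BuildConfig())
    assert once.total_bits == twice.total_bits
    assert (once.matrix != twice.matrix).nnz == 0


def test_frame_rows_disjoint_for_nonoverlapping_cds():
    seq = "ACGT" * 30
    cdss = [_cds("b1", 0, 12), _cds("b2", 13, 25), _cds("b3", 26, 38),
            _cds("b4", 40, 52, REVERSE)]
    b = build(seq, cdss, BuildConfig(include_codon_tracks=False))
    cds_rows = [k for k in b.row_keys if k.category == "cds"]
    cols = [set(np.flatnonzero(b.matrix[b.row_index(k)].toarray())) for k in cds_rows]
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            assert not cols[i] & cols[j]


def test_conservation_and_determinism(synth_data, tmp_path):
    sequence, features, _ = synth_data
    b = build(sequence, features, BuildConfig())
    assert b.total_bits == b.row_bit_counts().sum() == b.column_bit_counts().sum()
    b2 = build(sequence, features, BuildConfig())
    b.save(tmp_path / "a")
    b2.save(tmp_path / "b")
    for name in ("matrix.mtx", "row_keys.tsv", "header.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_save_load_round_trip(built, tmp_path):
    built.save(tmp_path / "bm")
    loaded = Bitome.load(tmp_path / "bm")
    assert loaded.row_keys == built.row_keys
    assert (loaded.matrix != built.matrix).nnz == 0
    assert loaded.sequence == built.sequence


def test_extract_identity_and_shift(built):
    whole = built.extract(GenomicInterval(0, built.n_cols))
    assert (whole.matrix != built.matrix).nnz == 0

    seq = "ATGGCTTAAG"
    b = build(seq, [_cds("b1", 2, 8)], BuildConfig(include_codon_tracks=False))
    sub = b.extract(GenomicInterval(2, 8))
    row = sub.matrix[sub.row_index(RowKey("cds", None, FORWARD, 2))].toarray().ravel()
    assert np.flatnonzero(row).tolist() == [0, 1, 2, 3, 4, 5]
    with pytest.raises(ValueError):
        b.extract(GenomicInterval(5, 5))


def test_extract_sum_equals_masked_sum(built):
    rng = np.random.default_rng(3)
    counts = built.column_bit_counts()
    for _ in range(100):
        start = int(rng.integers(0, built.n_cols - 2))
        end = int(rng.integers(start + 1, min(start + 3000, built.n_cols)))
        sub = built.extract(GenomicInterval(start, end))
        assert sub.total_bits == counts[start:end].sum()


def test_select_rows_partitions_bits(built):
    pred = lambda k: k.category in ("cds", "codon", "amino_acid")
    a = built.select_rows(pred)
    bcomp = built.select_rows(lambda k: not pred(k))
    assert a.total_bits + bcomp.total_bits == built.total_bits
    assert built.select_rows(lambda k: True).total_bits == built.total_bits
    nb = built.select_rows(lambda k: k.category == "nucleobase")
    only = nb.select_rows(lambda k: k.category == "cds")
    assert only.n_rows == 0


def test_wrapping_interval_on_circular_genome():
    seq = "ACGTACGTACGTACGTACGT"
    feat = FeatureRecord(
        id="ori", category="origin",
        intervals=[GenomicInterval(16, 4, FORWARD, wraps=True)], strand=FORWARD,
    )
    b = build(seq, [feat], BuildConfig(circular=True, include_codon_tracks=False))
    row = b.matrix[b.row_index(RowKey("origin", None, FORWARD, None))].toarray().ravel()
    assert np.flatnonzero(row).tolist() == [0, 1, 2, 3, 16, 17, 18, 19]
    sub = b.extract(GenomicInterval(16, 4, wraps=True))
    assert sub.n_cols == 8


def test_bed_export(built, tmp_path):
    path = tmp_path / "rows.bed"
    built.to_bed(path)
    lines = path.read_text().splitlines()
    total = 0
    for line in lines:
        _, start, end, *_ = line.split("\t")
        assert int(start) < int(end) <= built.n_cols
        total += int(end) - int(start)
    assert total == built.total_bits
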