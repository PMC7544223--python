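"""Coverage, density, intergenic geometry and folding-window statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bitome import core, metrics
from bitome.core import BuildConfig, build
from bitome.types import FORWARD, REVERSE, FeatureRecord, GenomicInterval


def _feat(cat, start, end, strand=FORWARD, links=None, tag="f"):
    return FeatureRecord(id=tag, category=cat,
                         intervals=[GenomicInterval(start, end, strand)],
                         strand=strand, links=links or set())


def test_column_counts_constant_on_nucleobase_matrix(nucleobase_only):
    counts = metrics.column_bit_counts(nucleobase_only)
    assert (counts == 2).all()


def test_column_counts_match_transpose_oracle(built):
    counts = metrics.column_bit_counts(built)
    oracle = np.asarray(built.matrix.T.sum(axis=1)).ravel()
    assert np.array_equal(counts, oracle)


def test_sequence_coverage_union_not_sum():
    seq = "ACGTACGTAC"
    feats = [_feat("operon", 0, 5, tag="o1"), _feat("terminator", 3, 8, tag="t1")]
    b = build(seq, feats, BuildConfig(include_nucleobase=False))
    assert metrics.sequence_coverage(b, lambda k: k.category == "operon") == 0.5
    assert metrics.sequence_coverage(b, lambda k: True) == pytest.approx(0.8)


def test_bit_density_identities(built, nucleobase_only):
    whole = GenomicInterval(0, built.n_cols)
    assert metrics.bit_density(built, whole) * built.n_cols == pytest.approx(
        built.total_bits
    )
    any_iv = GenomicInterval(13, 250)
    assert metrics.bit_density(nucleobase_only, any_iv) == 2.0

    counts = built.column_bit_counts()
    rng = np.random.default_rng(4)
    for _ in range(200):
        s = int(rng.integers(0, built.n_cols - 2))
        e = int(rng.integers(s + 1, min(s + 2000, built.n_cols)))
        assert metrics.bit_density(built, GenomicInterval(s, e)) == pytest.approx(
            counts[s:e].sum() / (e - s)
        )


def test_partition_weighted_mean_equals_global_density(built):
    cuts = [0, 1000, 5000, 17000, built.n_cols]
    total = 0.0
    for s, e in zip(cuts, cuts[1:]):
        total += metrics.bit_density(built, GenomicInterval(s, e)) * (e - s)
    assert total / built.n_cols == pytest.approx(built.total_bits / built.n_cols)


def test_moving_density_uniform_and_consistency(nucleobase_only):
    profile = metrics.moving_density(nucleobase_only, window=50, step=10)
    assert np.allclose(profile.values, 2.0) and profile.sd == 0.0
    single = metrics.moving_density(nucleobase_only, window=nucleobase_only.n_cols,
                                    step=10)
    assert single.values.size == 1
    assert single.values[0] == pytest.approx(
        metrics.bit_density(nucleobase_only, GenomicInterval(0, nucleobase_only.n_cols))
    )
    with pytest.raises(ValueError):
        metrics.moving_density(nucleobase_only, window=0)


def test_moving_density_peak_at_dense_block():
    seq = "A" * 2000
    feats = [_feat("operon", 1000, 1100, tag=f"o{i}") for i in range(5)]
    # five identical operon records OR to one row; add stacked categories
    feats = [_feat("operon", 1000, 1100, tag="o"),
             _feat("terminator", 1000, 1100, tag="t"),
             _feat("riboswitch", 1000, 1100, tag="r")]
    b = build(seq, feats, BuildConfig(include_nucleobase=False))
    profile = metrics.moving_density(b, window=100, step=100)
    expected = np.zeros(20)
    expected[10] = 3.0  # 100 bp block x 3 rows inside one window
    assert np.allclose(profile.values, expected)


def test_moving_density_wraps_on_circular_genome():
    seq = "ACGT" * 25
    b = build(seq, [], BuildConfig(circular=True))
    profile = metrics.moving_density(b, window=40, step=1)
    assert profile.values.size == 100  # one window per start, wrapping
    assert np.allclose(profile.values, 2.0)
    assert profile.mean == pytest.approx(b.total_bits / b.n_cols)


def test_feature_density_distribution_median():
    seq = "A" * 100
    f1 = _feat("operon", 0, 10, tag="o1")
    f2 = _feat("terminator", 0, 10, tag="t1")
    b = build(seq, [f1, f2], BuildConfig(include_nucleobase=False))
    lone = _feat("riboswitch", 50, 60, tag="r1")
    densities, median = metrics.feature_density_distribution(b, [f1, lone])
    assert densities == [2.0, 0.0] and median == 1.0


def test_feature_densities_on_nucleobase_matrix(nucleobase_only):
    feats = [_feat("operon", 10 * i, 10 * i + 10, tag=f"o{i}") for i in range(5)]
    densities, median = metrics.feature_density_distribution(nucleobase_only, feats)
    assert densities == [2.0] * 5 and median == 2.0


def test_utr_lengths_strand_aware():
    gene = [FeatureRecord(id="g", category="cds",
                          intervals=[GenomicInterval(20, 80, FORWARD)],
                          strand=FORWARD)]
    tu_f = [_feat("transcription_unit", 0, 100, FORWARD, links={"g"}, tag="tu")]
    five, three = metrics.utr_lengths(tu_f, gene)
    assert (five, three) == ([20], [20])

    gene_r = [FeatureRecord(id="g", category="cds",
                            intervals=[GenomicInterval(20, 80, REVERSE)],
                            strand=REVERSE)]
    tu_r = [_feat("transcription_unit", 0, 100, REVERSE, links={"g"}, tag="tu")]
    five, three = metrics.utr_lengths(tu_r, gene_r)
    assert (five, three) == ([20], [20])


def test_utr_lengths_recover_planted_distribution(synth_data):
    """Generator round-trip: measured UTRs equal the planted ones."""
    _, features, truth = synth_data
    tus = [f for f in features if f.category == "transcription_unit"]
    genes = [f for f in features if f.category == "cds"]
    five, three = metrics.utr_lengths(tus, genes)
    assert sorted(five) == sorted(v for v in truth["utr5"] if v > 0)
    assert sorted(three) == sorted(v for v in truth["utr3"] if v > 0)
    kept = metrics.iqr_filter(five)
    assert len(kept) <= len(five) and np.median(kept) <= np.max(five)


def test_promoter_geometry_arithmetic():
    prom = FeatureRecord(
        id="p", category="promoter",
        intervals=[GenomicInterval(60, 101, FORWARD)], strand=FORWARD,
        attributes={"tss": 100,
                    "minus10": GenomicInterval(88, 94, FORWARD),
                    "minus35": GenomicInterval(63, 69, FORWARD)},
    )
    geom = metrics.promoter_geometry([prom])
    assert geom.minus10_distances == [9]  # center floor((88+94)/2)=91
    assert geom.minus35_distances == [34]
    assert geom.spacers == [19]  # 88 - 69
    assert geom.flagged == []


def test_promoter_geometry_recovers_planted_offsets(synth_data):
    _, features, truth = synth_data
    promoters = [f for f in features if f.category == "promoter"]
    geom = metrics.promoter_geometry(promoters)
    assert np.median(geom.minus10_distances) == pytest.approx(
        np.median(truth["minus10_distances"]), abs=1
    )
    assert np.median(geom.minus35_distances) == pytest.approx(
        np.median(truth["minus35_distances"]), abs=1
    )
    assert sorted(geom.spacers) == sorted(truth["spacers"])
    assert not geom.flagged


def test_inter_tu_regions_trivial_cases():
    tus = [_feat("transcription_unit", 0, 40, tag="a"),
           _feat("transcription_unit", 60, 100, tag="b")]
    regions = metrics.inter_tu_regions(tus, 100)
    assert [(r.start, r.end) for r in regions] == [(40, 60)]
    full = [_feat("transcription_unit", 0, 100, tag="a")]
    assert metrics.inter_tu_regions(full, 100) == []


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 180), st.integers(1, 60)), max_size=8))
def test_inter_tu_conservation(spans):
    tus = [
        _feat("transcription_unit", s, min(s + w, 200), tag=f"t{i}")
        for i, (s, w) in enumerate(spans) if s < 200
    ]
    regions = metrics.inter_tu_regions(tus, 200)
    covered = np.zeros(200, dtype=bool)
    for tu in tus:
        covered[tu.start : tu.end] = True
    region_mask = np.zeros(200, dtype=bool)
    for r in regions:
        assert not region_mask[r.start : r.end].any()  # no double cover
        region_mask[r.start : r.end] = True
    assert not (covered & region_mask).any()
    assert (covered | region_mask).all()


# -- folding windows ------------------------------------------------------


def _exhaustive_max_pairs(seq, min_loop=3):
    """Enumerate all nested pairings recursively (oracle for tiny inputs)."""
    seq = seq.upper().replace("T", "U")
    pairs = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

    def best(i, j):
        if j - i <= min_loop:
            return 0
        score = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in pairs:
                score = max(score, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(0, len(seq) - 1)


def test_pairing_engine_trivial_and_oracle():
    assert metrics.max_base_pairs("A" * 40) == 0
    assert metrics.max_base_pairs("GGGGAAAACCCC") == 4
    rng = np.random.default_rng(5)
    for _ in range(25):
        seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(4, 14))))
        assert metrics.max_base_pairs(seq) == _exhaustive_max_pairs(seq), seq


def test_window_fold_energies_plumbing():
    seq = "A" * 120
    starts, energies = metrics.window_fold_energies(seq, window=100, step=10)
    assert starts.tolist() == [0, 10, 20] and (energies == 0).all()
    starts, energies = metrics.window_fold_energies(
        seq, window=100, step=10, engine=lambda s: -7.5
    )
    assert (energies == -7.5).all()
    with pytest.raises(ValueError):
        metrics.window_fold_energies("ACGU", window=100)


def test_tight_structure_threshold_and_ties():
    starts = np.arange(0, 100, 10)
    energies = -np.arange(10, dtype=float)  # distinct: only the lowest wins
    regions, threshold, mean = metrics.tight_structure_regions(
        starts, energies, window=10, fraction=0.10
    )
    assert [(r.start, r.end) for r in regions] == [(90, 100)]
    assert mean == pytest.approx(energies.mean())

    flat = np.zeros(10)
    regions, _, _ = metrics.tight_structure_regions(starts, flat, window=10,
                                                    fraction=0.10)
    assert [(r.start, r.end) for r in regions] == [(0, 100)]  # all tied

    with pytest.raises(ValueError):
        metrics.tight_structure_regions([], [], window=10)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(-50, 0, allow_nan=False), min_size=5, max_size=60))
def test_tight_selection_at_least_quantile_fraction(energies):
    energies = np.asarray(energies)
    starts = np.arange(energies.size) * 10
    regions, threshold, _ = metrics.tight_structure_regions(
        starts, energies, window=10, fraction=0.10
    )
    n_selected = int((energies <= threshold).sum())
    assert n_selected / energies.size >= 0.10 or n_selected >= 1
    # minimal under the tie rule: dropping the threshold excludes ties
    strictly_below = int((energies < threshold).sum())
    assert strictly_below / energies.size <= 0.10 + 1.0 / energies.size
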