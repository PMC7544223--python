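"""Bitome-derived statistics: bit counts, coverage, density profiles,
intergenic geometry and tight-mRNA-structure windows."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import FORWARD, REVERSE, FeatureRecord, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class DensityProfile:
    """Moving-window bit density across the genome."""

    window_size: int
    step: int
    centers: np.ndarray
    values: np.ndarray
    mean: float
    sd: float


@dataclass
class PromoterGeometry:
    """Distances from promoter -10/-35 element centers to the TSS and the
    spacer between the two elements, one entry per promoter carrying both
    boxes (element centers are floor(midpoint))."""

    minus10_distances: list[int]
    minus35_distances: list[int]
    spacers: list[int]
    flagged: list[str]  # promoter ids with a box on the wrong side of the TSS


def column_bit_counts(bitome) -> np.ndarray:
    """Set bits per genomic position (column-wise sum)."""
    return bitome.column_bit_counts()


def sequence_coverage(bitome, predicate) -> float:
    """Fraction of genomic positions with at least one bit among the rows
    selected by ``predicate``."""
    sub = bitome.select_rows(predicate)
    if sub.n_rows == 0:
        return 0.0
    covered = (sub.column_bit_counts() > 0).sum()
    return float(covered) / bitome.n_cols


def bit_density(bitome, interval: GenomicInterval) -> float:
    """Total bits in the region divided by its length (bits per bp)."""
    sub = bitome.extract(interval)
    return sub.total_bits / sub.n_cols


def moving_density(bitome, window: int = 100_000, step: int = 1000) -> DensityProfile:
    """Moving-window bit density; windows wrap on circular genomes.

    The default window matches genome-scale density profiling (100 kb);
    the step is a configurable resolution choice.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    n = bitome.n_cols
    if window > n:
        raise ValueError(f"window {window} exceeds genome length {n}")
    counts = bitome.column_bit_counts()
    csum = np.concatenate([[0], np.cumsum(counts)])
    if bitome.circular:
        starts = np.arange(0, n, step)
    else:
        starts = np.arange(0, n - window + 1, step)
    values = np.empty(starts.size, dtype=float)
    for i, s in enumerate(starts):
        e = s + window
        if e <= n:
            total = csum[e] - csum[s]
        else:  # wrap
            total = (csum[n] - csum[s]) + csum[e - n]
        values[i] = total / window
    centers = (starts + window // 2) % n
    return DensityProfile(
        window_size=window,
        step=step,
        centers=centers,
        values=values,
        mean=float(values.mean()),
        sd=float(values.std()),
    )


def feature_density_distribution(bitome, features):
    """Bit density of each feature's spanning interval, with the median.

    Returns ``(densities, median)`` where ``densities`` aligns with the
    input feature order.
    """
    densities = []
    for feat in features:
        iv = GenomicInterval(feat.start, feat.end, feat.strand)
        densities.append(bit_density(bitome, iv))
    return densities, float(np.median(densities)) if densities else float("nan")


def utr_lengths(tus, genes, include_zero=False):
    """5' and 3' UTR lengths from transcription units and their genes.

    The 5' UTR runs from the TU's 5' end to the start of its first gene
    (strand-aware); the 3' UTR from the last gene's end to the TU's 3' end.
    Zero-length UTRs (gene abutting the TU edge) are excluded from the
    returned lists unless ``include_zero`` is set.
    """
    genes_by_tag = {g.id: g for g in genes}
    five, three = [], []
    for tu in tus:
        if tu.category != "transcription_unit":
            continue
        linked = [genes_by_tag[t] for t in tu.links if t in genes_by_tag]
        linked = [g for g in linked if g.start >= tu.start and g.end <= tu.end]
        if not linked:
            log.warning("TU %s has no linked gene inside its span; skipped", tu.id)
            continue
        first = min(g.start for g in linked)
        last = max(g.end for g in linked)
        if tu.strand == REVERSE:
            utr5 = tu.end - last
            utr3 = first - tu.start
        else:
            utr5 = first - tu.start
            utr3 = tu.end - last
        for val, out in ((utr5, five), (utr3, three)):
            if val > 0 or include_zero:
                out.append(val)
    return five, three


def iqr_filter(values):
    """Values within 1.5 x IQR of the quartiles (standard boxplot rule)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return values[(values >= lo) & (values <= hi)]


def _center(interval: GenomicInterval) -> int:
    # floor of the half-open midpoint; even-length boxes round down
    return (interval.start + interval.end) // 2


def promoter_geometry(promoters) -> PromoterGeometry:
    """Element-to-TSS distances and -10/-35 spacers for promoters with
    a TSS and both boxes.

    Distances are unsigned (|element center - TSS|); the spacer is the gap
    in bp between the TSS-proximal end of the -35 box and the TSS-distal
    end of the -10 box. Promoters with a box downstream of the TSS are
    included but flagged.
    """
    d10, d35, spacers, flagged = [], [], [], []
    for prom in promoters:
        attrs = prom.attributes
        if "tss" not in attrs or "minus10" not in attrs or "minus35" not in attrs:
            continue
        tss = attrs["tss"]
        b10, b35 = attrs["minus10"], attrs["minus35"]
        d10.append(abs(_center(b10) - tss))
        d35.append(abs(_center(b35) - tss))
        if prom.strand == REVERSE:
            spacer = b35.start - b10.end
            wrong_side = b10.start <= tss or b35.start <= tss
        else:
            spacer = b10.start - b35.end
            wrong_side = b10.end > tss or b35.end > tss
        spacers.append(spacer)
        if wrong_side:
            flagged.append(prom.id)
    return PromoterGeometry(d10, d35, spacers, flagged)


def inter_tu_regions(tus, genome_length) -> list[GenomicInterval]:
    """Maximal intervals covered by no transcription unit on either strand.

    Together with the TU coverage union these tile the genome exactly.
    """
    covered = np.zeros(genome_length, dtype=bool)
    for tu in tus:
        for iv in tu.intervals:
            if iv.wraps:
                covered[iv.start :] = True
                covered[: iv.end] = True
            else:
                covered[iv.start : iv.end] = True
    free = np.flatnonzero(~covered)
    if free.size == 0:
        return []
    breaks = np.where(np.diff(free) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [free.size - 1]])
    return [
        GenomicInterval(int(free[s]), int(free[e]) + 1)
        for s, e in zip(starts, ends)
    ]


# -- mRNA folding windows -------------------------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def max_base_pairs(rna: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs (Watson-Crick + GU wobble) with
    a minimum hairpin loop, by the classic O(n^3) dynamic program."""
    seq = rna.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        return 0
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            if (seq[i], seq[j]) in _PAIRS:
                best = max(best, dp[i + 1, j - 1] + 1)
            for k in range(i + min_loop + 1, j):
                if (seq[i], seq[k]) in _PAIRS:
                    cand = dp[i + 1, k - 1] + 1 + dp[k + 1, j]
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return int(dp[0, n - 1])


def pairing_energy(subsequence: str) -> float:
    """Default folding engine: negated maximum base-pair count. A simple
    structure-propensity score used where a thermodynamic folding engine is
    not plugged in."""
    return -float(max_base_pairs(subsequence))


def window_fold_energies(sequence, window: int = 100, step: int = 10,
                         engine=pairing_energy):
    """Apply a folding engine to sliding windows of the sequence.

    Returns ``(starts, energies)``. The engine is any callable mapping a
    subsequence to a scalar; swap in a thermodynamic MFE engine for real
    free energies.
    """
    n = len(sequence)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    starts = np.arange(0, n - window + 1, step)
    energies = np.array([engine(sequence[s : s + window]) for s in starts], dtype=float)
    return starts, energies


def tight_structure_regions(starts, energies, window: int, fraction: float = 0.10):
    """Windows whose energy falls at or below the genome-wide ``fraction``
    quantile, merged into maximal intervals; ties at the threshold are
    included. Returns ``(regions, threshold, genome_wide_mean)``."""
    energies = np.asarray(energies, dtype=float)
    if energies.size == 0:
        raise ValueError("empty energy vector")
    threshold = float(np.quantile(energies, fraction))
    mean_energy = float(energies.mean())
    tight = np.asarray(starts)[energies <= threshold]
    regions = []
    for s in np.sort(tight):
        if regions and s <= regions[-1].end:
            regions[-1] = GenomicInterval(regions[-1].start, int(s) + window)
        else:
            regions.append(GenomicInterval(int(s), int(s) + window))
    return regions, threshold, mean_energy
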