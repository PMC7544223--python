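"""Mapping SNPs onto a bitome: per-feature SNP density, per-amino-acid
mutation frequency, and the bit-count rank test.

The rank test asks whether positions acquiring SNPs carry systematically
fewer (or more) encoded features than coding positions at large: a
two-sided Mann-Whitney U comparison of the column bit-count distribution
over all coding positions against the bit counts at SNP positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RankTestResult:
    statistic_U: float
    p_two_sided: float
    n: int  # population size (coding positions)
    m: int  # sample size (SNP positions)
    method: str = "asymptotic"


def snp_positions(snps, deduplicate=True) -> np.ndarray:
    pos = np.array([s.position for s in snps], dtype=np.int64)
    if deduplicate:
        pos = np.unique(pos)
    return pos


def snp_density_by_feature(bitome, predicate, snps, deduplicate=True):
    """SNPs per covered bp for the rows selected by ``predicate``.

    Covered positions are columns with at least one bit among the selected
    rows; the density is the number of SNPs at covered positions divided by
    the number of covered positions. Returns ``None`` when no position is
    covered.
    """
    sub = bitome.select_rows(predicate)
    if sub.n_rows == 0:
        return None
    covered = np.flatnonzero(sub.column_bit_counts() > 0)
    if covered.size == 0:
        return None
    pos = snp_positions(snps, deduplicate)
    hits = np.isin(pos, covered).sum()
    return float(hits) / covered.size


def aa_mutation_frequencies(bitome, snps, deduplicate=True) -> tuple[pd.DataFrame, float]:
    """Per-amino-acid SNP frequency table and the genome-wide baseline.

    For each amino-acid subtype, coverage is the union of its six rows'
    columns; the frequency is SNPs at covered positions / covered
    positions. The baseline is total SNPs / genome length. Amino acids with
    zero coverage are excluded.
    """
    pos = snp_positions(snps, deduplicate)
    baseline = pos.size / bitome.n_cols
    subtypes = sorted(
        {k.subtype for k in bitome.row_keys if k.category == "amino_acid"}
    )
    rows = []
    for aa in subtypes:
        sub = bitome.select_rows(
            lambda k, aa=aa: k.category == "amino_acid" and k.subtype == aa
        )
        covered = np.flatnonzero(sub.column_bit_counts() > 0)
        if covered.size == 0:
            continue
        count = int(np.isin(pos, covered).sum())
        rows.append(
            {
                "amino_acid": aa,
                "coverage_bp": int(covered.size),
                "snp_count": count,
                "frequency": count / covered.size,
            }
        )
    return pd.DataFrame(rows), float(baseline)


def mann_whitney_u(sample, population, max_enumeration=200_000) -> RankTestResult:
    """Two-sided Mann-Whitney U of ``sample`` against ``population``.

    U is the number of (sample, population) pairs in which the sample value
    wins (ties count one half). Small instances are solved by exhaustive
    enumeration of all group assignments of the pooled values (exact even
    under heavy ties); larger ones use the normal approximation with the
    standard tie-corrected variance and continuity correction.
    """
    sample = np.asarray(sample, dtype=float)
    population = np.asarray(population, dtype=float)
    m, n = sample.size, population.size
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([sample, population])
    ranks = stats.rankdata(pooled)
    r_sample = ranks[:m].sum()
    u = r_sample - m * (m + 1) / 2.0

    if comb(n + m, m) <= max_enumeration:
        u_null = _enumerate_u(pooled, m)
        center = n * m / 2.0
        p = float(np.mean(np.abs(u_null - center) >= abs(u - center) - 1e-12))
        return RankTestResult(u, p, n, m, method="exact")

    # tie-corrected normal approximation
    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return RankTestResult(u, 1.0, n, m, method="asymptotic")
    z = (u - n * m / 2.0 - np.sign(u - n * m / 2.0) * 0.5) / np.sqrt(sigma2)
    p = float(2 * stats.norm.sf(abs(z)))
    return RankTestResult(u, min(p, 1.0), n, m, method="asymptotic")


def _enumerate_u(pooled, m):
    """U statistics over every assignment of m pooled values to the sample."""
    ranks = stats.rankdata(pooled)
    out = np.empty(comb(len(pooled), m))
    offset = m * (m + 1) / 2.0
    for i, idx in enumerate(combinations(range(len(pooled)), m)):
        out[i] = ranks[list(idx)].sum() - offset
    return out


def bitcount_snp_test(bitome, snps, coding_predicate, deduplicate=True,
                      max_enumeration=200_000) -> RankTestResult:
    """Compare bit counts over all coding positions with bit counts at
    coding SNP positions (two-sided Mann-Whitney U).

    Coding positions are columns with at least one bit among the rows
    selected by ``coding_predicate``; bit counts come from the full matrix.
    """
    coding_rows = bitome.select_rows(coding_predicate)
    coding_cols = np.flatnonzero(coding_rows.column_bit_counts() > 0)
    if coding_cols.size == 0:
        raise ValueError("no coding positions under the given predicate")
    counts = bitome.column_bit_counts()
    population = counts[coding_cols]
    pos = snp_positions(snps, deduplicate)
    pos = pos[np.isin(pos, coding_cols)]
    if pos.size == 0:
        raise ValueError("no SNPs at coding positions")
    sample = counts[pos]
    return mann_whitney_u(sample, population, max_enumeration=max_enumeration)
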