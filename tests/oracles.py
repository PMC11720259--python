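"""Independent brute-force oracles used to validate the fast implementations.

Everything here follows the operation definitions literally with explicit
loops and exact arithmetic; nothing imports the code paths it checks
(beyond the shared parameter containers and genotype codes).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from rohscan.io import GT
from rohscan.roh import ROHParams

#: Tolerance making the window-support comparator inclusive at the printed
#: decimal (0.05 in binary is slightly above 1/20).
_SUPPORT_EPS = 1e-9


def brute_force_roh(
    calls: np.ndarray,
    positions: np.ndarray,
    chromosomes: np.ndarray,
    individuals: list[str],
    p: ROHParams,
) -> list[tuple]:
    """Enumerate every window and filter explicitly.

    Returns tuples (individual, chromosome, start_bp, end_bp, n_snps)
    sorted like detect_roh output.
    """
    out = []
    chrom_order = list(dict.fromkeys(int(c) for c in chromosomes))
    for ii, ind in enumerate(individuals):
        for chrom in chrom_order:
            idx = [j for j in range(len(chromosomes)) if chromosomes[j] == chrom]
            m = len(idx)
            w = p.window_snps
            if m < w:
                continue
            g = [int(calls[ii, j]) for j in idx]
            pos = [int(positions[j]) for j in idx]
            windows = list(range(m - w + 1))
            hom = []
            for s in windows:
                n_het = sum(1 for k in range(s, s + w) if g[k] == GT.HET)
                n_mis = sum(1 for k in range(s, s + w) if g[k] == GT.MISSING)
                hom.append(n_het <= p.max_het_per_window and n_mis <= p.max_missing_per_window)
            in_run = []
            for j in range(m):
                covering = [s for s in windows if s <= j <= s + w - 1]
                support = sum(hom[s] for s in covering) / len(covering)
                in_run.append(support >= p.window_support_threshold - _SUPPORT_EPS)
            # maximal stretches, split at big gaps
            stretches = []
            start = None
            for j in range(m):
                broken = j > 0 and pos[j] - pos[j - 1] > p.max_gap_bp
                if in_run[j] and (start is None):
                    start = j
                elif in_run[j] and broken:
                    stretches.append((start, j - 1))
                    start = j
                elif not in_run[j] and start is not None:
                    stretches.append((start, j - 1))
                    start = None
            if start is not None:
                stretches.append((start, m - 1))
            for a, b in stretches:
                n_snps = b - a + 1
                length = pos[b] - pos[a]
                if n_snps < p.min_snps_in_run or length < p.min_length_bp:
                    continue
                if length <= 0 or n_snps / length < p.min_density:
                    continue
                out.append((ind, chrom, pos[a], pos[b], n_snps))
    return out


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact-rational HWE p-value by direct enumeration of genotype tables
    with the observed allele counts."""
    from math import comb

    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het  # count of one allele
    if n == 0 or min(n_a, 2 * n - n_a) == 0:
        return Fraction(1)

    def weight(h: int) -> int:
        # multinomial count of allele arrangements giving h hets
        if (n_a - h) % 2 or h > min(n_a, 2 * n - n_a) or (n_a - h) < 0:
            return 0
        aa = (n_a - h) // 2
        bb = n - aa - h
        if bb < 0:
            return 0
        # number of ways: n!/(aa! h! bb!) * 2^h
        from math import factorial

        return factorial(n) // (factorial(aa) * factorial(h) * factorial(bb)) * 2**h

    total = sum(weight(h) for h in range(0, min(n_a, 2 * n - n_a) + 1))
    p_obs = Fraction(weight(n_het), total)
    p = sum(
        Fraction(weight(h), total)
        for h in range(0, min(n_a, 2 * n - n_a) + 1)
        if Fraction(weight(h), total) <= p_obs
    )
    return p


def interval_stab_counts(segments, positions, chromosomes, individuals) -> np.ndarray:
    """O(n_segments x m) scan counting individuals whose closed segment
    interval contains each SNP."""
    m = len(positions)
    covered = {ind: np.zeros(m, dtype=bool) for ind in individuals}
    for seg in segments:
        for j in range(m):
            if (
                chromosomes[j] == seg.chromosome
                and seg.start_bp <= positions[j] <= seg.end_bp
            ):
                covered[seg.individual][j] = True
    return np.sum([covered[ind] for ind in individuals], axis=0)


def all_pairs_overlap_count(islands, genes) -> int:
    """Closed-interval overlap count over all island x gene pairs."""
    n = 0
    for isl in islands:
        for g in genes:
            if g.chromosome == isl.chromosome and not (
                g.end_bp < isl.start_bp or g.start_bp > isl.end_bp
            ):
                n += 1
    return n
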