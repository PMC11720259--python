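"""Genotype quality control, heterozygosity and Hardy-Weinberg statistics.

The QC filters mirror common SNP-array practice: keep SNPs called in at
least 90% of samples (inclusive comparator), keep individuals with more
than 95% of SNPs called (strict comparator), and restrict to the 31 horse
autosomes.  The two comparators differ deliberately and are configurable.

The Hardy-Weinberg test is the exact (enumeration) test over heterozygote
counts conditional on the allele counts; a chi-square variant is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .errors import EmptyAfterQCError
from .io import GT, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "HetSummary",
    "apply_qc",
    "heterozygosity",
    "hwe_test",
    "hwe_exact_pvalue",
]

log = logging.getLogger(__name__)

N_AUTOSOMES = 31


@dataclass(frozen=True)
class QCThresholds:
    """Call-rate and autosome filters.

    ``snp_call_rate`` keeps a SNP when its call rate is **>=** the threshold
    ("at least"); ``individual_call_rate`` keeps an individual when its call
    rate is strictly **>** the threshold ("more than").  ``order`` controls
    the filter sequence and is logged with every run.
    """

    snp_call_rate: float = 0.90
    individual_call_rate: float = 0.95
    autosomes_only: bool = True
    snp_comparator: str = ">="
    individual_comparator: str = ">"
    order: tuple[str, ...] = ("snp", "individual", "autosome")

    def __post_init__(self) -> None:
        for name in ("snp_call_rate", "individual_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if set(self.order) - {"snp", "individual", "autosome"}:
            raise ValueError(f"unknown QC stage in order={self.order}")


def _compare(rates: np.ndarray, threshold: float, comparator: str) -> np.ndarray:
    if comparator == ">=":
        return rates >= threshold
    if comparator == ">":
        return rates > threshold
    raise ValueError(f"comparator must be '>' or '>=', got {comparator!r}")


def apply_qc(gm: GenotypeMatrix, t: QCThresholds = QCThresholds()) -> GenotypeMatrix:
    """Apply call-rate and autosome filters; idempotent.

    Raises :class:`EmptyAfterQCError` when a stage removes every SNP or
    every individual.
    """
    out = gm
    for stage in t.order:
        nonmiss = out.calls != GT.MISSING
        if stage == "snp":
            rates = nonmiss.mean(axis=0) if out.n_individuals else np.ones(out.n_markers)
            keep = np.flatnonzero(_compare(rates, t.snp_call_rate, t.snp_comparator))
            log.info("QC snp filter (call rate %s %.3f): kept %d/%d SNPs",
                     t.snp_comparator, t.snp_call_rate, keep.size, out.n_markers)
            if keep.size == 0:
                raise EmptyAfterQCError("empty after QC: no SNP passed the call-rate filter")
            out = out.subset(marker_idx=keep)
        elif stage == "individual":
            rates = nonmiss.mean(axis=1) if out.n_markers else np.ones(out.n_individuals)
            keep = np.flatnonzero(_compare(rates, t.individual_call_rate, t.individual_comparator))
            log.info("QC individual filter (call rate %s %.3f): kept %d/%d individuals",
                     t.individual_comparator, t.individual_call_rate, keep.size, out.n_individuals)
            if keep.size == 0:
                raise EmptyAfterQCError("empty after QC: no individual passed the call-rate filter")
            out = out.subset(individual_idx=keep)
        elif stage == "autosome" and t.autosomes_only:
            keep = np.flatnonzero((out.chromosomes >= 1) & (out.chromosomes <= N_AUTOSOMES))
            log.info("QC autosome filter: kept %d/%d SNPs", keep.size, out.n_markers)
            if keep.size == 0:
                raise EmptyAfterQCError("empty after QC: no autosomal SNP left")
            out = out.subset(marker_idx=keep)
    return out


@dataclass
class HetSummary:
    """Per-SNP, per-chromosome and population heterozygosity / HWE summary.

    ``per_snp`` columns: snp_id, chromosome, position_bp, n_called, ho, he,
    and hwe_p when the HWE test was run.  SNPs with zero non-missing calls
    carry NaN and are excluded from every mean.
    """

    per_snp: pd.DataFrame
    per_chromosome: pd.DataFrame
    mean_ho: float = math.nan
    mean_he: float = math.nan


def _genotype_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = gm.calls
    n_ref = (c == GT.HOM_REF).sum(axis=0)
    n_het = (c == GT.HET).sum(axis=0)
    n_alt = (c == GT.HOM_ALT).sum(axis=0)
    return n_ref, n_het, n_alt


def _base_frame(gm: GenotypeMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [m.snp_id for m in gm.markers],
            "chromosome": gm.chromosomes,
            "position_bp": gm.positions,
        }
    )


def heterozygosity(gm: GenotypeMatrix) -> HetSummary:
    """Observed and expected heterozygosity per SNP, chromosome and overall.

    Ho = het count / non-missing count; He = 2p(1-p) with p the
    alternate-allele frequency among non-missing calls (no small-sample
    correction).  Chromosome and population means are unweighted over SNPs.
    """
    if gm.n_markers == 0 or gm.n_individuals == 0:
        raise ValueError("heterozygosity requires a non-empty genotype matrix")
    n_ref, n_het, n_alt = _genotype_counts(gm)
    n_called = n_ref + n_het + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, n_het / n_called, np.nan)
        p = np.where(n_called > 0, (2 * n_alt + n_het) / (2 * n_called), np.nan)
    he = 2 * p * (1 - p)
    if (n_called == 0).any():
        log.warning("%d SNPs with zero non-missing calls excluded from Ho/He means",
                    int((n_called == 0).sum()))
    per_snp = _base_frame(gm)
    per_snp["n_called"] = n_called
    per_snp["ho"] = ho
    per_snp["he"] = he
    per_chrom = (
        per_snp.groupby("chromosome", sort=True)[["ho", "he"]].mean().reset_index()
    )
    return HetSummary(
        per_snp=per_snp,
        per_chromosome=per_chrom,
        mean_ho=float(np.nanmean(ho)),
        mean_he=float(np.nanmean(he)),
    )


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int, midp: bool = False) -> float:
    """Exact Hardy-Weinberg p-value by enumeration of heterozygote counts.

    Conditional on the observed allele counts, every heterozygote count of
    the same parity is enumerated; the p-value sums the probabilities of
    configurations no more likely than the observed one.  Monomorphic SNPs
    return 1 by convention.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n == 0 or n_rare == 0:
        return 1.0

    # unnormalized probabilities over het counts of the observed parity
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(n_het = h | allele counts) up to a shared constant:
    #   2^h * n! / (h! * n_AA! * n_aa!) with n_AA=(n_rare-h)/2 etc.
    n_common = 2 * n - n_rare
    rare_hom = (n_rare - hets) // 2
    common_hom = (n_common - hets) // 2
    logp = (
        hets * math.log(2.0)
        - special.gammaln(hets + 1)
        - special.gammaln(rare_hom + 1)
        - special.gammaln(common_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    if midp:
        p = probs[probs < obs * (1 + 1e-12)].sum() - 0.5 * obs
    else:
        p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_test(gm: GenotypeMatrix, method: str = "exact", midp: bool = False) -> HetSummary:
    """Per-SNP Hardy-Weinberg p-values plus per-chromosome mean p.

    ``method`` is ``"exact"`` (enumeration; default) or ``"chisq"``
    (1-df goodness of fit without continuity correction).
    """
    if method not in ("exact", "chisq"):
        raise ValueError(f"method must be 'exact' or 'chisq', got {method!r}")
    n_ref, n_het, n_alt = _genotype_counts(gm)
    n_called = n_ref + n_het + n_alt
    if method == "exact":
        pvals = np.array(
            [
                hwe_exact_pvalue(int(r), int(h), int(a), midp=midp) if c > 0 else np.nan
                for r, h, a, c in zip(n_ref, n_het, n_alt, n_called)
            ]
        )
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (2 * n_alt + n_het) / (2 * n_called)
            exp = np.stack(
                [n_called * (1 - p) ** 2, n_called * 2 * p * (1 - p), n_called * p**2]
            )
            obs = np.stack([n_ref, n_het, n_alt])
            chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0).sum(axis=0)
        pvals = np.where(n_called > 0, sps.chi2.sf(chi2, df=1), np.nan)
        mono = (n_het + np.minimum(n_ref, n_alt)) == 0
        pvals = np.where(mono & (n_called > 0), 1.0, pvals)
    per_snp = _base_frame(gm)
    per_snp["n_called"] = n_called
    per_snp["hwe_p"] = pvals
    per_chrom = per_snp.groupby("chromosome", sort=True)[["hwe_p"]].mean().reset_index()
    return HetSummary(per_snp=per_snp, per_chromosome=per_chrom)
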