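"""Genomic inbreeding coefficients from runs of homozygosity.

F_ROH is the fraction of the SNP-covered genome lying inside an
individual's ROH: ``F_ROH = sum(L_ROH) / L_genome``, at genome scope or per
chromosome (with the chromosome's covered length as denominator).

The coefficient is decomposed by run length: under Fisher's recombination
theory the expected length of an autozygous fragment inherited from a
common ancestor ``g`` generations back is ``100/(2g)`` cM, taken here as
``100/(2g)`` Mb (1 cM ~ 1 Mb).  The thresholds are truncated (not rounded)
to one decimal — 16.6, 8.3 and 5.5 Mb for 3, 6 and 9 generations — and a
run counts toward generation ``g`` when its length is **>=** the threshold.
The ancestral component is the remainder: ``F_ROHANC = F_ROH - F_ROH9G``
(more precisely, minus the component of the deepest generation supplied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roh import ROHSegment, segments_to_frame

__all__ = [
    "GenomeSpec",
    "GenerationThresholds",
    "InbreedingRecord",
    "generation_threshold",
    "compute_froh",
    "records_to_frame",
    "length_class_summary",
]

#: Total autosomal length covered by the 70k horse array (bp).
DEFAULT_GENOME_BP = 2_276_871_601


@dataclass(frozen=True)
class GenomeSpec:
    """Per-chromosome and total SNP-covered lengths (bp).

    When both are supplied the total must equal the chromosome sum; when
    only chromosome lengths are given the total is their sum.  The default
    total is the 70k-array constant; per-chromosome coefficients then
    require chromosome lengths (see :meth:`from_genotypes`).
    """

    chromosome_lengths: dict[int, int] = field(default_factory=dict)
    total_bp: int | None = None

    def __post_init__(self) -> None:
        for c, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {c}: length must be positive")
        if self.total_bp is not None and self.total_bp <= 0:
            raise ValueError("total_bp must be positive")
        if self.total_bp is not None and self.chromosome_lengths:
            s = sum(self.chromosome_lengths.values())
            if s != self.total_bp:
                raise ValueError(
                    f"total_bp={self.total_bp} != sum of chromosome lengths {s}"
                )

    @property
    def total(self) -> int:
        if self.total_bp is not None:
            return self.total_bp
        if self.chromosome_lengths:
            return sum(self.chromosome_lengths.values())
        return DEFAULT_GENOME_BP

    @classmethod
    def from_genotypes(cls, gm) -> "GenomeSpec":
        """Covered length per chromosome = last minus first SNP position."""
        lengths: dict[int, int] = {}
        for chrom, sl in gm.chromosome_slices().items():
            pos = gm.positions[sl]
            lengths[chrom] = int(pos[-1] - pos[0])
        return cls(chromosome_lengths=lengths)


def generation_threshold(g: int) -> float:
    """Minimum ROH length (Mb) dating autozygosity within ``g`` generations.

    ``100/(2g)`` truncated to one decimal: 3 -> 16.6, 6 -> 8.3, 9 -> 5.5.
    """
    if g <= 0:
        raise ValueError(f"g must be a positive integer, got {g}")
    return math.floor(100.0 / (2 * g) * 10 + 1e-9) / 10


@dataclass(frozen=True)
class GenerationThresholds:
    """Mapping generation -> minimum ROH length in Mb (strictly decreasing)."""

    thresholds_mb: dict[int, float] = field(
        default_factory=lambda: {3: 16.6, 6: 8.3, 9: 5.5}
    )

    def __post_init__(self) -> None:
        gens = sorted(self.thresholds_mb)
        vals = [self.thresholds_mb[g] for g in gens]
        if not all(a > b for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be strictly decreasing in g")
        if any(v <= 0 for v in vals):
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_generations(cls, generations=(3, 6, 9)) -> "GenerationThresholds":
        return cls({g: generation_threshold(g) for g in generations})

    @property
    def generations(self) -> tuple[int, ...]:
        return tuple(sorted(self.thresholds_mb))


@dataclass(frozen=True)
class InbreedingRecord:
    """Per-individual inbreeding coefficients at one scope.

    ``scope`` is ``"genome"`` or a chromosome index.  ``froh_by_generation``
    maps g to the coefficient restricted to runs >= the g-generation length;
    ``froh_anc`` is ``froh`` minus the deepest generation's component.
    """

    individual: str
    scope: object
    froh: float
    froh_by_generation: dict[int, float]
    froh_anc: float


def _sum_by_threshold(lengths: np.ndarray, thresholds: GenerationThresholds) -> dict[int, float]:
    # thresholds carry one decimal in Mb; round to an exact bp integer so
    # a run of exactly the boundary length counts (inclusive comparator)
    return {
        g: float(lengths[lengths >= round(thresholds.thresholds_mb[g] * 1e6)].sum())
        for g in thresholds.generations
    }


def compute_froh(
    segments: list[ROHSegment],
    spec: GenomeSpec = GenomeSpec(),
    thresholds: GenerationThresholds = GenerationThresholds(),
    individuals: list[str] | None = None,
    per_chromosome: bool = True,
) -> list[InbreedingRecord]:
    """Genome- and chromosome-scope inbreeding records per individual.

    ``individuals`` fixes the output roster (individuals without segments
    get all-zero records); by default it is inferred from the segments.
    Chromosome-scope records require ``spec.chromosome_lengths`` covering
    every chromosome carrying a segment.
    """
    df = segments_to_frame(segments)
    if individuals is None:
        individuals = list(dict.fromkeys(df["individual"])) if len(df) else []
    if per_chromosome and len(df):
        missing = set(df["chromosome"]) - set(spec.chromosome_lengths)
        if missing:
            raise ValueError(
                f"segments on chromosomes absent from GenomeSpec: {sorted(missing)}"
            )

    records: list[InbreedingRecord] = []
    grouped = dict(tuple(df.groupby("individual"))) if len(df) else {}
    for ind in individuals:
        sub = grouped.get(ind)
        lengths = sub["length_bp"].to_numpy(dtype=float) if sub is not None else np.array([])
        total = float(lengths.sum())
        by_g = _sum_by_threshold(lengths, thresholds)
        deepest = max(thresholds.generations)
        records.append(
            InbreedingRecord(
                individual=ind,
                scope="genome",
                froh=total / spec.total,
                froh_by_generation={g: v / spec.total for g, v in by_g.items()},
                froh_anc=(total - by_g[deepest]) / spec.total,
            )
        )
        if per_chromosome and sub is not None:
            for chrom, csub in sub.groupby("chromosome"):
                clen = spec.chromosome_lengths[chrom]
                clengths = csub["length_bp"].to_numpy(dtype=float)
                ctotal = float(clengths.sum())
                cby_g = _sum_by_threshold(clengths, thresholds)
                records.append(
                    InbreedingRecord(
                        individual=ind,
                        scope=int(chrom),
                        froh=ctotal / clen,
                        froh_by_generation={g: v / clen for g, v in cby_g.items()},
                        froh_anc=(ctotal - cby_g[deepest]) / clen,
                    )
                )
    return records


def records_to_frame(records: list[InbreedingRecord]) -> pd.DataFrame:
    """Records as a DataFrame with froh_{g}g columns and froh_anc."""
    rows = []
    for r in records:
        row = {"individual": r.individual, "scope": r.scope, "froh": r.froh}
        for g, v in sorted(r.froh_by_generation.items()):
            row[f"froh_{g}g"] = v
        row["froh_anc"] = r.froh_anc
        rows.append(row)
    cols = ["individual", "scope", "froh"]
    if records:
        cols += [f"froh_{g}g" for g in sorted(records[0].froh_by_generation)] + ["froh_anc"]
    return pd.DataFrame(rows, columns=cols)


#: Length-class bin edges in Mb (right-open except the last).
LENGTH_CLASS_EDGES_MB = (1.0, 5.5, 8.3, 16.6, math.inf)


def length_class_summary(
    segments: list[ROHSegment], n_individuals: int | None = None
) -> pd.DataFrame:
    """Run counts and lengths binned by length class.

    Bins (Mb): [1, 5.5), [5.5, 8.3), [8.3, 16.6), [16.6, inf), plus a
    Total row.  Columns: n_roh, pct_of_total, mean_length_mb, sd_length_mb,
    pct_individuals_with_roh.  ``n_individuals`` defaults to the number of
    distinct individuals among the segments.
    """
    df = segments_to_frame(segments)
    if n_individuals is None:
        n_individuals = df["individual"].nunique() if len(df) else 0
    edges = LENGTH_CLASS_EDGES_MB
    labels = [
        f"[{lo:g}, {hi:g}) Mb" if math.isfinite(hi) else f">= {lo:g} Mb"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    rows = []
    total_n = len(df)
    mb = df["length_bp"] / 1e6 if total_n else pd.Series(dtype=float)
    for lo, hi, label in zip(edges[:-1], edges[1:], labels):
        sel = df[(mb >= lo) & (mb < hi)] if total_n else df
        n = len(sel)
        carriers = sel["individual"].nunique() if n else 0
        rows.append(
            {
                "length_class": label,
                "n_roh": n,
                "pct_of_total": 100.0 * n / total_n if total_n else 0.0,
                "mean_length_mb": sel["length_bp"].mean() / 1e6 if n else 0.0,
                "sd_length_mb": sel["length_bp"].std() / 1e6 if n > 1 else 0.0,
                "pct_individuals_with_roh": 100.0 * carriers / n_individuals
                if n_individuals
                else 0.0,
            }
        )
    rows.append(
        {
            "length_class": "Total",
            "n_roh": total_n,
            "pct_of_total": 100.0 if total_n else 0.0,
            "mean_length_mb": mb.mean() if total_n else 0.0,
            "sd_length_mb": mb.std() if total_n > 1 else 0.0,
            "pct_individuals_with_roh": 100.0
            * (df["individual"].nunique() / n_individuals)
            if n_individuals and total_n
            else 0.0,
        }
    )
    return pd.DataFrame(rows)
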