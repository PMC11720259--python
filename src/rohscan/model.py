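"""Model/Results facade over the ROH analysis pipeline.

:class:`ROHInbreedingModel` is built from a genotype matrix (or a PLINK
text fileset) together with the scan parameters; :meth:`fit` runs QC,
heterozygosity/HWE, ROH detection, F_ROH decomposition, incidence and
island calling, and returns a :class:`ROHResults` carrying every estimate
plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import annotation as _annotation
from .inbreeding import (
    GenerationThresholds,
    GenomeSpec,
    InbreedingRecord,
    compute_froh,
    length_class_summary,
    records_to_frame,
)
from .io import GenotypeMatrix, read_ped_map
from .islands import (
    IncidenceTrack,
    ROHIsland,
    call_islands,
    incidence_pvalues,
    islands_to_frame,
    snp_incidence,
)
from .qc import HetSummary, QCThresholds, apply_qc, heterozygosity, hwe_test
from .roh import LFormulaInputs, ROHParams, ROHSegment, detect_roh, min_snp_threshold, segments_to_frame

__all__ = ["ROHInbreedingModel", "ROHResults"]


def summarize_froh(records: list[InbreedingRecord]) -> pd.DataFrame:
    """Cohort mean +/- SD of each inbreeding component and its share of
    mean F_ROH (integer percent, half-up), from genome-scope records.

    Shares are NA when mean F_ROH is zero.
    """
    genome = [r for r in records if r.scope == "genome"]
    if not genome:
        raise ValueError("summarize_froh requires at least one genome-scope record")
    df = records_to_frame(genome)
    comp_cols = [c for c in df.columns if c.startswith("froh_")]
    rows = []
    mean_froh = df["froh"].mean()
    for col in ["froh"] + comp_cols:
        mean, sd = df[col].mean(), df[col].std()
        if col == "froh":
            share = np.nan
        elif mean_froh > 0:
            share = float(np.floor(100.0 * mean / mean_froh + 0.5))
        else:
            share = np.nan
        rows.append({"component": col, "mean": mean, "sd": sd, "pct_of_froh": share})
    return pd.DataFrame(rows)


class ROHInbreedingModel:
    """Runs-of-homozygosity inbreeding model for a genotyped cohort.

    Parameters
    ----------
    genotypes
        The cohort; QC is applied during :meth:`fit` when ``qc`` is given.
    roh_params
        Sliding-window scan parameters (default: 70k-array settings).
    genome
        Denominators for F_ROH; derived from the SNP map when omitted.
    generations
        Generations defining the recent/ancestral decomposition.
    qc
        Call-rate/autosome thresholds; ``None`` skips QC.
    recompute_min_snps
        When True, the window size and minimum run SNP count are recomputed
        from the post-QC data (alpha 0.05, observed mean heterozygosity)
        instead of the fixed defaults.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        roh_params: ROHParams | None = None,
        genome: GenomeSpec | None = None,
        generations: tuple[int, ...] = (3, 6, 9),
        qc: QCThresholds | None = QCThresholds(),
        recompute_min_snps: bool = False,
        island_freq_min: float = 0.5,
        island_p_max: float = 0.01,
        island_min_sig_snps: int = 3,
    ) -> None:
        self.genotypes = genotypes
        self.roh_params = roh_params or ROHParams()
        self.genome = genome
        self.generations = tuple(generations)
        self.qc = qc
        self.recompute_min_snps = recompute_min_snps
        self.island_freq_min = island_freq_min
        self.island_p_max = island_p_max
        self.island_min_sig_snps = island_min_sig_snps

    @classmethod
    def from_ped(cls, ped_path, map_path, **kwargs) -> "ROHInbreedingModel":
        """Build the model from a PLINK text fileset."""
        return cls(read_ped_map(ped_path, map_path), **kwargs)

    def fit(
        self,
        method: str = "closed_form",
        reps: int = 1_000_000,
        seed: int | None = None,
    ) -> "ROHResults":
        """Run the full analysis and return a results object.

        ``method``/``reps``/``seed`` control the island randomization test
        (exact closed form by default; ``"monte_carlo"`` needs a seed).
        """
        gm = apply_qc(self.genotypes, self.qc) if self.qc is not None else self.genotypes
        het = heterozygosity(gm)
        hwe = hwe_test(gm)

        params = self.roh_params
        min_snps = None
        if self.recompute_min_snps:
            min_snps = min_snp_threshold(
                LFormulaInputs(
                    alpha=0.05, ns=gm.n_markers, ni=gm.n_individuals, het=het.mean_ho
                )
            )
            params = replace(params, window_snps=min_snps, min_snps_in_run=min_snps)

        genome = self.genome or GenomeSpec.from_genotypes(gm)
        thresholds = GenerationThresholds.from_generations(self.generations)

        segments = detect_roh(gm, params)
        records = compute_froh(segments, genome, thresholds, individuals=gm.individuals)
        track = snp_incidence(segments, gm)
        track = incidence_pvalues(track, reps=reps, seed=seed, method=method)
        islands = call_islands(
            track,
            freq_min=self.island_freq_min,
            p_max=self.island_p_max,
            min_sig_snps=self.island_min_sig_snps,
        )
        return ROHResults(
            model=self,
            genotypes=gm,
            params=params,
            genome=genome,
            thresholds=thresholds,
            het=het,
            hwe=hwe,
            segments=segments,
            inbreeding=records,
            incidence=track,
            islands=islands,
            min_snps_recomputed=min_snps,
        )


@dataclass
class ROHResults:
    """Fitted results: detected runs, inbreeding coefficients, incidence
    track and called islands, with tabular and text summaries."""

    model: ROHInbreedingModel
    genotypes: GenotypeMatrix
    params: ROHParams
    genome: GenomeSpec
    thresholds: GenerationThresholds
    het: HetSummary
    hwe: HetSummary
    segments: list[ROHSegment]
    inbreeding: list[InbreedingRecord]
    incidence: IncidenceTrack
    islands: list[ROHIsland]
    min_snps_recomputed: int | None = None
    gene_annotation: pd.DataFrame | None = None

    # -- tabular views -------------------------------------------------------

    def segments_frame(self) -> pd.DataFrame:
        return segments_to_frame(self.segments)

    def inbreeding_frame(self, scope: str = "genome") -> pd.DataFrame:
        df = records_to_frame(self.inbreeding)
        if scope == "genome":
            return df[df["scope"] == "genome"].reset_index(drop=True)
        if scope == "chromosome":
            return df[df["scope"] != "genome"].reset_index(drop=True)
        raise ValueError("scope must be 'genome' or 'chromosome'")

    def length_classes(self) -> pd.DataFrame:
        return length_class_summary(self.segments, n_individuals=self.genotypes.n_individuals)

    def islands_frame(self) -> pd.DataFrame:
        return islands_to_frame(self.islands)

    def froh_summary(self) -> pd.DataFrame:
        return summarize_froh(self.inbreeding)

    def annotate(self, genes, containment: bool = False) -> pd.DataFrame:
        """Attach gene overlaps to the called islands (also cached on the
        results object)."""
        if isinstance(genes, (str, bytes)) or hasattr(genes, "__fspath__"):
            genes = _annotation.load_genes(genes)
        self.gene_annotation = _annotation.annotate_islands(
            self.islands, genes, containment=containment
        )
        return self.gene_annotation

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text cohort summary in the spirit of a model results table."""
        gm = self.genotypes
        n_roh = len(self.segments)
        mean_len = (
            np.mean([s.length_bp for s in self.segments]) / 1e6 if n_roh else 0.0
        )
        froh = self.froh_summary().set_index("component")
        lines = [
            "ROH inbreeding analysis",
            "=" * 60,
            f"Individuals: {gm.n_individuals}    SNPs: {gm.n_markers}    "
            f"Chromosomes: {len(gm.chromosome_slices())}",
            f"Mean Ho: {self.het.mean_ho:.3f}    Mean He: {self.het.mean_he:.3f}",
            f"Window/min SNPs: {self.params.window_snps}/{self.params.min_snps_in_run}"
            + (
                f" (recomputed L = {self.min_snps_recomputed})"
                if self.min_snps_recomputed is not None
                else ""
            ),
            f"ROH detected: {n_roh} ({n_roh / gm.n_individuals:.1f} per individual)"
            if gm.n_individuals
            else f"ROH detected: {n_roh}",
            f"Mean ROH length: {mean_len:.2f} Mb",
            "-" * 60,
            "Inbreeding coefficients (mean +/- SD, share of F_ROH):",
        ]
        for comp, row in froh.iterrows():
            share = "" if np.isnan(row["pct_of_froh"]) else f"  {row['pct_of_froh']:3.0f}%"
            lines.append(f"  {comp:<10s} {row['mean']:.4f} +/- {row['sd']:.4f}{share}")
        lines.append("-" * 60)
        lines.append(f"ROH islands called: {len(self.islands)}")
        for isl in self.islands:
            lines.append(
                f"  island {isl.island_id}: chr{isl.chromosome} "
                f"{isl.start_bp:,}-{isl.end_bp:,} ({isl.length_bp / 1e6:.2f} Mb, "
                f"{isl.n_snps} SNPs, mean p = {isl.mean_p:.4f})"
            )
        return "\n".join(lines)
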