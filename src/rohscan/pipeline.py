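"""End-to-end pipeline: QC -> ROH -> inbreeding -> islands -> annotation.

:func:`run_pipeline` executes the stages in the published order and writes
the full report bundle to the output directory:

* ``qc_summary.tsv`` — per-SNP call rate / Ho / He / HWE p after QC
* ``het_hwe_by_chrom.tsv`` — per-chromosome mean Ho, He and HWE p
* ``roh_segments.tsv`` — every detected run (1-based inclusive)
* ``roh_length_classes.tsv`` — run counts by length class
* ``froh_individual.csv`` / ``froh_by_chrom.csv`` — inbreeding coefficients
* ``incidence.tsv`` — per-SNP incidence track (Manhattan-ready)
* ``islands.csv`` (1-based inclusive) and ``islands.bed`` (0-based half-open)
* ``island_genes.csv`` — only when a gene annotation is supplied
* ``run_manifest.json`` — every parameter, comparator and seed, plus a
  sha256 per output, so identical (inputs, config, seed) give an identical
  manifest.

Outputs are pure functions of the inputs, the configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import load_genes
from .errors import StageError
from .inbreeding import GenerationThresholds, GenomeSpec
from .io import GenotypeMatrix
from .model import ROHInbreedingModel
from .qc import QCThresholds
from .roh import ROHParams

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: str | Path
    ped_path: str | Path | None = None
    map_path: str | Path | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    roh: ROHParams = field(default_factory=ROHParams)
    recompute_min_snps: bool = False
    generations: tuple[int, ...] = (3, 6, 9)
    genome: GenomeSpec | None = None
    island_freq_min: float = 0.5
    island_p_max: float = 0.01
    island_min_sig_snps: int = 3
    pvalue_method: str = "closed_form"
    reps: int = 1_000_000
    seed: int | None = None
    annotation_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.pvalue_method == "monte_carlo" and self.seed is None:
            raise ValueError("Monte-Carlo island p-values require a seed")


def _write(df, path: Path, sep: str) -> None:
    df.to_csv(path, sep=sep, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, genotypes: GenotypeMatrix | None = None) -> dict:
    """Run every stage and write the report bundle.

    ``genotypes`` may be passed directly (e.g. fresh from the simulator);
    otherwise the PED/MAP paths of the config are read.  Returns the run
    manifest (also written as ``run_manifest.json``).  A stage failure
    raises :class:`StageError` naming the stage; files already written by
    earlier stages are listed as stale in the exception message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name):
        def deco(fn):
            def wrapper(*a, **kw):
                try:
                    return fn(*a, **kw)
                except Exception as exc:
                    stale = ", ".join(p.name for p in written) or "none"
                    raise StageError(
                        f"stage '{name}' failed: {exc} (stale partial outputs: {stale})"
                    ) from exc
            return wrapper
        return deco

    @stage("input")
    def _load():
        if genotypes is not None:
            return genotypes
        if cfg.ped_path is None or cfg.map_path is None:
            raise ValueError("either genotypes or ped/map paths are required")
        from .io import read_ped_map

        return read_ped_map(cfg.ped_path, cfg.map_path)

    gm = _load()

    @stage("analysis")
    def _fit():
        model = ROHInbreedingModel(
            gm,
            roh_params=cfg.roh,
            genome=cfg.genome,
            generations=cfg.generations,
            qc=cfg.qc,
            recompute_min_snps=cfg.recompute_min_snps,
            island_freq_min=cfg.island_freq_min,
            island_p_max=cfg.island_p_max,
            island_min_sig_snps=cfg.island_min_sig_snps,
        )
        return model.fit(method=cfg.pvalue_method, reps=cfg.reps, seed=cfg.seed)

    res = _fit()

    @stage("report")
    def _report():
        qc_table = res.het.per_snp.merge(
            res.hwe.per_snp[["snp_id", "hwe_p"]], on="snp_id"
        )
        by_chrom = res.het.per_chromosome.merge(
            res.hwe.per_chromosome, on="chromosome", suffixes=("", "_hwe")
        )
        files = {
            "qc_summary.tsv": (qc_table, "\t"),
            "het_hwe_by_chrom.tsv": (by_chrom, "\t"),
            "roh_segments.tsv": (res.segments_frame(), "\t"),
            "roh_length_classes.tsv": (res.length_classes(), "\t"),
            "froh_individual.csv": (res.inbreeding_frame("genome"), ","),
            "froh_by_chrom.csv": (res.inbreeding_frame("chromosome"), ","),
            "incidence.tsv": (res.incidence.per_snp, "\t"),
            "islands.csv": (res.islands_frame(), ","),
        }
        for name, (df, sep) in files.items():
            path = out / name
            _write(df, path, sep)
            written.append(path)
        # islands as BED: convert 1-based inclusive -> 0-based half-open
        bed = out / "islands.bed"
        with open(bed, "w") as fh:
            for isl in res.islands:
                fh.write(
                    f"{isl.chromosome}\t{isl.start_bp - 1}\t{isl.end_bp}\t"
                    f"island_{isl.island_id}\t{isl.mean_p:.6g}\n"
                )
        written.append(bed)
        if cfg.annotation_path is not None:
            genes = load_genes(cfg.annotation_path)
            ann = res.annotate(genes)
            ann = ann.assign(genes=ann["genes"].map(";".join))
            path = out / "island_genes.csv"
            _write(ann, path, ",")
            written.append(path)

    _report()

    manifest = {
        "config": {
            "qc": dataclasses.asdict(cfg.qc),
            "roh_params": dataclasses.asdict(res.params),
            "recompute_min_snps": cfg.recompute_min_snps,
            "min_snps_recomputed": res.min_snps_recomputed,
            "generations": list(cfg.generations),
            "generation_thresholds_mb": res.thresholds.thresholds_mb,
            "genome_total_bp": res.genome.total,
            "island": {
                "freq_min": cfg.island_freq_min,
                "p_max": cfg.island_p_max,
                "min_sig_snps": cfg.island_min_sig_snps,
                "pvalue_method": cfg.pvalue_method,
                "reps": cfg.reps if cfg.pvalue_method == "monte_carlo" else None,
                "seed": cfg.seed,
            },
            "comparators": {
                "snp_call_rate": cfg.qc.snp_comparator,
                "individual_call_rate": cfg.qc.individual_comparator,
                "window_support": ">=",
                "generation_threshold": ">=",
                "island_frequency": ">=",
                "island_p": "<",
            },
        },
        "n_individuals": res.genotypes.n_individuals,
        "n_snps": res.genotypes.n_markers,
        "n_roh": len(res.segments),
        "n_islands": len(res.islands),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d outputs in %s", len(written) + 1, out)
    return manifest
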