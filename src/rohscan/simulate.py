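"""Synthetic SNP-array populations with planted homozygous structure.

The generator emulates a 70k equine array cohort: 31 autosomes totalling
~2.28 Gb covered by ~64k SNPs, background heterozygosity ~0.32, per-
individual autozygous tracts drawn from four length classes (the observed
landscape is dominated by short runs: roughly 76/13/9/2% across
<5.5 / 5.5-8.3 / 8.3-16.6 / >=16.6 Mb), and optional shared homozygous
"island" regions carried by a chosen fraction of individuals.

Background SNPs are independent given their allele frequency (no linkage
disequilibrium): every downstream statistic in this package depends only on
hom/het/missing runs, and independence keeps the chance-run probability
analyzable — a 52-SNP all-homozygous window arises by chance with
probability (1-het)^52 ~ 1.6e-9 at het 0.32.  Allele frequencies are drawn
from a symmetric Beta(a, a); the shape giving mean heterozygosity h is
a = h / (1 - 2h) (from E[2p(1-p)] = 1/2 - 1/(2(2a+1))).

Planted tracts and island carriers overwrite genotypes with the
major-allele homozygote; missingness is applied after planting.  The short
tract class starts at 2 Mb: at the array density (~28 SNPs/Mb) a tract
below ~1.85 Mb carries fewer SNPs than the 52-SNP detection floor, and the
landscape being emulated is itself a landscape of *detected* runs.

Identical seeds give identical populations, PED output included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GT, GenotypeMatrix, Marker, canonicalize_calls

__all__ = ["ChromosomeSpec", "IslandSpec", "SimConfig", "TruthSet", "simulate_population",
           "equcab_like_chromosomes"]

#: Total autosomal bp covered by the emulated array.
_TOTAL_BP = 2_276_871_601
#: Total SNPs on the emulated array after QC.
_TOTAL_SNPS = 64_203

# Approximate horse autosome lengths (Mb), largest to smallest, rescaled so
# the 31 autosomes sum exactly to the covered-genome constant.
_EQCAB_MB = [
    188, 121, 121, 109, 96, 87, 100, 97, 85, 85, 61, 36, 43, 94, 92, 88,
    81, 82, 62, 65, 58, 50, 56, 48, 40, 43, 40, 48, 34, 31, 26,
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated autosome: index, physical length and SNP count."""

    index: int
    length_bp: int
    n_snps: int


def equcab_like_chromosomes(
    total_bp: int = _TOTAL_BP, total_snps: int = _TOTAL_SNPS, n_chromosomes: int = 31
) -> list[ChromosomeSpec]:
    """31 autosomes with horse-like relative sizes summing to ``total_bp``,
    SNPs apportioned proportionally (largest-remainder rounding)."""
    rel = np.array(_EQCAB_MB[:n_chromosomes], dtype=float)
    lengths = np.floor(rel / rel.sum() * total_bp).astype(np.int64)
    lengths[0] += total_bp - lengths.sum()
    quota = lengths / lengths.sum() * total_snps
    snps = np.floor(quota).astype(np.int64)
    remainder = total_snps - snps.sum()
    order = np.argsort(-(quota - snps))
    snps[order[:remainder]] += 1
    return [
        ChromosomeSpec(i + 1, int(lengths[i]), int(snps[i])) for i in range(n_chromosomes)
    ]


@dataclass(frozen=True)
class IslandSpec:
    """A shared homozygous region: every carrier gets a tract over the span."""

    chromosome: int
    center_bp: int
    span_bp: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in [0, 1]")
        if self.span_bp <= 0:
            raise ValueError("span_bp must be positive")


#: Expected tract counts per individual per length class, mimicking the
#: emulated cohort's 79.5 runs/individual split 76/13/9/2%.
DEFAULT_TRACTS_PER_CLASS = (60.8, 10.0, 7.3, 1.5)
#: Length-class bounds in Mb (uniform within class; short class floored at
#: the detectability limit, see module docstring).
DEFAULT_CLASS_BOUNDS_MB = ((2.0, 5.5), (5.5, 8.3), (8.3, 16.6), (16.6, 35.0))


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the defaults emulate the study cohort."""

    seed: int
    n_individuals: int = 506
    chromosomes: tuple[ChromosomeSpec, ...] = tuple(equcab_like_chromosomes())
    target_het: float = 0.32
    missing_rate: float = 0.005
    tract_error_rate: float = 0.0
    tracts_per_class: tuple[float, ...] = DEFAULT_TRACTS_PER_CLASS
    class_bounds_mb: tuple[tuple[float, float], ...] = DEFAULT_CLASS_BOUNDS_MB
    islands: tuple[IslandSpec, ...] = ()

    def __post_init__(self) -> None:
        for name in ("missing_rate", "tract_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.target_het <= 0.5:
            raise ValueError(
                f"target heterozygosity must be in (0, 0.5], got {self.target_het}"
            )
        if len(self.tracts_per_class) != len(self.class_bounds_mb):
            raise ValueError("tracts_per_class and class_bounds_mb lengths differ")
        chrom_len = {c.index: c.length_bp for c in self.chromosomes}
        for isl in self.islands:
            if isl.chromosome not in chrom_len:
                raise ValueError(f"island on unknown chromosome {isl.chromosome}")
            if isl.span_bp >= chrom_len[isl.chromosome]:
                raise ValueError("island span must be smaller than its chromosome")

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)


@dataclass
class TruthSet:
    """Ground truth of a simulated population.

    ``tracts`` maps individual -> list of (chromosome, start_bp, end_bp)
    planted homozygous tracts (island tracts included); ``islands`` lists
    (spec, carrier ids); ``coverage`` maps individual -> q, the planted
    union length divided by the genome length.
    """

    tracts: dict[str, list[tuple[int, int, int]]]
    islands: list[tuple[IslandSpec, list[str]]]
    coverage: dict[str, float]


def _merged_length(intervals: list[tuple[int, int, int]]) -> int:
    by_chrom: dict[int, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def _beta_shape(target_het: float) -> float:
    # E[2p(1-p)] under Beta(a, a) is 1/2 - 1/(2(2a+1)); invert for a
    if target_het >= 0.5:
        return np.inf
    return target_het / (1.0 - 2.0 * target_het)


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate((pos, extra)))
    return pos[:n]


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate a genotyped cohort and its ground truth.

    Raises ``ValueError`` for an infeasible heterozygosity target (> 0.5).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    individuals = [f"I{i + 1:04d}" for i in range(n)]

    markers: list[Marker] = []
    freqs: list[np.ndarray] = []
    a = _beta_shape(cfg.target_het)
    base_pairs = np.array(list("ACGT"))
    chrom_offsets: dict[int, int] = {}
    for chrom in cfg.chromosomes:
        chrom_offsets[chrom.index] = len(markers)
        pos = _draw_positions(rng, chrom.n_snps, chrom.length_bp)
        p = rng.beta(a, a, size=chrom.n_snps)
        freqs.append(p)
        pair_idx = rng.integers(0, 4, size=(chrom.n_snps, 2))
        # resample collisions, then sort alphabetically for canonical coding
        while True:
            clash = pair_idx[:, 0] == pair_idx[:, 1]
            if not clash.any():
                break
            pair_idx[clash, 1] = rng.integers(0, 4, size=int(clash.sum()))
        pair_idx.sort(axis=1)
        for k in range(chrom.n_snps):
            markers.append(
                Marker(
                    f"snp_{chrom.index}_{k + 1}",
                    chrom.index,
                    int(pos[k]),
                    (str(base_pairs[pair_idx[k, 0]]), str(base_pairs[pair_idx[k, 1]])),
                )
            )
    m = len(markers)
    p_alt = np.concatenate(freqs)
    positions = np.array([mk.position_bp for mk in markers], dtype=np.int64)

    # background genotypes: two independent allele draws per call (HWE)
    calls = (
        (rng.random((n, m)) < p_alt).astype(np.int8)
        + (rng.random((n, m)) < p_alt).astype(np.int8)
    )

    # plant per-individual tracts
    chrom_lengths = np.array([c.length_bp for c in cfg.chromosomes], dtype=float)
    chrom_weights = chrom_lengths / chrom_lengths.sum()
    tracts: dict[str, list[tuple[int, int, int]]] = {ind: [] for ind in individuals}
    for i, ind in enumerate(individuals):
        for mean_count, (lo_mb, hi_mb) in zip(cfg.tracts_per_class, cfg.class_bounds_mb):
            for _ in range(rng.poisson(mean_count)):
                length = int(rng.uniform(lo_mb, hi_mb) * 1e6)
                ci = rng.choice(len(cfg.chromosomes), p=chrom_weights)
                chrom = cfg.chromosomes[ci]
                if length >= chrom.length_bp:
                    length = chrom.length_bp - 1
                start = int(rng.integers(1, chrom.length_bp - length + 1))
                tracts[ind].append((chrom.index, start, start + length))

    # island carriers
    islands_truth: list[tuple[IslandSpec, list[str]]] = []
    for isl in cfg.islands:
        n_carriers = int(round(isl.carrier_fraction * n))
        carrier_idx = rng.choice(n, size=n_carriers, replace=False)
        carriers = sorted(individuals[i] for i in carrier_idx)
        half = isl.span_bp // 2
        chrom_len = next(c.length_bp for c in cfg.chromosomes if c.index == isl.chromosome)
        start = max(1, isl.center_bp - half)
        end = min(chrom_len, isl.center_bp + half)
        for ind in carriers:
            tracts[ind].append((isl.chromosome, start, end))
        islands_truth.append((isl, carriers))

    # overwrite planted intervals with the major-allele homozygote
    major_hom = np.where(p_alt >= 0.5, GT.HOM_ALT, GT.HOM_REF).astype(np.int8)
    chrom_pos = {c.index: positions[chrom_offsets[c.index]:
                                    chrom_offsets[c.index] + c.n_snps]
                 for c in cfg.chromosomes}
    for i, ind in enumerate(individuals):
        for chrom_idx, start, end in tracts[ind]:
            cpos = chrom_pos[chrom_idx]
            off = chrom_offsets[chrom_idx]
            lo = off + int(np.searchsorted(cpos, start, side="left"))
            hi = off + int(np.searchsorted(cpos, end, side="right"))
            calls[i, lo:hi] = major_hom[lo:hi]
            if cfg.tract_error_rate > 0 and hi > lo:
                err = rng.random(hi - lo) < cfg.tract_error_rate
                calls[i, lo:hi][err] = GT.HET

    if cfg.missing_rate > 0:
        calls[rng.random((n, m)) < cfg.missing_rate] = GT.MISSING

    total_bp = cfg.total_bp
    coverage = {
        ind: (_merged_length(tracts[ind]) / total_bp if tracts[ind] else 0.0)
        for ind in individuals
    }
    # canonical observational coding so PED round trips are exact
    calls, pairs = canonicalize_calls(calls, [mk.alleles for mk in markers])
    markers = [
        Marker(mk.snp_id, mk.chromosome, mk.position_bp, pair)
        for mk, pair in zip(markers, pairs)
    ]
    gm = GenotypeMatrix(individuals, markers, calls)
    truth = TruthSet(tracts=tracts, islands=islands_truth, coverage=coverage)
    return gm, truth
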