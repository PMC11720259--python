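"""SNP incidence in ROH, randomization enrichment p-values, and ROH islands.

For every SNP the incidence ``c`` is the number of individuals whose ROH
covers it.  Under the null that runs fall uniformly on the chromosome, a
random incidence ``r`` is drawn uniformly on the integers ``{0, ..., M}``
with ``M`` the chromosome's maximum incidence; the enrichment p-value is
the upper tail ``P(r >= c) = (M - c + 1) / (M + 1)``, so small p marks high
incidence.  The closed form is exact and is the default; a Monte-Carlo
estimator (one seeded stream per chromosome, chromosomes in ascending
order) reproduces it to sampling error and is kept for fidelity and
testing.  The lower-tail reading ``P(c > r)`` is available behind
``tail="literal"`` but is not used for island calling.

A ROH island is a maximal stretch of consecutive SNPs whose in-ROH
frequency is at least 50%, reported when it contains at least three SNPs
with p below 0.01.  Island boundaries are the stretch's first and last SNP
positions (1-based inclusive); ``length_bp = end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .roh import ROHSegment

__all__ = [
    "IncidenceTrack",
    "ROHIsland",
    "snp_incidence",
    "incidence_pvalues",
    "call_islands",
    "islands_to_frame",
]


@dataclass
class IncidenceTrack:
    """Per-SNP ROH incidence with optional p-values.

    ``per_snp`` columns: snp_id, chromosome, position_bp, count, frequency,
    and p once :func:`incidence_pvalues` has run.  ``max_per_chromosome``
    maps chromosome -> maximum incidence.
    """

    per_snp: pd.DataFrame
    n_individuals: int
    max_per_chromosome: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.max_per_chromosome and len(self.per_snp):
            self.max_per_chromosome = {
                int(c): int(v)
                for c, v in self.per_snp.groupby("chromosome")["count"].max().items()
            }


@dataclass(frozen=True)
class ROHIsland:
    """A called ROH-enriched region (coordinates 1-based inclusive)."""

    island_id: int
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_significant: int
    mean_p: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def snp_incidence(segments: list[ROHSegment], gm: GenotypeMatrix) -> IncidenceTrack:
    """Count, per SNP, the individuals whose ROH covers it.

    A segment covers a SNP when its closed interval [start_bp, end_bp]
    contains the SNP position.  Segments of one individual never overlap
    (guaranteed by detection), so each individual is counted at most once.
    """
    counts = np.zeros(gm.n_markers, dtype=np.int64)
    slices = gm.chromosome_slices()
    for seg in segments:
        sl = slices.get(seg.chromosome)
        if sl is None:
            continue
        pos = gm.positions[sl]
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
        counts[sl.start + lo : sl.start + hi] += 1
    per_snp = pd.DataFrame(
        {
            "snp_id": [m.snp_id for m in gm.markers],
            "chromosome": gm.chromosomes,
            "position_bp": gm.positions,
            "count": counts,
            "frequency": counts / gm.n_individuals if gm.n_individuals else 0.0,
        }
    )
    return IncidenceTrack(per_snp=per_snp, n_individuals=gm.n_individuals)


def incidence_pvalues(
    track: IncidenceTrack,
    reps: int = 1_000_000,
    seed: int | None = None,
    method: str = "closed_form",
    tail: str = "upper",
) -> IncidenceTrack:
    """Attach the randomization p-value to every SNP of the track.

    ``method="closed_form"`` computes ``(M - c + 1)/(M + 1)`` exactly;
    ``method="monte_carlo"`` draws ``reps`` uniform integers on ``{0..M}``
    per chromosome (streams seeded from ``seed`` and the chromosome index,
    chromosomes processed in ascending order).  ``tail="literal"`` gives
    the lower-tail proportion ``P(c > r)`` instead.  Chromosomes with
    ``M = 0`` get p = 1 everywhere.
    """
    if method not in ("closed_form", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if tail not in ("upper", "literal"):
        raise ValueError(f"unknown tail {tail!r}")
    if method == "monte_carlo":
        if reps <= 0:
            raise ValueError(f"reps must be positive, got {reps}")
        if seed is None:
            raise ValueError("monte_carlo mode requires a seed")

    df = track.per_snp.copy()
    p = np.ones(len(df))
    for chrom in sorted(track.max_per_chromosome):
        m_k = track.max_per_chromosome[chrom]
        idx = np.flatnonzero(df["chromosome"].to_numpy() == chrom)
        c = df["count"].to_numpy()[idx]
        if m_k == 0:
            p[idx] = 1.0
            continue
        if method == "closed_form":
            if tail == "upper":
                p[idx] = (m_k - c + 1) / (m_k + 1)
            else:
                p[idx] = c / (m_k + 1)
        else:
            rng = np.random.default_rng([seed, chrom])
            draws = rng.integers(0, m_k + 1, size=reps)
            hist = np.bincount(draws, minlength=m_k + 1)
            if tail == "upper":
                # tail_ge[v] = #draws >= v
                tail_ge = np.concatenate((np.cumsum(hist[::-1])[::-1], [0]))
                p[idx] = tail_ge[c] / reps
            else:
                below = np.concatenate(([0], np.cumsum(hist)))  # below[v] = #draws < v
                p[idx] = below[c] / reps
    df["p"] = p
    return IncidenceTrack(
        per_snp=df,
        n_individuals=track.n_individuals,
        max_per_chromosome=dict(track.max_per_chromosome),
    )


def call_islands(
    track: IncidenceTrack,
    freq_min: float = 0.5,
    p_max: float = 0.01,
    min_sig_snps: int = 3,
) -> list[ROHIsland]:
    """Call ROH islands from an incidence track with p-values.

    Islands are maximal stretches of consecutive SNPs with frequency >=
    ``freq_min``; a stretch is reported iff it holds >= ``min_sig_snps``
    SNPs with p < ``p_max``.  ``mean_p`` averages over every SNP of the
    stretch.  Output sorted by (chromosome, start); ids are 1-based.
    """
    if "p" not in track.per_snp.columns:
        raise ValueError("call_islands requires p-values; run incidence_pvalues first")
    islands: list[ROHIsland] = []
    df = track.per_snp
    for chrom, sub in df.groupby("chromosome", sort=True):
        freq = sub["frequency"].to_numpy()
        pvals = sub["p"].to_numpy()
        pos = sub["position_bp"].to_numpy()
        ok = freq >= freq_min
        if not ok.any():
            continue
        padded = np.concatenate(([False], ok, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for a, b in zip(edges[0::2], edges[1::2]):
            n_sig = int((pvals[a:b] < p_max).sum())
            if n_sig < min_sig_snps:
                continue
            islands.append(
                ROHIsland(
                    island_id=0,
                    chromosome=int(chrom),
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b - 1]),
                    n_snps=int(b - a),
                    n_significant=n_sig,
                    mean_p=float(pvals[a:b].mean()),
                )
            )
    islands.sort(key=lambda i: (i.chromosome, i.start_bp))
    return [
        ROHIsland(k + 1, i.chromosome, i.start_bp, i.end_bp, i.n_snps, i.n_significant, i.mean_p)
        for k, i in enumerate(islands)
    ]


def islands_to_frame(islands: list[ROHIsland]) -> pd.DataFrame:
    """Islands as a Table-style DataFrame (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "island_id": i.island_id,
                "chromosome": i.chromosome,
                "start_bp": i.start_bp,
                "end_bp": i.end_bp,
                "length_bp": i.length_bp,
                "n_snps": i.n_snps,
                "n_significant": i.n_significant,
                "mean_p": i.mean_p,
            }
            for i in islands
        ],
        columns=[
            "island_id",
            "chromosome",
            "start_bp",
            "end_bp",
            "length_bp",
            "n_snps",
            "n_significant",
            "mean_p",
        ],
    )
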