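"""Optional figures: per-chromosome F_ROH stacked bars and an incidence
Manhattan plot.  The tables, not the figures, are the analysis surface."""

from __future__ import annotations

import numpy as np

from .inbreeding import InbreedingRecord, records_to_frame
from .islands import IncidenceTrack, ROHIsland

__all__ = ["plot_froh_by_chromosome", "plot_incidence_manhattan"]


def plot_froh_by_chromosome(records: list[InbreedingRecord], ax=None):
    """Stacked bars of mean chromosome-scope F_ROH split into generation
    components (recent at the bottom, ancestral on top)."""
    import matplotlib.pyplot as plt

    df = records_to_frame(records)
    df = df[df["scope"] != "genome"]
    comp_cols = sorted(
        (c for c in df.columns if c.startswith("froh_") and c != "froh_anc"),
        key=lambda c: int(c.removeprefix("froh_").removesuffix("g")),
    )
    means = df.groupby("scope")[comp_cols + ["froh_anc", "froh"]].mean().sort_index()
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    bottom = np.zeros(len(means))
    # convert nested >= components to disjoint slices (3g, 6g-3g, 9g-6g, anc)
    prev = np.zeros(len(means))
    for col in comp_cols:
        h = means[col].to_numpy() - prev
        ax.bar(means.index.astype(str), h, bottom=bottom, label=col)
        bottom += h
        prev = means[col].to_numpy()
    ax.bar(means.index.astype(str), means["froh_anc"], bottom=bottom, label="froh_anc")
    ax.set_xlabel("chromosome")
    ax.set_ylabel("mean F_ROH")
    ax.legend(fontsize=8)
    return ax


def plot_incidence_manhattan(
    track: IncidenceTrack, islands: list[ROHIsland] | None = None, ax=None
):
    """SNP in-ROH frequency along the genome, islands highlighted."""
    import matplotlib.pyplot as plt

    df = track.per_snp
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    offset = 0
    ticks, labels = [], []
    offsets = {}
    for k, (chrom, sub) in enumerate(df.groupby("chromosome", sort=True)):
        x = sub["position_bp"].to_numpy() + offset
        ax.scatter(x, sub["frequency"], s=2, color=f"C{k % 2}", rasterized=True)
        offsets[chrom] = offset
        ticks.append(offset + sub["position_bp"].max() / 2)
        labels.append(str(chrom))
        offset += sub["position_bp"].max()
    for isl in islands or []:
        o = offsets.get(isl.chromosome, 0)
        ax.axvspan(o + isl.start_bp, o + isl.end_bp, color="red", alpha=0.3)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("in-ROH frequency")
    return ax
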