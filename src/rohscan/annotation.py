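"""Gene-interval annotation of ROH islands.

Gene intervals are normalized to 1-based inclusive coordinates and integer
autosome indices (labels like ``chr3``, ``ECA3`` and ``3`` are equivalent).
A gene is reported for an island when their closed intervals overlap by at
least one base pair; full containment is available behind a flag.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError
from .islands import ROHIsland

__all__ = ["GeneInterval", "load_genes", "annotate_islands"]

log = logging.getLogger(__name__)

_CHROM_RE = re.compile(r"^(?:chr|eca)?(\d+)$", re.IGNORECASE)


def _normalize_chromosome(label: str) -> int | None:
    m = _CHROM_RE.match(label.strip())
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class GeneInterval:
    """One annotated gene (1-based inclusive coordinates)."""

    name: str
    chromosome: int
    start_bp: int
    end_bp: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"gene {self.name}: end_bp must exceed start_bp "
                f"({self.start_bp}..{self.end_bp})"
            )


def _load_bed(path) -> list[GeneInterval]:
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >= 3 columns")
            chrom = _normalize_chromosome(parts[0])
            if chrom is None:
                log.warning("%s: line %d: unknown chromosome %r, skipped", path, lineno, parts[0])
                continue
            start0, end0 = int(parts[1]), int(parts[2])
            name = parts[3].strip() if len(parts) > 3 and parts[3].strip() else f"feature_{lineno}"
            # BED is 0-based half-open; internal convention 1-based inclusive
            genes.append(GeneInterval(name, chrom, start0 + 1, end0, source=f"{path}:{lineno}"))
    return genes


def _load_gff3(path) -> list[GeneInterval]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneInterval] = []
    for feat in db.features_of_type("gene"):
        chrom = _normalize_chromosome(feat.seqid)
        if chrom is None:
            log.warning("%s: unknown chromosome %r for %s, skipped", path, feat.seqid, feat.id)
            continue
        name = (
            feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("gene_id", [None])[0]
            or feat.id
        )
        # GFF3 is already 1-based inclusive
        genes.append(GeneInterval(name, chrom, feat.start, feat.end, source=f"{path}:{feat.id}"))
    return genes


def load_genes(path, fmt: str | None = None) -> list[GeneInterval]:
    """Load gene intervals from BED or GFF3.

    ``fmt`` is ``"bed"`` or ``"gff3"``; inferred from the extension when
    omitted.  GFF3 features are filtered to type ``gene``.  Records on
    unrecognized chromosomes (X, MT, scaffolds) are skipped with a warning.
    Duplicate gene names at different loci are all kept.
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        return _load_bed(path)
    if fmt == "gff3":
        return _load_gff3(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def annotate_islands(
    islands: list[ROHIsland],
    genes: list[GeneInterval],
    containment: bool = False,
) -> pd.DataFrame:
    """Report the genes overlapping each island.

    One row per island with ``genes`` as a list of names sorted by gene
    start (empty list when nothing overlaps).  ``containment=True``
    restricts to genes fully inside the island.
    """
    trees: dict[int, IntervalTree] = {}
    for g in genes:
        # intervaltree is half-open; +1 makes the closed gene interval inclusive
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)
    rows = []
    for isl in islands:
        hits: list[GeneInterval] = []
        tree = trees.get(isl.chromosome)
        if tree is not None:
            for iv in tree.overlap(isl.start_bp, isl.end_bp + 1):
                g = iv.data
                if containment and not (g.start_bp >= isl.start_bp and g.end_bp <= isl.end_bp):
                    continue
                hits.append(g)
        hits.sort(key=lambda g: (g.start_bp, g.end_bp, g.name))
        rows.append(
            {
                "island_id": isl.island_id,
                "chromosome": isl.chromosome,
                "start_bp": isl.start_bp,
                "end_bp": isl.end_bp,
                "n_genes": len(hits),
                "genes": [g.name for g in hits],
            }
        )
    return pd.DataFrame(
        rows, columns=["island_id", "chromosome", "start_bp", "end_bp", "n_genes", "genes"]
    )
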