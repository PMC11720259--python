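"""PLINK text (PED/MAP) genotype I/O and the in-memory genotype container.

Genotypes are stored phase-free as small integer codes: ``HOM_REF`` and
``HOM_ALT`` distinguish the two homozygotes (allele pair ordered
lexicographically, so the coding is deterministic), ``HET`` has no allele
order, and ``MISSING`` covers both ``0 0`` and half-called pairs.  All
downstream run-of-homozygosity logic depends only on hom/het/missing, so the
reference/alternate labelling is a bookkeeping convention, not a biological
claim.

Coordinates follow the MAP convention: 1-based, inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "GT",
    "Marker",
    "GenotypeMatrix",
    "read_ped_map",
    "write_ped_map",
    "canonicalize_calls",
]


class GT(enum.IntEnum):
    """Genotype codes used in :class:`GenotypeMatrix.calls`."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


#: Valid allele symbols in PED files (letter or numeric dialect; 0 = missing).
_ALLELE_SYMBOLS = frozenset("ACGT120")


@dataclass(frozen=True)
class Marker:
    """One SNP of the array map.

    ``alleles`` is the ordered pair backing the HOM_REF/HOM_ALT codes;
    ``alleles[0]`` is the lexicographically smaller symbol when both were
    observed, and ``"0"`` stands in for the unobserved allele of a
    monomorphic SNP.
    """

    snp_id: str
    chromosome: int
    position_bp: int
    alleles: tuple[str, str] = ("0", "0")

    def __post_init__(self) -> None:
        if self.position_bp <= 0:
            raise ValidationError(
                f"marker {self.snp_id}: position_bp must be positive, got {self.position_bp}"
            )
        if self.chromosome < 1:
            raise ValidationError(
                f"marker {self.snp_id}: chromosome index must be >= 1, got {self.chromosome}"
            )


class GenotypeMatrix:
    """Individuals x SNPs genotype codes plus the marker map.

    Parameters
    ----------
    individuals
        Sample identifiers, in PED row order.
    markers
        One :class:`Marker` per SNP, grouped by chromosome with strictly
        ascending positions inside each chromosome block.
    calls
        ``(n_individuals, n_markers)`` array of :class:`GT` codes.
    fam
        Optional PED metadata (fid/iid/pat/mat/sex/phenotype) used to make
        write->read round trips byte-identical; synthesized when absent.
    """

    def __init__(
        self,
        individuals: list[str],
        markers: list[Marker],
        calls: np.ndarray,
        fam: pd.DataFrame | None = None,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(individuals), len(markers)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(individuals)} individuals x {len(markers)} markers"
            )
        valid = np.isin(calls, (GT.MISSING, GT.HOM_REF, GT.HET, GT.HOM_ALT))
        if not valid.all():
            bad = calls[~valid][0]
            raise ValidationError(f"invalid genotype code {bad}; expected -1/0/1/2")
        if len(set(individuals)) != len(individuals):
            raise ValidationError("duplicate individual identifiers")
        ids = [m.snp_id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNP identifiers")

        self.individuals = list(individuals)
        self.markers = list(markers)
        self.calls = calls
        self.chromosomes = np.array([m.chromosome for m in markers], dtype=np.int64)
        self.positions = np.array([m.position_bp for m in markers], dtype=np.int64)
        self._check_sorted()
        if fam is None:
            fam = pd.DataFrame(
                {
                    "fid": individuals,
                    "iid": individuals,
                    "pat": "0",
                    "mat": "0",
                    "sex": "0",
                    "phenotype": "-9",
                }
            )
        self.fam = fam.reset_index(drop=True)

    def _check_sorted(self) -> None:
        # chromosome blocks must be contiguous, positions strictly ascending
        chroms = self.chromosomes
        seen: set[int] = set()
        prev = None
        for c in chroms:
            if c != prev:
                if c in seen:
                    raise ValidationError(f"chromosome {c} markers are not contiguous")
                seen.add(int(c))
                prev = c
        same_chrom = chroms[1:] == chroms[:-1]
        if np.any(same_chrom & (np.diff(self.positions) <= 0)):
            j = int(np.flatnonzero(same_chrom & (np.diff(self.positions) <= 0))[0])
            raise ValidationError(
                f"markers not strictly ascending within chromosome {chroms[j]} "
                f"near SNP {self.markers[j + 1].snp_id}"
            )

    # -- shape ---------------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def chromosome_slices(self) -> dict[int, slice]:
        """Column slice of each chromosome block, in order of appearance."""
        out: dict[int, slice] = {}
        chroms = self.chromosomes
        if chroms.size == 0:
            return out
        breaks = np.flatnonzero(np.diff(chroms) != 0) + 1
        starts = np.concatenate(([0], breaks))
        stops = np.concatenate((breaks, [chroms.size]))
        for s, e in zip(starts, stops):
            out[int(chroms[s])] = slice(int(s), int(e))
        return out

    # -- subsetting ----------------------------------------------------------

    def subset(
        self,
        individual_idx: np.ndarray | list[int] | None = None,
        marker_idx: np.ndarray | list[int] | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset preserving order; indices are positional."""
        ii = np.arange(self.n_individuals) if individual_idx is None else np.asarray(individual_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            [self.individuals[i] for i in ii],
            [self.markers[j] for j in mi],
            self.calls[np.ix_(ii, mi)],
            fam=self.fam.iloc[ii],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GenotypeMatrix {self.n_individuals} individuals x "
            f"{self.n_markers} SNPs on {len(self.chromosome_slices())} chromosomes>"
        )


def canonicalize_calls(
    calls: np.ndarray, allele_pairs: list[tuple[str, str]]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Rewrite codes/alleles to the observational convention of PED text.

    MAP files carry no allele column, so a reader can only code what it
    observes: at a SNP where a single allele appears, that allele is the
    reference and the homozygote is HOM_REF.  Applying this rule before
    writing makes write->read an exact identity on codes.  ROH statistics
    are invariant to the relabelling.
    """
    calls = np.asarray(calls, dtype=np.int8).copy()
    out_pairs: list[tuple[str, str]] = []
    ref_seen = ((calls == GT.HOM_REF) | (calls == GT.HET)).any(axis=0)
    alt_seen = ((calls == GT.HOM_ALT) | (calls == GT.HET)).any(axis=0)
    for j, (ref, alt) in enumerate(allele_pairs):
        if ref_seen[j] and alt_seen[j]:
            out_pairs.append((ref, alt))
        elif alt_seen[j]:
            calls[calls[:, j] == GT.HOM_ALT, j] = GT.HOM_REF
            out_pairs.append((alt, "0"))
        elif ref_seen[j]:
            out_pairs.append((ref, "0"))
        else:
            out_pairs.append(("0", "0"))
    return calls, out_pairs


def _read_map(map_path) -> list[tuple[str, int, int]]:
    rows: list[tuple[str, int, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise ParseError(f"{map_path}: line {lineno}: expected 3 or 4 columns, got {len(parts)}")
            chrom_s, snp_id = parts[0], parts[1]
            pos_s = parts[-1]
            try:
                chrom = int(chrom_s.lower().removeprefix("chr").removeprefix("eca"))
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{map_path}: line {lineno}: {exc}") from None
            rows.append((snp_id, chrom, pos))
    return rows


def read_ped_map(ped_path, map_path, sort_markers: bool = False) -> GenotypeMatrix:
    """Read a PLINK text fileset into a :class:`GenotypeMatrix`.

    ``0 0`` (or half-called) genotype pairs become :data:`GT.MISSING`; a pair
    of two different non-missing alleles is :data:`GT.HET`.  Allele pairs are
    ordered lexicographically so the homozygote coding does not depend on row
    order.  Markers must already be position-sorted within each chromosome
    unless ``sort_markers`` is set.

    Raises
    ------
    ParseError
        On a PED/MAP dimension mismatch (names the line), a marker carrying
        more than two alleles (names the SNP), or unparseable fields.
    ValidationError
        If markers are unsorted and ``sort_markers`` is False.
    """
    map_rows = _read_map(map_path)
    m = len(map_rows)

    fam_rows: list[list[str]] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"for {m} MAP markers, got {len(parts)}"
                )
            fam_rows.append(parts[:6])
            allele_rows.append(np.array(parts[6:], dtype="U1"))

    n = len(fam_rows)
    alleles = (
        np.stack(allele_rows) if n else np.empty((0, 2 * m), dtype="U1")
    )
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]

    calls = np.full((n, m), GT.MISSING, dtype=np.int8)
    marker_alleles: list[tuple[str, str]] = []
    for j in range(m):
        cj1, cj2 = a1[:, j], a2[:, j]
        missing = (cj1 == "0") | (cj2 == "0")
        observed = np.unique(np.concatenate((cj1[~missing], cj2[~missing])))
        bad = [s for s in observed if s not in _ALLELE_SYMBOLS]
        if bad:
            raise ParseError(f"SNP {map_rows[j][0]}: invalid allele symbol {bad[0]!r}")
        if observed.size > 2:
            raise ParseError(
                f"SNP {map_rows[j][0]}: more than 2 alleles observed: {', '.join(observed)}"
            )
        if observed.size == 2:
            ref, alt = sorted(observed)
        elif observed.size == 1:
            ref, alt = observed[0], "0"
        else:
            ref, alt = "0", "0"
        marker_alleles.append((str(ref), str(alt)))
        het = ~missing & (cj1 != cj2)
        hom_alt = ~missing & ~het & (cj1 == alt)
        hom_ref = ~missing & ~het & ~hom_alt
        calls[hom_ref, j] = GT.HOM_REF
        calls[het, j] = GT.HET
        calls[hom_alt, j] = GT.HOM_ALT

    markers = [
        Marker(snp_id, chrom, pos, marker_alleles[j])
        for j, (snp_id, chrom, pos) in enumerate(map_rows)
    ]

    fam = pd.DataFrame(fam_rows, columns=["fid", "iid", "pat", "mat", "sex", "phenotype"])
    individuals = list(fam["iid"])
    if len(set(individuals)) != len(individuals):
        # fall back to fid_iid keys when iid alone is ambiguous
        individuals = [f"{f}_{i}" for f, i in zip(fam["fid"], fam["iid"])]

    if sort_markers:
        order = np.lexsort((np.array([mk.position_bp for mk in markers]),
                            np.array([mk.chromosome for mk in markers])))
        markers = [markers[k] for k in order]
        calls = calls[:, order]
    return GenotypeMatrix(individuals, markers, calls, fam=fam)


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a :class:`GenotypeMatrix` as PLINK text, readable by
    :func:`read_ped_map`.  MISSING is written as ``0 0``; HET is written as
    ``a1 a2`` in the marker's stored allele order.
    """
    with open(map_path, "w") as fh:
        for mk in gm.markers:
            fh.write(f"{mk.chromosome}\t{mk.snp_id}\t0\t{mk.position_bp}\n")

    # genotype-code -> allele-pair lookup per marker, then one big fancy-index
    m = gm.n_markers
    lut = np.empty((m, 4), dtype="U3")  # rows: marker; cols: code+1 (MISSING..HOM_ALT)
    for j, mk in enumerate(gm.markers):
        ref, alt = mk.alleles
        lut[j, 0] = "0 0"
        lut[j, 1] = f"{ref} {ref}"
        lut[j, 2] = f"{ref} {alt}" if alt != "0" else "0 0"
        lut[j, 3] = f"{alt} {alt}" if alt != "0" else "0 0"
    cols = np.arange(m)
    with open(ped_path, "w") as fh:
        for i in range(gm.n_individuals):
            meta = gm.fam.iloc[i]
            geno = lut[cols, gm.calls[i] + 1]
            fh.write(
                f"{meta.fid} {meta.iid} {meta.pat} {meta.mat} {meta.sex} {meta.phenotype} "
                + " ".join(geno)
                + "\n"
            )
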