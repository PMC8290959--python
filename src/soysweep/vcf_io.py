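"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: VCF positions are 1-based inclusive at ingestion;
all internal windows, gene regions and BED output are 0-based half-open.
Missing alleles are encoded as -1 in the haplotype matrix and every
frequency is computed over non-missing chromosomes only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

SUBPOPULATIONS = ("S", "L", "C")
TRAIT_COLUMNS = ("seed_weight_100", "fatty_acid_pct", "protein_pct")

MISSING = -1


class VCFFormatError(ValueError):
    """Raised when a VCF record violates the biallelic / GT contract."""


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant (SNP or short In/Del).

    ``pos`` is the 1-based VCF coordinate; ``maf`` is the minor-allele
    frequency over non-missing chromosomes, always in [0, 0.5] and 0 for a
    monomorphic site.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    is_indel: bool
    maf: float

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class HaplotypeMatrix:
    """Phased alleles for a cohort: one row per chromosome, two per accession.

    ``alleles`` is an (2 * n_accessions, n_sites) int8 array with entries in
    {0, 1, -1} (-1 = missing).  Chromosome rows ``2*i`` and ``2*i + 1`` belong
    to accession ``accessions[i]``.  ``phased`` is False when any
    heterozygous genotype was read unphased; EHH operations require True.
    """

    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    ref: np.ndarray
    alt: np.ndarray
    is_indel: np.ndarray
    alleles: np.ndarray
    accessions: list[str]
    phased: bool = True

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (chromosomes x sites)")
        if self.alleles.shape[0] != 2 * len(self.accessions):
            raise ValueError("need exactly 2 chromosome rows per accession")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("site count mismatch")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per site over non-missing chromosomes."""
        present = self.alleles != MISSING
        n = present.sum(axis=0)
        k = np.where(self.alleles == 1, 1, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, k / np.maximum(n, 1), 0.0)
        return np.minimum(p, 1.0 - p)

    def sites(self) -> list[VariantSite]:
        maf = self.maf()
        return [
            VariantSite(self.chrom, int(p), str(r), str(a), bool(i), float(m))
            for p, r, a, i, m in zip(self.positions, self.ref, self.alt, self.is_indel, maf)
        ]

    def chromosome_rows(self, accessions: Iterable[str]) -> np.ndarray:
        """Row indices of both chromosomes of each named accession."""
        index = {a: i for i, a in enumerate(self.accessions)}
        rows = []
        for acc in accessions:
            if acc not in index:
                raise KeyError(f"accession {acc!r} not in matrix")
            rows.extend((2 * index[acc], 2 * index[acc] + 1))
        return np.asarray(rows, dtype=np.intp)

    def subset_sites(self, mask: np.ndarray) -> "HaplotypeMatrix":
        mask = np.asarray(mask)
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[mask],
            ref=np.asarray(self.ref)[mask],
            alt=np.asarray(self.alt)[mask],
            is_indel=np.asarray(self.is_indel)[mask],
            alleles=self.alleles[:, mask],
            accessions=list(self.accessions),
            phased=self.phased,
        )


@dataclass
class AnnotationTrack:
    """Genomic intervals (0-based half-open) with a name and a category."""

    intervals: pd.DataFrame  # columns: chrom, start, end, name, category

    def __post_init__(self):
        required = ["chrom", "start", "end", "name", "category"]
        missing = [c for c in required if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"annotation track missing columns {missing}")
        bad = self.intervals[self.intervals.start >= self.intervals.end]
        if len(bad):
            raise ValueError("annotation intervals must satisfy start < end")


def read_vcf(path: str | Path) -> HaplotypeMatrix:
    """Read a biallelic phased VCF into a :class:`HaplotypeMatrix`.

    Phased genotypes ``a|b`` contribute their two alleles in order; an
    unphased genotype is accepted only when homozygous (phase unambiguous).
    Any unphased heterozygote marks the whole matrix unphased.  ``.``
    alleles become missing.  Multiallelic records are rejected.
    """
    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    positions, refs, alts, indels, rows = [], [], [], [], []
    phased = True
    chrom = None
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise VCFFormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} (ALT={rec.ALT})"
            )
        if chrom is None:
            chrom = rec.CHROM
        elif rec.CHROM != chrom:
            raise VCFFormatError(
                f"expected single-chromosome VCF, found {chrom} and {rec.CHROM}"
            )
        col = np.empty(2 * len(accessions), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            if gt is None or len(gt) < 3:
                raise VCFFormatError(f"missing GT at {rec.CHROM}:{rec.POS}")
            a, b, is_phased = gt[0], gt[1], gt[-1]
            if not is_phased and a != b and a >= 0 and b >= 0:
                phased = False
            col[2 * i] = a if a >= 0 else MISSING
            col[2 * i + 1] = b if b >= 0 else MISSING
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        indels.append(len(rec.REF) != 1 or len(rec.ALT[0]) != 1)
        rows.append(col)
    if chrom is None:
        raise VCFFormatError(f"no records in {path}")
    alleles = np.stack(rows, axis=1) if rows else np.empty((2 * len(accessions), 0), np.int8)
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        is_indel=np.asarray(indels, dtype=bool),
        alleles=alleles,
        accessions=accessions,
        phased=phased,
    )


def write_vcf(matrix: HaplotypeMatrix, path: str | Path) -> Path:
    """Write a :class:`HaplotypeMatrix` as an uncompressed VCFv4.2 file."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={matrix.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.accessions),
    ]
    def allele_str(a: int) -> str:
        return "." if a == MISSING else str(int(a))

    for j in range(matrix.n_sites):
        gts = [
            f"{allele_str(matrix.alleles[2 * i, j])}|{allele_str(matrix.alleles[2 * i + 1, j])}"
            for i in range(len(matrix.accessions))
        ]
        lines.append(
            "\t".join(
                [
                    matrix.chrom,
                    str(int(matrix.positions[j])),
                    ".",
                    str(matrix.ref[j]),
                    str(matrix.alt[j]),
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                + gts
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sample<TAB>S|L|C`` (header line required)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty population map")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            acc, pop = parts
            if pop not in SUBPOPULATIONS:
                raise ValueError(
                    f"{path}:{lineno}: unknown subpopulation {pop!r} (expected S, L or C)"
                )
            if acc in out:
                raise ValueError(f"{path}:{lineno}: duplicate accession {acc!r}")
            out[acc] = pop
    return out


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read the 4-column trait TSV into a DataFrame indexed by accession.

    Empty fields become NaN (missing), never 0.  Non-missing values must be
    positive and percentage traits must not exceed 100.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    expected = ["sample", *TRAIT_COLUMNS]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate accession {dup!r}")
    df = df.set_index("sample")
    for col in TRAIT_COLUMNS:
        vals = df[col].dropna()
        if (vals <= 0).any():
            raise ValueError(f"{path}: non-positive value in {col}")
        if col.endswith("_pct") and (vals > 100).any():
            raise ValueError(f"{path}: percentage > 100 in {col}")
    return df


_BED_CATEGORIES = ("gene", "qtl_seed_size", "qtl_oil", "qtl_protein")


def read_bed(path: str | Path) -> AnnotationTrack:
    """Read BED3+ annotation intervals (0-based half-open).

    Column 4 is the feature name (default ``feature<i>``), column 5 the
    category (default ``gene``).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end")
            name = parts[3] if len(parts) > 3 else f"feature{lineno}"
            category = parts[4] if len(parts) > 4 else "gene"
            if category not in _BED_CATEGORIES:
                raise ValueError(
                    f"{path}:{lineno}: unknown category {category!r} "
                    f"(expected one of {_BED_CATEGORIES})"
                )
            rows.append((parts[0], start, end, name, category))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "category"])
    return AnnotationTrack(df)


def write_stat_track(track, path: str | Path) -> Path:
    """Write a windowed statistic as a BED-like TSV.

    Columns ``chrom start0 end stat_name value`` with 6 decimal places;
    NaN values are written as ``NA``.
    """
    path = Path(path)
    lines = ["chrom\tstart0\tend\tstat_name\tvalue"]
    for start, end, value in zip(track.starts, track.ends, track.values):
        txt = "NA" if (value is None or math.isnan(value)) else f"{value:.6f}"
        lines.append(f"{track.chrom}\t{int(start)}\t{int(end)}\t{track.stat_name}\t{txt}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_stat_track(path: str | Path):
    """Read a TSV written by :func:`write_stat_track`."""
    from soysweep.diversity import WindowedStatTrack

    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if len(df) == 0:
        raise ValueError(f"{path}: empty track (header only); cannot infer chrom/stat")
    name = df["stat_name"].iloc[0]
    return WindowedStatTrack(
        chrom=str(df["chrom"].iloc[0]),
        starts=df["start0"].to_numpy(dtype=np.int64),
        ends=df["end"].to_numpy(dtype=np.int64),
        stat_name=str(name),
        values=df["value"].to_numpy(dtype=float),
    )
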