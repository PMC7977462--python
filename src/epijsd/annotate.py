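"""Genomic context classification of epiallele loci.

Two independent axes:

* gene context — promoter (TSS −1500 bp to +500 bp in the direction of
  transcription), 5'UTR, exon, intron, or intergenic, with precedence
  promoter > 5'UTR > exon > intron;
* CpG-density context — island (overlapping a CpG island), shore (within
  2 kb of an island), shelf (2–4 kb), or opensea.

Membership is decided by the locus midpoint, not span overlap, so every
locus receives exactly one label on each axis.
"""

from __future__ import annotations

import os
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

from .epiallele import EpialleleLocus
from .errors import DataFormatError

__all__ = [
    "GeneModel",
    "RegionLabel",
    "classify_gene_context",
    "classify_cpg_context",
    "read_bed_intervals",
    "read_bed12_genes",
    "merge_intervals",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "SHORE_BP",
    "SHELF_BP",
]

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
SHORE_BP = 2000
SHELF_BP = 4000  # outer edge: shores plus another 2 kb


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: strand-aware TSS, exons, optional CDS span."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # transcript span, 0-based half-open
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    cds_start: int | None = None  # thickStart/thickEnd, for UTR derivation
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError("empty transcript span")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError("exon outside transcript span")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter_contains(self, pos: int) -> bool:
        d = pos - self.tss if self.strand == "+" else self.tss - pos
        return -PROMOTER_UPSTREAM <= d < PROMOTER_DOWNSTREAM

    def five_prime_utr_contains(self, pos: int) -> bool:
        if self.cds_start is None or self.cds_end is None:
            return False
        if self.cds_start >= self.cds_end:  # non-coding: no UTR defined
            return False
        if not self.exon_contains(pos):
            return False
        return pos < self.cds_start if self.strand == "+" else pos >= self.cds_end

    def exon_contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def span_contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class RegionLabel:
    gene_context: str  # promoter | five_prime_utr | exon | intron | intergenic
    cpg_context: str  # island | shore | shelf | opensea


def classify_gene_context(
    locus: EpialleleLocus | tuple[str, int], genes: Sequence[GeneModel]
) -> str:
    """Gene-context label of a locus midpoint.

    Promoter membership is checked against every gene; overlapping genes are
    resolved by label precedence, then by distance from midpoint to TSS.
    """
    chrom, mid = _chrom_mid(locus)
    here = [g for g in genes if g.chrom == chrom]
    by_dist = sorted(here, key=lambda g: abs(mid - g.tss))
    if any(g.promoter_contains(mid) for g in by_dist):
        return "promoter"
    for predicate, label in (
        (GeneModel.five_prime_utr_contains, "five_prime_utr"),
        (GeneModel.exon_contains, "exon"),
        (GeneModel.span_contains, "intron"),
    ):
        for g in by_dist:
            if predicate(g, mid):
                return label
    return "intergenic"


def classify_cpg_context(
    locus: EpialleleLocus | tuple[str, int],
    cgi: dict[str, Sequence[tuple[int, int]]],
) -> str:
    """CpG-density label of a locus midpoint given CpG-island intervals.

    Distance to the nearest island edge: 0 within an island, <= 2 kb shore,
    <= 4 kb shelf, else opensea.  The four classes partition the genome.
    """
    chrom, mid = _chrom_mid(locus)
    intervals = merge_intervals(cgi.get(chrom, ()))
    dist = _distance_to_nearest(intervals, mid)
    if dist is None:
        return "opensea"
    if dist == 0:
        return "island"
    if dist <= SHORE_BP:
        return "shore"
    if dist <= SHELF_BP:
        return "shelf"
    return "opensea"


def _chrom_mid(locus: EpialleleLocus | tuple[str, int]) -> tuple[str, int]:
    if isinstance(locus, EpialleleLocus):
        return locus.chrom, locus.midpoint
    return locus


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _distance_to_nearest(
    intervals: Sequence[tuple[int, int]], pos: int
) -> int | None:
    if not intervals:
        return None
    starts = [s for s, _ in intervals]
    i = bisect_left(starts, pos + 1)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(intervals):
            s, e = intervals[j]
            d = 0 if s <= pos < e else min(abs(pos - s), abs(pos - (e - 1)))
            best = d if best is None else min(best, d)
    return best


def read_bed_intervals(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """Read BED3+ intervals into a per-chromosome list of (start, end)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(f"{path}:{ln}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataFormatError(f"{path}:{ln}: non-integer coordinate") from exc
            if start < 0 or end < start:
                raise DataFormatError(f"{path}:{ln}: bad interval {start}-{end}")
            out.setdefault(fields[0], []).append((start, end))
    return out


def read_bed12_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from BED12 (blocks = exons, thick = CDS)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise DataFormatError(f"{path}:{ln}: BED12 needs 12 fields")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds_start=thick_start,
                    cds_end=thick_end,
                )
            )
    return genes
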