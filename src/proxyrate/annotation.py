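"""Gene models and the region grammar used throughout the pipeline.

A gene is delimited by its transcription start site (TSS) and its
polyadenylation/cleavage site (pA). From those two anchors we derive the
three quantitation windows used for nascent-transcription density —
promoter-proximal (PP, −100/+500 bp of the TSS), gene body (GB, +500 bp of
the TSS to the pA site) and 3′ end (pA site to 3000 bp downstream) — plus
the ROCC regression region (GB through the 3′ end) and gene-length
quartiles Q1–Q4.

All genomic coordinates are 0-based, half-open (BED convention). Offsets
such as "+500 of the TSS" are *gene-oriented*: on the − strand they run
toward smaller genomic coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


class MalformedRecordError(ValueError):
    """A BED record that violates the format or the gene-model invariants."""


@dataclass(frozen=True)
class GeneModel:
    """One gene's strand-aware TSS/pA anchors.

    ``tss`` and ``pa_site`` are genomic positions (0-based). On the +
    strand ``tss < pa_site``; on the − strand ``tss > pa_site``. The
    transcribed unit occupies the half-open genomic interval
    ``[min(tss, pa), max(tss, pa))``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    pa_site: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MalformedRecordError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss == self.pa_site:
            raise MalformedRecordError(f"{self.gene_id}: tss == pa_site")
        if self.strand == "+" and not self.tss < self.pa_site:
            raise MalformedRecordError(f"{self.gene_id}: + strand requires tss < pa")
        if self.strand == "-" and not self.tss > self.pa_site:
            raise MalformedRecordError(f"{self.gene_id}: - strand requires tss > pa")

    @property
    def length(self) -> int:
        return abs(self.pa_site - self.tss)

    def oriented_interval(self, x0: int, x1: int) -> tuple[int, int]:
        """Map a gene-oriented offset interval [x0, x1) (bp from the TSS,
        positive = downstream) to a genomic half-open interval."""
        if x1 <= x0:
            raise ValueError(f"empty oriented interval [{x0}, {x1})")
        if self.strand == "+":
            return (self.tss + x0, self.tss + x1)
        return (self.tss - x1, self.tss - x0)


@dataclass(frozen=True)
class RegionSet:
    """PP / GB / 3′-end windows for one gene, as genomic intervals.

    ``rocc_region`` is the contiguous union of ``gb`` and ``three_prime``:
    the window over which per-bin coverage slopes are regressed.
    """

    gene_id: str
    chrom: str
    strand: str
    pp: tuple[int, int]
    gb: tuple[int, int]
    three_prime: tuple[int, int]
    rocc_region: tuple[int, int]


@dataclass(frozen=True)
class QuartileSet:
    """Q1..Q4 genomic intervals partitioning [TSS, pA), ordered 5'->3'."""

    gene_id: str
    chrom: str
    strand: str
    quartiles: tuple[tuple[int, int], ...]
    #: gene-oriented boundaries (0, L/4, 2L/4, 3L/4, L) with floor rounding
    boundaries: tuple[int, ...]


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Parse a BED6 annotation into gene models.

    Column semantics follow BED: ``start < end`` half-open. For + strand
    genes the TSS is ``start`` and the pA site is ``end``; for − strand
    genes the two are swapped. Gene names (column 4) must be unique.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected >= 6 tab-separated fields"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise MalformedRecordError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise MalformedRecordError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if strand not in ("+", "-"):
                raise MalformedRecordError(
                    f"{path}:{lineno}: missing or invalid strand {strand!r}"
                )
            if name in seen:
                raise MalformedRecordError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            if strand == "+":
                tss, pa = start, end
            else:
                tss, pa = end, start
            genes.append(GeneModel(name, chrom, strand, tss, pa))
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = min(g.tss, g.pa_site), max(g.tss, g.pa_site)
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def derive_regions(
    gene: GeneModel,
    pp_up: int = 100,
    pp_down: int = 500,
    three_prime_ext: int = 3000,
) -> RegionSet | None:
    """Derive PP/GB/3′ windows for one gene.

    Genes not longer than ``pp_down`` would have an empty gene body; they
    are excluded with a warning and ``None`` is returned.
    """
    if gene.length <= pp_down:
        warnings.warn(
            f"{gene.gene_id}: length {gene.length} <= pp_down {pp_down}; "
            "gene excluded from region derivation",
            stacklevel=2,
        )
        return None
    length = gene.length
    pp = gene.oriented_interval(-pp_up, pp_down)
    gb = gene.oriented_interval(pp_down, length)
    three_prime = gene.oriented_interval(length, length + three_prime_ext)
    rocc = gene.oriented_interval(pp_down, length + three_prime_ext)
    return RegionSet(gene.gene_id, gene.chrom, gene.strand, pp, gb, three_prime, rocc)


def split_quartiles(gene: GeneModel) -> QuartileSet:
    """Split [TSS, pA) into four 5′→3′ quartiles of near-equal width.

    Boundary k (k = 1..3) sits at ``floor(k * length / 4)`` bp downstream
    of the TSS, so widths differ by at most 1 bp; a 10-kb gene yields four
    2.5-kb quartiles exactly.
    """
    length = gene.length
    if length < 4:
        raise ValueError(f"{gene.gene_id}: length {length} < 4, cannot split")
    bounds = tuple(k * length // 4 for k in range(5))
    intervals = tuple(
        gene.oriented_interval(bounds[i], bounds[i + 1]) for i in range(4)
    )
    return QuartileSet(gene.gene_id, gene.chrom, gene.strand, intervals, bounds)


def regions_to_bed(
    region_sets: Sequence[RegionSet],
    quartile_sets: Sequence[QuartileSet] | None = None,
    path: str | Path = "regions.bed",
) -> None:
    """Export derived regions as BED with names <gene>_PP/_GB/_3p/_Q1.._Q4."""
    rows: list[tuple[str, int, int, str, str]] = []
    for rs in region_sets:
        for label, iv in (("PP", rs.pp), ("GB", rs.gb), ("3p", rs.three_prime)):
            rows.append((rs.chrom, iv[0], iv[1], f"{rs.gene_id}_{label}", rs.strand))
    for qs in quartile_sets or ():
        for i, iv in enumerate(qs.quartiles, start=1):
            rows.append((qs.chrom, iv[0], iv[1], f"{qs.gene_id}_Q{i}", qs.strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
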