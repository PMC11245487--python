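"""Region-level density quantitation, fold changes and metagene profiles.

Density is the mean per-bp normalized signal over a region (not a sum),
so promoter-proximal, gene-body and 3′-end densities are comparable across
genes of different lengths. Condition contrasts are log2 ratios with a
small pseudocount; box-plot summaries follow the Tukey convention
(whiskers at the most extreme data within 1.5 x IQR of the quartiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .coverage import BinnedSignal, CoverageTrack, bin_coverage


@dataclass
class RegionDensity:
    gene_id: str
    region_label: str
    density: float
    condition: str | None = None
    timepoint: float | None = None


@dataclass
class FiveNumberSummary:
    """Tukey box-plot statistics. Quartiles use linear interpolation
    (numpy's default, R type 7); whiskers are the most extreme data within
    Q1 - 1.5*IQR and Q3 + 1.5*IQR; values beyond them are outliers."""

    median: float
    q1: float
    q3: float
    lower_whisker: float
    upper_whisker: float
    outliers: np.ndarray


@dataclass
class MetageneMatrix:
    """Per-gene fixed-length profiles: upstream flank bins, scaled-body
    bins, downstream flank bins — all rows read 5′→3′ left to right."""

    matrix: pd.DataFrame
    n_flank_bins: int
    body_bins: int

    @property
    def mean_profile(self) -> np.ndarray:
        return self.matrix.to_numpy().mean(axis=0)


def region_density(
    track: CoverageTrack,
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    gene_id: str = "",
    region_label: str = "",
) -> RegionDensity:
    """Mean per-bp signal over a region — a single full-region bin."""
    if end - start < 1:
        raise ValueError(f"empty region [{start}, {end})")
    dens = track.interval_sum(chrom, start, end) / (end - start)
    return RegionDensity(
        gene_id, region_label, dens,
        condition=track.meta.condition, timepoint=track.meta.timepoint,
    )


def condition_log2fc(
    density: float, reference_density: float, pseudocount: float = 0.01
) -> float:
    """log2((density + eps) / (reference + eps)); finite for all inputs >= 0
    and antisymmetric under swapping the two densities."""
    if density < 0 or reference_density < 0:
        raise ValueError("densities must be >= 0")
    return float(np.log2((density + pseudocount) / (reference_density + pseudocount)))


def median_percent_change(log2fc_values: Sequence[float]) -> float:
    """Median of per-gene percent changes (2^log2fc - 1) * 100."""
    vals = np.asarray(log2fc_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty log2fc vector")
    return float(np.median((np.power(2.0, vals) - 1.0) * 100.0))


def five_number_summary(values: Sequence[float]) -> FiveNumberSummary:
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty vector")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    return FiveNumberSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        lower_whisker=float(inside.min()),
        upper_whisker=float(inside.max()),
        outliers=np.sort(vals[(vals < lo_fence) | (vals > hi_fence)]),
    )


def paired_signed_rank(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-gene values;
    returns (statistic, p). Delegated to scipy."""
    res = stats.wilcoxon(np.asarray(a, float), np.asarray(b, float),
                         alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def density_table(
    track: CoverageTrack,
    region_sets,
    regions: tuple[str, ...] = ("PP", "GB", "3p"),
) -> pd.DataFrame:
    """Gene x region densities for one track, long format."""
    attr = {"PP": "pp", "GB": "gb", "3p": "three_prime", "ROCC": "rocc_region"}
    rows = []
    for rs in region_sets:
        if rs is None:
            continue
        for label in regions:
            start, end = getattr(rs, attr[label])
            rd = region_density(track, rs.chrom, start, end, rs.strand,
                                gene_id=rs.gene_id, region_label=label)
            rows.append(dict(
                gene_id=rs.gene_id, region=label, density=rd.density,
                condition=rd.condition, timepoint=rd.timepoint,
            ))
    return pd.DataFrame(rows)


def metagene_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    body_bins: int = 100,
    flank: int = 1000,
    flank_bin: int = 50,
) -> MetageneMatrix:
    """Scale-regions metagene profile.

    Each gene body [TSS, pA) is rescaled to ``body_bins`` near-equal
    segments (segment k spans gene-oriented [floor(k*L/B), floor((k+1)*L/B));
    mean per-bp signal within each); flanks of ``flank`` bp up- and
    downstream are binned at ``flank_bin`` bp. Rows for − strand genes are
    computed in gene orientation, so every row reads 5′→3′. Genes shorter
    than ``body_bins`` bp are excluded with a warning.
    """
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    n_flank = -(-flank // flank_bin)
    rows: dict[str, np.ndarray] = {}
    for gene in genes:
        if gene.length < body_bins:
            warnings.warn(
                f"{gene.gene_id}: length {gene.length} < body_bins {body_bins}; "
                "excluded from metagene",
                stacklevel=2,
            )
            continue
        up_iv = gene.oriented_interval(-flank, 0)
        dn_iv = gene.oriented_interval(gene.length, gene.length + flank)
        up = bin_coverage(track, gene.chrom, up_iv[0], up_iv[1], gene.strand,
                          flank_bin).values
        dn = bin_coverage(track, gene.chrom, dn_iv[0], dn_iv[1], gene.strand,
                          flank_bin).values
        bounds = np.floor(np.arange(body_bins + 1) * gene.length / body_bins).astype(int)
        body = np.empty(body_bins)
        for k in range(body_bins):
            g0, g1 = gene.oriented_interval(int(bounds[k]), int(bounds[k + 1]))
            body[k] = track.interval_sum(gene.chrom, g0, g1) / (g1 - g0)
        rows[gene.gene_id] = np.concatenate([up, body, dn])
    if not rows:
        raise ValueError("no genes eligible for the metagene matrix")
    cols = (
        [f"up{i}" for i in range(n_flank)]
        + [f"body{i}" for i in range(body_bins)]
        + [f"dn{i}" for i in range(n_flank)]
    )
    return MetageneMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=cols),
        n_flank_bins=n_flank,
        body_bins=body_bins,
    )
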