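"""Rate of Change in Coverage (ROCC) and the gene-level Proxy Rate.

ROCC regresses each 50-bp bin's normalized nascent-transcription coverage
on time with the y-intercept fixed at zero; the zero intercept keeps bins
with no pre-induction signal interpretable rather than letting negligible
t = 0 fluctuations dominate. Because the pre-induction sample is collected
at t = 0 but the regression needs strictly positive abscissae, the 0-min
measurement is positioned at an effective time of 0.5 min.

The zero-intercept least-squares slope has the closed form

    slope_b = sum_t( t * y_{b,t} ) / sum_t( t^2 )

over effective times t. The gene-level Proxy Rate is the mean of absolute
per-bin slopes over the ROCC region (TSS+500 through pA+3000). It tracks
the Pol II elongation rate ordering but is not bp/min.

A "single time point" variant draws the slope through (t0_eff approx 0)
and one induced time point: slope_b = (y_{b,t} - y_{b,0}) / t. It lets the
0-min sample exert maximal influence and feeds the per-quartile breakdown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, derive_regions, split_quartiles
from .coverage import BinnedSignal, CoverageTrack, bin_coverage


@dataclass(frozen=True)
class TimeGrid:
    """Measurement times (min) and the effective regression abscissae.

    The only default remapping places 0 min at 0.5 min; later timepoints
    keep their nominal values.
    """

    times: tuple[float, ...] = (0.0, 5.0, 10.0)
    effective: tuple[float, ...] = (0.5, 5.0, 10.0)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.effective):
            raise ValueError("times and effective times differ in length")
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("times must be strictly increasing")
        if list(self.effective) != sorted(set(self.effective)):
            raise ValueError("effective times must be strictly increasing")
        if any(t <= 0 for t in self.effective):
            raise ValueError("all effective times must be > 0")


@dataclass
class RoccResult:
    """Per-bin slopes and the averaged absolute slope for one gene."""

    gene_id: str
    variant: str  # global | single_5 | single_10 (single_<t> generally)
    slopes: np.ndarray
    proxy_rate: float
    condition: str | None = None
    quartile_rates: dict[str, float] | None = None


@dataclass
class RateCorrelation:
    """Agreement between two per-gene rate vectors (e.g. ROCC Proxy Rates
    vs leading-edge elongation rates), by three standard measures."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float
    n: int


def rocc_global(
    bins_by_time: Sequence[BinnedSignal], grid: TimeGrid = TimeGrid()
) -> np.ndarray:
    """Zero-intercept least-squares slope per bin across all timepoints.

    Exact for signal linear in effective time: y = c*t gives slope c.
    """
    if len(bins_by_time) != len(grid.times):
        raise ValueError(
            f"need one BinnedSignal per timepoint ({len(grid.times)}), "
            f"got {len(bins_by_time)}"
        )
    n_bins = {b.n_bins for b in bins_by_time}
    if len(n_bins) != 1:
        raise ValueError(f"mismatched bin counts across timepoints: {sorted(n_bins)}")
    y = np.vstack([b.values for b in bins_by_time])  # (T, B)
    t = np.asarray(grid.effective, dtype=float)[:, None]
    return (t * y).sum(axis=0) / float((t**2).sum())


def rocc_single(
    bins_t: BinnedSignal, bins_0: BinnedSignal, t: float
) -> np.ndarray:
    """Two-point slope per bin: (y_t - y_0) / t.

    Sign is kept here; absolute values are applied at gene-level
    aggregation.
    """
    if t <= 0:
        raise ValueError("t must be > 0 for the single-timepoint slope")
    if bins_t.n_bins != bins_0.n_bins:
        raise ValueError(
            f"mismatched bin counts: {bins_t.n_bins} vs {bins_0.n_bins}"
        )
    return (bins_t.values - bins_0.values) / t


def gene_proxy_rate(slopes: np.ndarray, absolute_per_bin: bool = True) -> float:
    """Average the per-bin slopes into a single Proxy Rate.

    Default is the mean of |slope_b| (the "absolute average"); for purely
    induced genes all slopes are nonnegative and this coincides with
    |mean slope|, available via absolute_per_bin=False.
    """
    slopes = np.asarray(slopes, dtype=float)
    if slopes.size == 0:
        raise ValueError("empty slope vector")
    if absolute_per_bin:
        return float(np.mean(np.abs(slopes)))
    return float(abs(np.mean(slopes)))


def quartile_proxy_rate(
    slopes: np.ndarray,
    gene: GeneModel,
    bin_width: int = 50,
    region_start_offset: int = 500,
    absolute_per_bin: bool = True,
) -> dict[str, float]:
    """Per-quartile mean absolute slope for the single-timepoint variant.

    Slopes are indexed by gene-oriented ROCC-region bin (the region starts
    ``region_start_offset`` bp past the TSS). A bin belongs to the
    quartile containing its midpoint; quartiles partition [TSS, pA), so
    bins past the pA site belong to none. A quartile capturing no bin is
    reported as NaN with a warning.
    """
    qs = split_quartiles(gene)
    bounds = qs.boundaries  # gene-oriented (0, L/4, .., L)
    slopes = np.asarray(slopes, dtype=float)
    mids = region_start_offset + (np.arange(len(slopes)) + 0.5) * bin_width
    vals = np.abs(slopes) if absolute_per_bin else slopes
    out: dict[str, float] = {}
    for k in range(4):
        mask = (mids >= bounds[k]) & (mids < bounds[k + 1])
        if not mask.any():
            warnings.warn(
                f"{gene.gene_id}: quartile Q{k + 1} contains no bins", stacklevel=2
            )
            out[f"Q{k + 1}"] = float("nan")
        else:
            q = vals[mask].mean()
            out[f"Q{k + 1}"] = float(abs(q) if not absolute_per_bin else q)
    return out


def correlate_rates(
    reference: Sequence[float], rocc: Sequence[float]
) -> RateCorrelation:
    """Pearson r, Spearman rho and Kendall tau (tau-b tie convention)
    between a reference rate vector and ROCC Proxy Rates."""
    x = np.asarray(reference, dtype=float)
    y = np.asarray(rocc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rate vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 paired rates")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant rate vector")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    kt = stats.kendalltau(x, y)
    return RateCorrelation(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        kendall_tau=float(kt.statistic), kendall_p=float(kt.pvalue),
        n=int(x.size),
    )


def binned_rocc_signal(
    tracks_by_time: Mapping[float, CoverageTrack],
    gene: GeneModel,
    grid: TimeGrid = TimeGrid(),
    bin_width: int = 50,
    region_start_offset: int = 500,
    three_prime_ext: int = 3000,
) -> list[BinnedSignal] | None:
    """Bin each timepoint's coverage over the gene's ROCC region
    (TSS + offset through pA + extension), 5′→3′. None if the gene is too
    short for a gene body."""
    regions = derive_regions(
        gene, pp_down=region_start_offset, three_prime_ext=three_prime_ext
    )
    if regions is None:
        return None
    start, end = regions.rocc_region
    return [
        bin_coverage(
            tracks_by_time[t], gene.chrom, start, end, gene.strand,
            bin_width, gene_id=gene.gene_id, region_label="ROCC",
        )
        for t in grid.times
    ]


def compute_rocc(
    tracks_by_time: Mapping[float, CoverageTrack],
    gene: GeneModel,
    grid: TimeGrid = TimeGrid(),
    variant: str = "global",
    bin_width: int = 50,
    quartiles: bool = False,
    condition: str | None = None,
    absolute_per_bin: bool = True,
) -> RoccResult | None:
    """ROCC slopes and Proxy Rate for one gene.

    ``variant`` is "global" (all timepoints, zero intercept) or
    "single_<t>" (two-point slope against the 0-min sample, e.g.
    "single_5"). Quartile rates follow the single-timepoint convention.
    Returns None for genes too short to carry a gene body.
    """
    bins = binned_rocc_signal(tracks_by_time, gene, grid, bin_width)
    if bins is None:
        return None
    if variant == "global":
        slopes = rocc_global(bins, grid)
    elif variant.startswith("single_"):
        t = float(variant.split("_", 1)[1])
        if t not in grid.times or t <= 0:
            raise ValueError(f"single-timepoint t={t} not in grid {grid.times}")
        idx = list(grid.times).index(t)
        slopes = rocc_single(bins[idx], bins[0], t)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return RoccResult(
        gene_id=gene.gene_id,
        variant=variant,
        slopes=slopes,
        proxy_rate=gene_proxy_rate(slopes, absolute_per_bin),
        condition=condition,
        quartile_rates=(
            quartile_proxy_rate(
                slopes, gene, bin_width, absolute_per_bin=absolute_per_bin
            )
            if quartiles
            else None
        ),
    )


def proxy_rate_table(
    tracks_by_time: Mapping[float, CoverageTrack],
    genes: Sequence[GeneModel],
    grid: TimeGrid = TimeGrid(),
    variant: str = "global",
    bin_width: int = 50,
    quartiles: bool = False,
    condition: str | None = None,
    absolute_per_bin: bool = True,
) -> pd.DataFrame:
    """Per-gene Proxy Rates for one condition's time course, as a tidy
    table (gene_id, condition, variant, proxy_rate[, Q1..Q4])."""
    rows = []
    for gene in genes:
        res = compute_rocc(
            tracks_by_time, gene, grid, variant, bin_width,
            quartiles, condition, absolute_per_bin,
        )
        if res is None:
            continue
        row = dict(
            gene_id=res.gene_id,
            condition=res.condition,
            variant=res.variant,
            proxy_rate=res.proxy_rate,
        )
        if res.quartile_rates is not None:
            row.update(res.quartile_rates)
        rows.append(row)
    return pd.DataFrame(rows)
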