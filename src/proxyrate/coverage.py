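"""Coverage tracks, binned signal extraction and normalization.

The on-disk dialect is 4-column bedGraph (0-based, half-open). In memory a
track is a per-chromosome set of sorted, non-overlapping intervals with a
nonnegative value; positions outside every interval carry signal 0. Binned
values are *means per bp*, so a truncated final bin stays comparable with
full-width bins and constant coverage c bins to c everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class OverlapError(ValueError):
    """Two bedGraph intervals on one chromosome overlap."""


@dataclass
class TrackMetadata:
    condition: str | None = None
    timepoint: float | None = None
    normalization: str | None = None
    strand: str | None = None


@dataclass
class CoverageTrack:
    """Nonnegative per-base signal stored as sorted genomic intervals.

    ``data`` maps chromosome -> (starts, ends, values) arrays; intervals
    are sorted and non-overlapping within a chromosome.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    meta: TrackMetadata = field(default_factory=TrackMetadata)

    @classmethod
    def from_intervals(
        cls,
        records: Iterable[tuple[str, int, int, float]],
        meta: TrackMetadata | None = None,
        source: str = "<records>",
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if start >= end:
                raise ValueError(f"{source}: empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
            values = np.array([iv[2] for iv in ivs], dtype=np.float64)
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                i = int(bad[0])
                raise OverlapError(
                    f"{source}: overlapping intervals on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            data[chrom] = (starts, ends, values)
        return cls(data, meta or TrackMetadata())

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def scaled(self, factor: float, normalization: str | None = None) -> "CoverageTrack":
        data = {c: (s, e, v * factor) for c, (s, e, v) in self.data.items()}
        meta = replace(self.meta)
        if normalization is not None:
            meta.normalization = normalization
        return CoverageTrack(data, meta)

    def cumulative_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal sum over [-inf, p) for each position p (vectorized).

        Bin sums over [a, b) follow as ``cumulative_at(b) - cumulative_at(a)``.
        """
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self.data:
            return np.zeros(positions.shape, dtype=np.float64)
        starts, ends, values = self.data[chrom]
        if starts.size == 0:
            return np.zeros(positions.shape, dtype=np.float64)
        cum = np.concatenate(([0.0], np.cumsum((ends - starts) * values)))
        idx = np.searchsorted(starts, positions, side="right")
        total = cum[idx]
        has_prev = idx > 0
        j = np.maximum(idx - 1, 0)
        # subtract the part of the last started interval lying at/after p
        uncovered = np.clip(ends[j] - positions, 0, ends[j] - starts[j])
        total = total - np.where(has_prev, values[j] * uncovered, 0.0)
        return total

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        lo, hi = self.cumulative_at(chrom, np.array([start, end]))
        return float(hi - lo)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base signal over [start, end); zeros off-track."""
        arr = np.zeros(end - start, dtype=np.float64)
        if chrom not in self.data:
            return arr
        starts, ends, values = self.data[chrom]
        if starts.size == 0:
            return arr
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[i0:i1], ends[i0:i1], values[i0:i1]):
            arr[max(s, start) - start : min(e, end) - start] = v
        return arr


@dataclass
class BinnedSignal:
    """Gene-oriented mean per-bp signal in fixed-width bins.

    Index 0 is the most 5′ bin in gene orientation; the final bin may be
    truncated (its mean is taken over its actual width).
    """

    gene_id: str
    region_label: str
    bin_width: int
    values: np.ndarray
    widths: np.ndarray
    timepoint: float | None = None
    condition: str | None = None

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class ScaleFactors:
    """Spike-in scaling factors: the sample with the fewest spike-in reads
    gets factor 1.0 and deeper samples are scaled down proportionally."""

    sample_ids: tuple[str, ...]
    spike_counts: tuple[int, ...]
    factors: tuple[float, ...]


def read_bedgraph(path: str | Path, meta: TrackMetadata | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a validated CoverageTrack."""
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, start_s, end_s, value_s = fields[:4]
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            records.append((chrom, start, end, value))
    return CoverageTrack.from_intervals(records, meta, source=str(path))


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph. Deterministic: chromosomes sorted,
    intervals in genomic order, values in repr-shortest float format."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bigwig(path: str | Path, meta: TrackMetadata | None = None) -> CoverageTrack:
    """Optional bigWig reader behind the same contract as read_bedgraph."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("bigWig support requires pyBigWig") from exc
    records: list[tuple[str, int, int, float]] = []
    bw = pyBigWig.open(str(path))
    try:
        for chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or ():
                records.append((chrom, start, end, value))
    finally:
        bw.close()
    return CoverageTrack.from_intervals(records, meta, source=str(path))


def bin_coverage(
    track: CoverageTrack,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    bin_width: int = 50,
    gene_id: str = "",
    region_label: str = "",
) -> BinnedSignal:
    """Extract gene-oriented binned mean per-bp signal over [start, end).

    Bins are anchored at the 5′ end in gene orientation, so on the − strand
    the first bin covers the *highest* genomic coordinates and a truncated
    bin, if any, sits at the 3′ end. Regions extending past the covered
    portion of a chromosome are zero-padded (the track defines signal 0
    there); a warning is emitted if the region lies on a chromosome absent
    from the track entirely.
    """
    width = end - start
    if width < 1:
        raise ValueError(f"region width must be >= 1, got {width}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if chrom not in track.data:
        warnings.warn(f"chromosome {chrom!r} absent from track; signal is 0", stacklevel=2)
    n_bins = -(-width // bin_width)
    # gene-oriented bin offsets from the 5' end
    offs = np.minimum(np.arange(n_bins + 1, dtype=np.int64) * bin_width, width)
    if strand == "+":
        edges = start + offs
        cum = track.cumulative_at(chrom, edges)
        sums = np.diff(cum)
    else:
        edges = end - offs  # descending genomic positions
        cum = track.cumulative_at(chrom, edges)
        sums = -np.diff(cum)
    widths = np.diff(offs).astype(np.float64)
    values = sums / widths
    return BinnedSignal(
        gene_id=gene_id,
        region_label=region_label,
        bin_width=bin_width,
        values=values,
        widths=widths,
        timepoint=track.meta.timepoint,
        condition=track.meta.condition,
    )


def normalize_track(
    track: CoverageTrack,
    total_mapped_reads: int,
    mode: str = "RPKM",
    bin_width: int = 50,
) -> CoverageTrack:
    """Scale raw per-bin counts to RPKM or CPM.

    RPKM divides each count by (bin_width/1000) * (total/1e6); CPM divides
    by (total/1e6) only. With total = 1e6 and bin_width = 1000, RPKM is the
    identity on counts.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    per_million = total_mapped_reads / 1e6
    if mode == "RPKM":
        factor = 1.0 / ((bin_width / 1000.0) * per_million)
    elif mode == "CPM":
        factor = 1.0 / per_million
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return track.scaled(factor, normalization=mode)


def spike_in_factors(counts: Mapping[str, int]) -> ScaleFactors:
    """Per-sample scaling factors from exogenous spike-in read counts.

    factor_i = min_j(count_j) / count_i, so multiplying each sample's
    signal by its factor equalizes expected spike-in signal across samples.
    """
    if not counts:
        raise ValueError("no spike-in counts supplied")
    ids = tuple(counts)
    vals = tuple(int(counts[s]) for s in ids)
    if any(c <= 0 for c in vals):
        bad = [s for s, c in zip(ids, vals) if c <= 0]
        raise ValueError(f"spike-in failed (zero/negative counts) for: {bad}")
    lo = min(vals)
    return ScaleFactors(ids, vals, tuple(lo / c for c in vals))


def merge_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-base mean of >= 1 normalized replicate tracks.

    A chromosome missing from some replicate contributes 0 there (with a
    warning), so its merged signal is scaled down accordingly — the same
    convention as averaging dense genome-wide arrays.
    """
    if not tracks:
        raise ValueError("merge_replicates requires at least one track")
    tags = {t.meta.normalization for t in tracks}
    if len(tags) > 1:
        raise ValueError(f"replicates carry different normalization tags: {tags}")
    n = len(tracks)
    all_chroms = sorted({c for t in tracks for c in t.data})
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in all_chroms:
        missing = [i for i, t in enumerate(tracks) if chrom not in t.data]
        if missing and len(missing) < n:
            warnings.warn(
                f"{chrom!r} absent from replicate(s) {missing}; treated as 0",
                stacklevel=2,
            )
        breaks_list = []
        for t in tracks:
            if chrom in t.data:
                s, e, _ = t.data[chrom]
                breaks_list.extend((s, e))
        breaks = np.unique(np.concatenate(breaks_list))
        if len(breaks) < 2:
            continue
        seg_starts, seg_ends = breaks[:-1], breaks[1:]
        mean_vals = np.zeros(len(seg_starts), dtype=np.float64)
        for t in tracks:
            if chrom not in t.data:
                continue
            s, e, v = t.data[chrom]
            # each segment lies fully inside or outside each interval
            idx = np.searchsorted(s, seg_starts, side="right") - 1
            inside = (idx >= 0) & (seg_starts < e[np.maximum(idx, 0)])
            mean_vals += np.where(inside, v[np.maximum(idx, 0)], 0.0)
        mean_vals /= n
        # compress runs of equal value, drop zero segments
        keep = np.nonzero(mean_vals != 0.0)[0]
        if keep.size == 0:
            continue
        starts_out: list[int] = []
        ends_out: list[int] = []
        vals_out: list[float] = []
        for i in keep:
            s0, e0, v0 = int(seg_starts[i]), int(seg_ends[i]), float(mean_vals[i])
            if starts_out and ends_out[-1] == s0 and vals_out[-1] == v0:
                ends_out[-1] = e0
            else:
                starts_out.append(s0)
                ends_out.append(e0)
                vals_out.append(v0)
        data[chrom] = (
            np.array(starts_out, dtype=np.int64),
            np.array(ends_out, dtype=np.int64),
            np.array(vals_out, dtype=np.float64),
        )
    meta = TrackMetadata(normalization=tags.pop() if tags else None)
    return CoverageTrack(data, meta)
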