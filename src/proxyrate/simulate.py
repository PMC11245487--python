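"""Synthetic serum-induction coverage and differential-expression tables.

The generator emulates the structure the downstream estimators assume:
genes transcriptionally inert before stimulation, then a Pol II wave that
enters the gene body and advances at an elongation rate v bp/min, leaving a
plateau of nascent-transcription density behind its front, optionally with
a pileup past the pA site. Two conditions differing only in v provide the
contrast the rate estimator must resolve.

The wave is deliberately a step function (sharp front, flat plateau)
rather than a kinematic polymerase simulation: it is the simplest signal
for which the per-bin coverage slope is identifiable, and a ``pileup_gain``
knob reproduces the 3′ accumulation seen in real nascent data. Noise, when
requested, is Poisson on per-bin counts rescaled back to density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .clustering import CLUSTER_BANDS, NONDE_FOLD
from .coverage import CoverageTrack, TrackMetadata


@dataclass
class WavefrontParams:
    """Parameters of one condition's induction time course.

    ``elongation_rate`` may be a single v (bp/min) for all genes or a
    mapping gene_id -> v. ``noise_scale`` is the expected Poisson count per
    bin where the density equals ``plateau_density``.
    """

    elongation_rate: float | Mapping[str, float] = 1000.0
    plateau_density: float = 10.0
    basal_density: float = 0.0
    timepoints: tuple[float, ...] = (0.0, 5.0, 10.0)
    pileup_gain: float = 1.0
    noise: str = "none"
    noise_scale: float = 100.0
    seed: int = 0
    bin_width: int = 50
    three_prime_ext: int = 3000

    def __post_init__(self) -> None:
        if isinstance(self.elongation_rate, (int, float)):
            if self.elongation_rate <= 0:
                raise ValueError("elongation_rate must be > 0")
        else:
            if any(v <= 0 for v in self.elongation_rate.values()):
                raise ValueError("all per-gene elongation rates must be > 0")
        if self.plateau_density < 0 or self.basal_density < 0:
            raise ValueError("densities must be >= 0")
        if self.pileup_gain < 1:
            raise ValueError("pileup_gain must be >= 1")
        tps = tuple(self.timepoints)
        if list(tps) != sorted(tps) or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be sorted ascending and unique")
        if 0.0 not in tps:
            raise ValueError("timepoints must include 0")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise mode {self.noise!r}")
        if self.noise == "poisson" and self.plateau_density <= 0:
            raise ValueError("poisson noise requires plateau_density > 0")

    def rate_for(self, gene_id: str) -> float:
        if isinstance(self.elongation_rate, (int, float)):
            return float(self.elongation_rate)
        return float(self.elongation_rate[gene_id])


@dataclass
class SimulationResult:
    """Per-(condition, timepoint) tracks plus ground truth.

    ``truth_genes`` has one row per gene x condition (true v, plateau,
    seed); ``truth_bins`` one row per gene x condition x timepoint x bin
    with the noiseless expected density.
    """

    tracks: dict[tuple[str, float], CoverageTrack]
    truth_genes: pd.DataFrame
    truth_bins: pd.DataFrame = field(repr=False, default=None)


def _expected_bin_density(
    length: int, front: float, beta: float, basal: float, gain: float,
    bin_width: int, tail: int,
) -> np.ndarray:
    """Noiseless expected mean density per gene-oriented bin over
    [0, length + tail).

    At gene-oriented position x the density is basal beyond the front
    (x > front) and beta behind it, scaled by ``gain`` past the pA site;
    bins straddling the front or the pA site take the exact average.
    """
    total = length + tail
    edges = np.minimum(
        np.arange(0, total + bin_width, bin_width, dtype=np.float64), total
    )
    edges = np.unique(edges)
    lo, hi = edges[:-1], edges[1:]
    wid = hi - lo

    def plateau_overlap(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # bp of [lo,hi) inside [a,b) and behind the front
        return np.clip(np.minimum(hi, np.minimum(b, front)) - np.maximum(lo, a), 0, None)

    body = plateau_overlap(np.float64(0.0), np.float64(length))
    past = plateau_overlap(np.float64(length), np.float64(total))
    covered = body + past
    dens = basal + (beta - basal) * body / wid + (beta * gain - basal) * past / wid
    # note: positions behind front get beta (or beta*gain); ahead get basal
    return np.where(covered > 0, dens, basal)


def simulate_wavefront_timecourse(
    genes: Sequence[GeneModel],
    params_by_condition: Mapping[str, WavefrontParams],
    collect_bin_truth: bool = True,
) -> SimulationResult:
    """Generate per-timepoint coverage tracks for each condition.

    The emitted signal spans each gene's oriented [0, length + 3′ ext)
    window. Identical seeds and parameters give byte-identical bedGraph
    output. Genes overlapping on the same strand are rejected.
    """
    _check_no_overlap(genes)
    tracks: dict[tuple[str, float], CoverageTrack] = {}
    gene_rows = []
    bin_rows = []
    for condition in params_by_condition:
        p = params_by_condition[condition]
        rng = np.random.default_rng(p.seed)
        per_tp_records: dict[float, list[tuple[str, int, int, float]]] = {
            t: [] for t in p.timepoints
        }
        for gene in genes:
            v = p.rate_for(gene.gene_id)
            gene_rows.append(
                dict(
                    gene_id=gene.gene_id,
                    condition=condition,
                    elongation_rate=v,
                    plateau_density=p.plateau_density,
                    basal_density=p.basal_density,
                    seed=p.seed,
                )
            )
            for t in p.timepoints:
                front = v * t if t > 0 else 0.0
                expected = _expected_bin_density(
                    gene.length, front, p.plateau_density, p.basal_density,
                    p.pileup_gain, p.bin_width, p.three_prime_ext,
                )
                if p.noise == "poisson":
                    lam = expected * (p.noise_scale / p.plateau_density)
                    observed = rng.poisson(lam) * (p.plateau_density / p.noise_scale)
                else:
                    observed = expected
                n_bins = len(expected)
                if collect_bin_truth:
                    bin_rows.extend(
                        (gene.gene_id, condition, t, b, expected[b])
                        for b in range(n_bins)
                    )
                total = gene.length + p.three_prime_ext
                offs = np.minimum(
                    np.arange(n_bins + 1, dtype=np.int64) * p.bin_width, total
                )
                nz = np.nonzero(observed != 0.0)[0]
                chrom = gene.chrom
                if gene.strand == "+":
                    g0s, g1s = gene.tss + offs[nz], gene.tss + offs[nz + 1]
                else:
                    g0s, g1s = gene.tss - offs[nz + 1], gene.tss - offs[nz]
                per_tp_records[t].extend(
                    zip([chrom] * len(nz), g0s.tolist(), g1s.tolist(),
                        observed[nz].tolist())
                )
        empty = (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.float64),
        )
        for t, records in per_tp_records.items():
            track = CoverageTrack.from_intervals(
                records,
                TrackMetadata(condition=condition, timepoint=t, normalization="sim"),
            )
            # register every simulated chromosome even when basal-only
            # signal left it without intervals (coverage 0 everywhere)
            for g in genes:
                track.data.setdefault(g.chrom, empty)
            tracks[(condition, t)] = track
    truth_genes = pd.DataFrame(gene_rows)
    truth_bins = pd.DataFrame(
        bin_rows, columns=["gene_id", "condition", "timepoint", "bin", "expected"]
    )
    return SimulationResult(tracks, truth_genes, truth_bins)


def _check_no_overlap(genes: Sequence[GeneModel]) -> None:
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    for (chrom, strand), gs in by_key.items():
        spans = sorted(
            (min(g.tss, g.pa_site), max(g.tss, g.pa_site), g.gene_id) for g in gs
        )
        for (s0, e0, id0), (s1, e1, id1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(
                    f"genes {id0} and {id1} overlap on {chrom}{strand}"
                )


def make_toy_annotation(
    n_genes: int,
    length_range: tuple[int, int] = (8000, 15000),
    minus_fraction: float = 0.5,
    chrom: str = "chrS",
    gap: int = 10000,
    seed: int = 0,
) -> list[GeneModel]:
    """Non-overlapping toy gene models on one synthetic chromosome.

    Genes are laid out left to right with ``gap`` bp between transcribed
    units (gap must exceed flank/extension windows used downstream).
    Deterministic under ``seed``; lengths below 1 kb are rejected.
    """
    if length_range[0] < 1000:
        raise ValueError("gene lengths must be >= 1000 bp")
    if length_range[1] < length_range[0]:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    pos = gap
    for i in range(n_genes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        strand = "-" if rng.random() < minus_fraction else "+"
        start, end = pos, pos + length
        if strand == "+":
            genes.append(GeneModel(f"gene{i:03d}", chrom, "+", start, end))
        else:
            genes.append(GeneModel(f"gene{i:03d}", chrom, "-", end, start))
        pos = end + gap
    return genes


def simulate_de_table(
    n_genes: int,
    cluster_spec: Mapping[str, tuple[int, tuple[float, float]]],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Differential-expression table with a known cluster composition.

    ``cluster_spec`` maps a target label (16fold/8fold/4fold/2fold/nonDE/
    other) to (gene count, inclusive log2FC sampling range). The range must
    be consistent with the label's fold-change band, so that re-clustering
    the emitted table recovers the requested labels exactly; genes beyond
    the specified clusters are emitted as not expressed.

    Returns (table with gene_id/log2fc/expressed, true label Series).
    """
    total_requested = sum(count for count, _ in cluster_spec.values())
    if total_requested > n_genes:
        raise ValueError("cluster counts exceed n_genes")
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    idx = 0
    for label, (count, (lo, hi)) in cluster_spec.items():
        if hi < lo:
            raise ValueError(f"{label}: empty log2FC range")
        band_lo, band_hi = _label_band(label)
        if not (band_lo <= lo and hi < band_hi):
            raise ValueError(
                f"{label}: requested range [{lo}, {hi}] is not inside the "
                f"label's log2FC band [{band_lo}, {band_hi})"
            )
        for _ in range(count):
            lfc = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            rows.append(dict(gene_id=f"g{idx:05d}", log2fc=lfc, expressed=True))
            labels.append(label)
            idx += 1
    for _ in range(n_genes - total_requested):
        rows.append(dict(gene_id=f"g{idx:05d}", log2fc=np.nan, expressed=False))
        labels.append("not_expressed")
        idx += 1
    table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "expressed"])
    return table, pd.Series(labels, index=table["gene_id"], name="true_label")


def _label_band(label: str) -> tuple[float, float]:
    """Half-open [lo, hi) log2FC band within which a gene gets this top label."""
    if label in CLUSTER_BANDS:
        return CLUSTER_BANDS[label]
    if label == "nonDE":
        return (-np.log2(NONDE_FOLD), np.log2(NONDE_FOLD))
    if label == "other":
        # expressed, not in the non-DE band, below the 2-fold cutoff
        return (np.log2(NONDE_FOLD), 1.0)
    raise ValueError(f"unknown cluster label {label!r}")
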