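"""Shared study conditions for the numbered analysis scripts.

Two conditions over a serum-style induction time course (0, 5, 10 min):
"control" with Pol II elongation at 1000 bp/min and "depleted" (acute loss
of a negative elongation regulator) at 2000 bp/min, over 30 synthetic
immediate-early genes with Poisson count noise. Tracks are cached as
bedGraph under scratch/simdata/ so the downstream scripts read the same
files a real analysis would.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from proxyrate import (
    TimeGrid,
    WavefrontParams,
    make_toy_annotation,
    read_bedgraph,
    read_gene_bed,
    simulate_wavefront_timecourse,
    write_bedgraph,
    write_gene_bed,
)
from proxyrate.coverage import TrackMetadata

ROOT = Path(__file__).resolve().parents[1]
SIMDIR = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"

GRID = TimeGrid()
N_GENES = 30
SEED = 20240918

CONDITIONS = {
    "control": WavefrontParams(
        elongation_rate=1000.0, plateau_density=10.0,
        noise="poisson", noise_scale=100.0, seed=SEED,
    ),
    "depleted": WavefrontParams(
        elongation_rate=2000.0, plateau_density=10.0,
        noise="poisson", noise_scale=100.0, seed=SEED + 1,
    ),
}


def track_path(condition: str, timepoint: float) -> Path:
    return SIMDIR / f"{condition}_t{timepoint:g}.bedGraph"


def generate(force: bool = False) -> None:
    """Simulate the study time course and cache it on disk."""
    SIMDIR.mkdir(parents=True, exist_ok=True)
    bed = SIMDIR / "genes.bed"
    if bed.exists() and not force:
        return
    genes = make_toy_annotation(N_GENES, (10000, 16000), gap=12000, seed=SEED)
    write_gene_bed(genes, bed)
    sim = simulate_wavefront_timecourse(genes, CONDITIONS, collect_bin_truth=False)
    for (condition, t), track in sim.tracks.items():
        write_bedgraph(track, track_path(condition, t))
    sim.truth_genes.to_csv(SIMDIR / "truth_genes.tsv", sep="\t", index=False)


def load_genes():
    generate()
    return read_gene_bed(SIMDIR / "genes.bed")


def load_tracks(condition: str):
    generate()
    import numpy as np

    chroms = {g.chrom for g in load_genes()}
    empty = (
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.float64),
    )
    tracks = {}
    for t in GRID.times:
        track = read_bedgraph(
            track_path(condition, t),
            TrackMetadata(condition=condition, timepoint=t, normalization="sim"),
        )
        # a pre-induction track may be empty; its chromosomes still exist
        for c in chroms:
            track.data.setdefault(c, empty)
        tracks[t] = track
    return tracks


def load_truth() -> pd.DataFrame:
    generate()
    return pd.read_csv(SIMDIR / "truth_genes.tsv", sep="\t")
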