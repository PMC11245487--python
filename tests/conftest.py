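import numpy as np
import pytest

from proxyrate import CoverageTrack, GeneModel


def perbase_signal(records, chrom, start, end):
    """Independent dense per-base oracle built straight from raw interval
    records, bypassing the track machinery."""
    arr = np.zeros(end - start, dtype=float)
    for c, s, e, v in records:
        if c != chrom:
            continue
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            arr[lo - start : hi - start] = v
    return arr


def perbase_bin_means(records, chrom, start, end, strand, bin_width):
    """Brute-force gene-oriented binned means from the dense per-base array."""
    arr = perbase_signal(records, chrom, start, end)
    if strand == "-":
        arr = arr[::-1]
    means = []
    for i in range(0, len(arr), bin_width):
        chunk = arr[i : i + bin_width]
        means.append(chunk.mean())
    return np.array(means)


def random_track_records(rng, chrom="chr1", n_iv=30, span=5000):
    """Sorted non-overlapping random intervals with gaps and random values."""
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_iv, replace=False))
    records = []
    for i in range(0, len(cuts) - 1, 2):
        if rng.random() < 0.8:  # leave some gaps at zero
            records.append((chrom, int(cuts[i]), int(cuts[i + 1]), float(rng.gamma(2.0, 2.0))))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def plus_gene():
    return GeneModel("FOS", "chr1", "+", 10000, 20000)


@pytest.fixture
def minus_gene():
    return GeneModel("NR4A1", "chr1", "-", 20000, 10000)


@pytest.fixture
def constant_track():
    def make(value, chrom="chr1", start=0, end=50000, **meta):
        from proxyrate import TrackMetadata

        return CoverageTrack.from_intervals(
            [(chrom, start, end, value)], TrackMetadata(**meta)
        )

    return make
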