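import numpy as np
import pytest

from proxyrate import (
    CoverageTrack,
    TrackMetadata,
    bin_coverage,
    merge_replicates,
    normalize_track,
    read_bedgraph,
    spike_in_factors,
    write_bedgraph,
)
from proxyrate.coverage import OverlapError

from conftest import perbase_bin_means, random_track_records


class TestBedgraphIO:
    def test_parse(self, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("chr1\t0\t100\t2.5\n")
        track = read_bedgraph(p)
        s, e, v = track.data["chr1"]
        assert (s[0], e[0], v[0]) == (0, 100, 2.5)

    def test_round_trip_identity(self, tmp_path, rng):
        records = random_track_records(rng)
        track = CoverageTrack.from_intervals(records)
        p1, p2 = tmp_path / "a.bg", tmp_path / "b.bg"
        write_bedgraph(track, p1)
        write_bedgraph(read_bedgraph(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_overlap_error_names_pair(self, tmp_path):
        p = tmp_path / "bad.bg"
        p.write_text("chr1\t0\t100\t1\nchr1\t50\t150\t1\n")
        with pytest.raises(OverlapError, match=r"\[0,100\).*\[50,150\)"):
            read_bedgraph(p)

    def test_non_numeric_value(self, tmp_path):
        p = tmp_path / "bad.bg"
        p.write_text("chr1\t0\t100\thigh\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_bedgraph(p)


class TestBinCoverage:
    def test_constant_signal(self, constant_track):
        bs = bin_coverage(constant_track(4.0), "chr1", 1000, 1150, "+", 50)
        assert np.allclose(bs.values, [4.0, 4.0, 4.0])

    def test_partial_bin_mean(self):
        track = CoverageTrack.from_intervals([("chr1", 0, 25, 2.0)])
        bs = bin_coverage(track, "chr1", 0, 50, "+", 50)
        assert bs.values == pytest.approx([1.0])

    def test_truncated_final_bin(self, constant_track):
        # 120-bp region: bins of width 50, 50, 20; last averaged over 20 bp
        track = CoverageTrack.from_intervals([("chr1", 100, 110, 2.0)])
        bs = bin_coverage(track, "chr1", 0, 120, "+", 50)
        assert list(bs.widths) == [50, 50, 20]
        assert bs.values == pytest.approx([0.0, 0.0, 1.0])

    def test_minus_strand_reads_3prime_to_5prime(self):
        track = CoverageTrack.from_intervals([("chr1", 0, 50, 1.0), ("chr1", 50, 100, 3.0)])
        plus = bin_coverage(track, "chr1", 0, 100, "+", 50)
        minus = bin_coverage(track, "chr1", 0, 100, "-", 50)
        assert list(plus.values) == [1.0, 3.0]
        assert list(minus.values) == [3.0, 1.0]

    def test_minus_strand_truncation_at_gene_3prime_end(self):
        # on the - strand the truncated bin must sit at the genomic *start*
        track = CoverageTrack.from_intervals([("chr1", 0, 120, 1.0)])
        bs = bin_coverage(track, "chr1", 0, 120, "-", 50)
        assert list(bs.widths) == [50, 50, 20]
        assert np.allclose(bs.values, 1.0)

    def test_absent_chromosome_zero_with_warning(self, constant_track):
        with pytest.warns(UserWarning, match="absent"):
            bs = bin_coverage(constant_track(1.0), "chrX", 0, 100, "+", 50)
        assert np.allclose(bs.values, 0.0)

    def test_empty_region_rejected(self, constant_track):
        with pytest.raises(ValueError):
            bin_coverage(constant_track(1.0), "chr1", 100, 100, "+")

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_perbase_oracle(self, strand, rng):
        for _ in range(40):
            records = random_track_records(rng)
            track = CoverageTrack.from_intervals(records)
            start = int(rng.integers(0, 2000))
            end = start + int(rng.integers(1, 3000))
            bw = int(rng.choice([1, 7, 50, 113]))
            got = bin_coverage(track, "chr1", start, end, strand, bw).values
            expected = perbase_bin_means(records, "chr1", start, end, strand, bw)
            assert np.allclose(got, expected, rtol=1e-9, atol=1e-9)

    def test_linearity_and_sum_conservation(self, rng):
        records = random_track_records(rng)
        track = CoverageTrack.from_intervals(records)
        scaled = track.scaled(3.7)
        a = bin_coverage(track, "chr1", 100, 1330, "+", 50)
        b = bin_coverage(scaled, "chr1", 100, 1330, "+", 50)
        assert np.allclose(b.values, 3.7 * a.values)
        total = float((a.values * a.widths).sum())
        assert total == pytest.approx(track.interval_sum("chr1", 100, 1330), abs=1e-9)


class TestNormalization:
    def test_rpkm_closed_form(self, constant_track):
        # count 10 in a 50-bp bin, 1e6 total reads -> 10/((50/1000)*(1)) = 200
        track = CoverageTrack.from_intervals([("chr1", 0, 50, 10.0)])
        out = normalize_track(track, 10**6, "RPKM", bin_width=50)
        assert out.data["chr1"][2][0] == pytest.approx(200.0)

    def test_cpm_closed_form(self):
        track = CoverageTrack.from_intervals([("chr1", 0, 50, 10.0)])
        out = normalize_track(track, 10**6, "CPM")
        assert out.data["chr1"][2][0] == pytest.approx(10.0)

    def test_rpkm_identity_case(self, rng):
        # total 1e6 reads and 1000-bp bins leave counts unchanged
        records = random_track_records(rng)
        track = CoverageTrack.from_intervals(records)
        out = normalize_track(track, 10**6, "RPKM", bin_width=1000)
        assert np.allclose(out.data["chr1"][2], track.data["chr1"][2])

    def test_zero_total_rejected(self, constant_track):
        with pytest.raises(ValueError):
            normalize_track(constant_track(1.0), 0, "RPKM")


class TestSpikeInFactors:
    def test_stated_rule(self):
        sf = spike_in_factors({"a": 1000, "b": 2000})
        assert sf.factors == (1.0, 0.5)
        # applying factors equalizes expected spike-in signal
        scaled = [c * f for c, f in zip(sf.spike_counts, sf.factors)]
        assert scaled[0] == scaled[1]

    def test_equal_counts_identity(self):
        assert spike_in_factors({"a": 500, "b": 500, "c": 500}).factors == (1, 1, 1)

    def test_zero_count_is_failure(self):
        with pytest.raises(ValueError, match="spike-in failed"):
            spike_in_factors({"a": 0, "b": 100})


class TestMergeReplicates:
    def test_identity_on_identical_tracks(self, rng):
        records = random_track_records(rng)
        t1 = CoverageTrack.from_intervals(records)
        t2 = CoverageTrack.from_intervals(records)
        merged = merge_replicates([t1, t2])
        arr = merged.per_base("chr1", 0, 5000)
        assert np.allclose(arr, t1.per_base("chr1", 0, 5000))

    def test_per_base_mean(self):
        t1 = CoverageTrack.from_intervals([("chr1", 0, 100, 2.0)])
        t2 = CoverageTrack.from_intervals([("chr1", 0, 100, 4.0)])
        merged = merge_replicates([t1, t2])
        assert np.allclose(merged.per_base("chr1", 0, 100), 3.0)

    def test_offset_intervals_mean(self):
        t1 = CoverageTrack.from_intervals([("chr1", 0, 100, 2.0)])
        t2 = CoverageTrack.from_intervals([("chr1", 50, 150, 4.0)])
        arr = merge_replicates([t1, t2]).per_base("chr1", 0, 150)
        assert np.allclose(arr[:50], 1.0)
        assert np.allclose(arr[50:100], 3.0)
        assert np.allclose(arr[100:150], 2.0)

    def test_missing_chromosome_halves_signal(self):
        t1 = CoverageTrack.from_intervals(
            [("chr1", 0, 100, 2.0), ("chr2", 0, 100, 6.0)]
        )
        t2 = CoverageTrack.from_intervals([("chr1", 0, 100, 2.0)])
        with pytest.warns(UserWarning, match="chr2"):
            merged = merge_replicates([t1, t2])
        assert np.allclose(merged.per_base("chr2", 0, 100), 3.0)

    def test_normalization_tag_mismatch(self):
        t1 = CoverageTrack.from_intervals(
            [("chr1", 0, 10, 1.0)], TrackMetadata(normalization="RPKM")
        )
        t2 = CoverageTrack.from_intervals(
            [("chr1", 0, 10, 1.0)], TrackMetadata(normalization="CPM")
        )
        with pytest.raises(ValueError, match="normalization"):
            merge_replicates([t1, t2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates([])
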