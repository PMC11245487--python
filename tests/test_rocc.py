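import numpy as np
import pytest

from proxyrate import (
    BinnedSignal,
    GeneModel,
    TimeGrid,
    WavefrontParams,
    correlate_rates,
    gene_proxy_rate,
    proxy_rate_table,
    quartile_proxy_rate,
    rocc_global,
    rocc_single,
    simulate_wavefront_timecourse,
)


def bins(values, t=None, bw=50):
    values = np.asarray(values, dtype=float)
    return BinnedSignal("g", "ROCC", bw, values, np.full(len(values), float(bw)), t)


def lstsq_through_origin(t, y):
    """Independent numeric oracle: least squares y ~ slope * t, no intercept."""
    t = np.asarray(t, float)[:, None]
    sol, *_ = np.linalg.lstsq(t, np.asarray(y, float), rcond=None)
    return float(sol[0])


class TestTimeGrid:
    def test_default_places_t0_at_half_minute(self):
        grid = TimeGrid()
        assert grid.times == (0.0, 5.0, 10.0)
        assert grid.effective == (0.5, 5.0, 10.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(times=(0.0, 5.0), effective=(0.5, 5.0, 10.0)),
            dict(times=(0.0, 10.0, 5.0), effective=(0.5, 10.0, 5.0)),
            dict(times=(0.0, 5.0), effective=(0.0, 5.0)),  # effective must be > 0
        ],
    )
    def test_invalid_grids(self, kwargs):
        with pytest.raises(ValueError):
            TimeGrid(**kwargs)


class TestRoccGlobal:
    def test_exact_on_linear_signal(self):
        series = [bins([1.0]), bins([10.0]), bins([20.0])]  # y = 2 * t_eff
        assert rocc_global(series)[0] == pytest.approx(2.0, abs=1e-15)

    def test_zero_signal(self):
        assert rocc_global([bins([0.0])] * 3)[0] == 0.0

    def test_closed_form_value(self):
        slope = rocc_global([bins([0.0]), bins([5.0]), bins([10.0])])[0]
        assert slope == pytest.approx(125 / 125.25, abs=1e-12)
        assert slope == pytest.approx(
            lstsq_through_origin([0.5, 5, 10], [0, 5, 10]), abs=1e-12
        )

    def test_matches_numeric_least_squares_oracle(self, rng):
        grid = TimeGrid()
        for _ in range(300):
            y = rng.gamma(1.0, 5.0, size=3)
            got = rocc_global([bins([v]) for v in y], grid)[0]
            want = lstsq_through_origin(grid.effective, y)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_vectorized_over_bins(self, rng):
        y = rng.gamma(1.0, 5.0, size=(3, 40))
        slopes = rocc_global([bins(row) for row in y])
        for b in range(40):
            assert slopes[b] == pytest.approx(
                lstsq_through_origin(TimeGrid().effective, y[:, b]), rel=1e-10
            )

    def test_mismatched_bin_counts(self):
        with pytest.raises(ValueError, match="mismatched"):
            rocc_global([bins([1, 2]), bins([1]), bins([1, 2])])

    def test_wrong_number_of_timepoints(self):
        with pytest.raises(ValueError):
            rocc_global([bins([1]), bins([2])])


class TestRoccSingle:
    @pytest.mark.parametrize(
        "y0,yt,t,expected",
        [(2.0, 7.0, 5.0, 1.0), (0.0, 5.0, 10.0, 0.5), (5.0, 0.0, 5.0, -1.0)],
    )
    def test_two_point_slope(self, y0, yt, t, expected):
        assert rocc_single(bins([yt]), bins([y0]), t)[0] == pytest.approx(expected)

    def test_t_zero_rejected(self):
        with pytest.raises(ValueError):
            rocc_single(bins([1.0]), bins([0.0]), 0.0)

    def test_limit_agreement_with_global(self):
        """With timepoints {0, t}, y0 = 0 and effective t0 -> 0, the
        zero-intercept fit collapses onto the two-point slope."""
        y0, yt, t = 0.0, 7.0, 5.0
        single = rocc_single(bins([yt]), bins([y0]), t)[0]
        for eps in (0.5, 0.05, 1e-6):
            grid = TimeGrid(times=(0.0, t), effective=(eps, t))
            glob = rocc_global([bins([y0]), bins([yt])], grid)[0]
            # t*yt/(eps^2+t^2) -> yt/t as eps -> 0
            assert abs(glob - single) <= yt * eps**2 / t**3 + 1e-12
        grid = TimeGrid(times=(0.0, t), effective=(1e-12, t))
        assert rocc_global([bins([y0]), bins([yt])], grid)[0] == pytest.approx(single)


class TestGeneProxyRate:
    def test_mean_of_absolute_slopes(self):
        assert gene_proxy_rate(np.array([1.0, -1.0])) == 1.0
        assert gene_proxy_rate(np.array([1.0, -1.0]), absolute_per_bin=False) == 0.0

    def test_zero_slopes(self):
        assert gene_proxy_rate(np.zeros(10)) == 0.0

    def test_scale_equivariance(self, rng):
        slopes = rng.normal(size=50)
        assert gene_proxy_rate(3.0 * slopes) == pytest.approx(3.0 * gene_proxy_rate(slopes))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_proxy_rate(np.array([]))


class TestQuartileProxyRate:
    def gene(self, length=10000):
        return GeneModel("g", "chr1", "+", 0, length)

    def test_uniform_slopes_give_equal_quartiles(self):
        # 10-kb gene, region offset 500, ext 3000 -> 260 bins of 50 bp
        q = quartile_proxy_rate(np.ones(260), self.gene())
        assert all(v == pytest.approx(1.0) for v in q.values())

    def test_localized_signal(self):
        # Q1 covers gene-oriented [0, 2500): region bins 0..39 (mid < 2500)
        slopes = np.full(260, 0.5)
        slopes[:40] = 2.0
        q = quartile_proxy_rate(slopes, self.gene())
        assert q["Q1"] == pytest.approx(2.0)
        assert q["Q4"] == pytest.approx(0.5)

    def test_bins_past_pa_site_belong_to_no_quartile(self):
        slopes = np.zeros(260)
        slopes[190:] = 9.0  # mids >= 10000: 3' extension only
        q = quartile_proxy_rate(slopes, self.gene())
        assert all(v == 0.0 for v in q.values())

    def test_empty_quartile_is_nan_with_warning(self):
        # a 2-kb gene: Q1 spans [0,500) which the ROCC region never reaches
        g = self.gene(2000)
        with pytest.warns(UserWarning, match="Q1"):
            q = quartile_proxy_rate(np.ones(100), g)
        assert np.isnan(q["Q1"])


class TestCorrelateRates:
    def test_perfect_monotone(self):
        r = correlate_rates([1, 2, 3], [2, 4, 6])
        assert (r.pearson_r, r.spearman_rho, r.kendall_tau) == pytest.approx((1.0, 1.0, 1.0))

    def test_reversal(self):
        r = correlate_rates([1, 2, 3], [3, 2, 1])
        assert (r.pearson_r, r.spearman_rho, r.kendall_tau) == pytest.approx((-1.0, -1.0, -1.0))

    def test_kendall_tau_one_third(self):
        assert correlate_rates([1, 2, 3], [1, 3, 2]).kendall_tau == pytest.approx(1 / 3)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate_rates([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            correlate_rates([1, 2], [2, 1])


class TestParameterRecovery:
    def test_noiseless_proxy_rate_increases_with_true_rate(self):
        genes = [GeneModel("g", "chrS", "+", 10000, 25000)]
        rates = []
        for v in (500, 1000, 2000, 4000):
            p = WavefrontParams(elongation_rate=v, plateau_density=10.0)
            sim = simulate_wavefront_timecourse(genes, {"c": p})
            tracks = {t: sim.tracks[("c", t)] for t in (0.0, 5.0, 10.0)}
            tab = proxy_rate_table(tracks, genes)
            rates.append(tab["proxy_rate"].iloc[0])
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_single_timepoint_variant_orders_conditions(self):
        genes = [GeneModel("g", "chrS", "+", 10000, 25000)]
        tabs = {}
        for name, v in (("slow", 1000), ("fast", 2000)):
            p = WavefrontParams(elongation_rate=v)
            sim = simulate_wavefront_timecourse(genes, {name: p})
            tracks = {t: sim.tracks[(name, t)] for t in (0.0, 5.0, 10.0)}
            tabs[name] = proxy_rate_table(tracks, genes, variant="single_5")
        assert tabs["fast"]["proxy_rate"].iloc[0] > tabs["slow"]["proxy_rate"].iloc[0]

    def test_quartile_rates_reflect_front_progress(self):
        """At 5 min a 1000-bp/min wave has reached 5 kb: promoter-proximal
        quartiles of a 15-kb gene show signal gain, distal ones none."""
        genes = [GeneModel("g", "chrS", "+", 10000, 25000)]
        p = WavefrontParams(elongation_rate=1000)
        sim = simulate_wavefront_timecourse(genes, {"c": p})
        tracks = {t: sim.tracks[("c", t)] for t in (0.0, 5.0, 10.0)}
        tab = proxy_rate_table(tracks, genes, variant="single_5", quartiles=True)
        row = tab.iloc[0]
        assert row["Q1"] > 0 and row["Q2"] > 0
        assert row["Q4"] == 0.0
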