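import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ftcd.errors import ConfigError, InsufficientDataError, NoDataError
from ftcd.events import TimingSpec
from ftcd.laterality import (
    Epoch,
    analyze,
    average_epochs,
    baseline_correct,
    compute_li,
    infer,
    per_epoch_li,
    summary_stat,
)

RATE = 25.0
EPOCH_LEN = 1250          # -20..30 s at 25 Hz
OFFSET = -500             # epoch starts 20 s before the marker
BASELINE = (125, 375)     # -15..-5 s
POI = (575, 825)          # 3..13 s


def make_epoch(left, right, status="accepted"):
    return Epoch(
        left=np.asarray(left, float),
        right=np.asarray(right, float),
        offset=OFFSET,
        baseline=BASELINE,
        poi=POI,
        sample_rate=RATE,
        status=status,
    )


def corrected(x):
    return baseline_correct(np.asarray(x, float), BASELINE)


class TestBaselineCorrect:
    def test_constant_maps_to_zero(self):
        np.testing.assert_allclose(corrected(np.full(EPOCH_LEN, 100.0)), 0.0)

    def test_arithmetic(self):
        x = np.full(EPOCH_LEN, 98.0)
        x[POI[0]: POI[1]] = 105.0
        out = corrected(x)
        assert out[POI[0]: POI[1]].mean() == pytest.approx(7.0)
        assert out[BASELINE[0]: BASELINE[1]].mean() == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self):
        x = np.random.default_rng(0).normal(100, 5, EPOCH_LEN)
        once = corrected(x)
        np.testing.assert_allclose(corrected(once), once, atol=1e-9)

    def test_empty_baseline_raises(self):
        with pytest.raises(ConfigError):
            baseline_correct(np.ones(10), (5, 5))


class TestAverageEpochs:
    def test_single_epoch_is_itself(self):
        rng = np.random.default_rng(1)
        e = make_epoch(corrected(rng.normal(100, 3, EPOCH_LEN)),
                       corrected(rng.normal(100, 3, EPOCH_LEN)))
        avg = average_epochs([e])
        np.testing.assert_array_equal(avg.left, e.left)
        assert np.all(avg.se_difference == 0)

    def test_mirrored_epochs_cancel(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0, 2, EPOCH_LEN)
        base = corrected(np.full(EPOCH_LEN, 100.0))
        e1 = make_epoch(base + d, base)
        e2 = make_epoch(base, base + d)
        avg = average_epochs([e1, e2])
        np.testing.assert_allclose(avg.difference, 0.0, atol=1e-9)

    def test_se_matches_brute_force(self):
        rng = np.random.default_rng(3)
        eps = [
            make_epoch(corrected(rng.normal(100, 3, EPOCH_LEN)),
                       corrected(rng.normal(100, 3, EPOCH_LEN)))
            for _ in range(7)
        ]
        avg = average_epochs(eps)
        D = np.stack([e.left - e.right for e in eps])
        brute = D.std(axis=0, ddof=1) / np.sqrt(7)
        np.testing.assert_allclose(avg.se_difference, brute, atol=1e-9)

    def test_rejected_epochs_excluded_and_empty_errors(self):
        e = make_epoch(np.zeros(EPOCH_LEN), np.zeros(EPOCH_LEN), status="rejected")
        with pytest.raises(NoDataError):
            average_epochs([e])


class TestComputeLI:
    def test_zero_difference_tie_rule(self):
        li, lat, peak = compute_li(np.zeros(EPOCH_LEN), POI, 2.0, RATE, OFFSET)
        assert li == 0.0
        assert lat == pytest.approx((OFFSET + POI[0]) / RATE)  # POI start, 3 s
        assert peak == POI[0]

    def test_swap_negates_exactly_same_latency(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.5, 2.0, EPOCH_LEN)
        li, lat, _ = compute_li(d, POI, 2.0, RATE, OFFSET)
        li2, lat2, _ = compute_li(-d, POI, 2.0, RATE, OFFSET)
        assert li2 == -li  # exact, not approximate
        assert lat2 == lat

    def test_triangular_peak_brute_force(self):
        # triangle peaking at 8 s with value 6; LI = brute-force mean over [7, 9) s
        t = (OFFSET + np.arange(EPOCH_LEN)) / RATE
        d = np.maximum(0.0, 6.0 - 2.0 * np.abs(t - 8.0))
        li, lat, _ = compute_li(d, POI, 2.0, RATE, OFFSET)
        window = (t >= 7.0) & (t < 9.0)
        assert li == pytest.approx(d[window].mean(), abs=1e-12)
        assert lat == pytest.approx(8.0)

    def test_window_beyond_epoch_is_error_not_truncation(self):
        d = np.zeros(100)
        d[98] = 5.0
        with pytest.raises(ConfigError):
            compute_li(d, (90, 100), 2.0, RATE, 0)

    def test_sum_mode_scales_with_sample_count(self):
        d = np.ones(EPOCH_LEN)
        li_mean, _, _ = compute_li(d, POI, 2.0, RATE, OFFSET, li_mode="mean")
        li_sum, _, _ = compute_li(d, POI, 2.0, RATE, OFFSET, li_mode="sum")
        assert li_sum == pytest.approx(li_mean * 50)  # 2 s at 25 Hz


class TestPerEpochLI:
    def test_identical_epochs_match_average(self):
        rng = np.random.default_rng(5)
        l = corrected(rng.normal(100, 2, EPOCH_LEN))
        r = corrected(rng.normal(100, 2, EPOCH_LEN))
        eps = [make_epoch(l, r) for _ in range(4)]
        lis = per_epoch_li(eps, 2.0)
        assert lis.shape == (4,)
        assert np.all(lis == lis[0])
        avg_li, _, _ = compute_li(
            average_epochs(eps).difference, POI, 2.0, RATE, OFFSET
        )
        assert lis[0] == pytest.approx(avg_li, abs=1e-9)


class TestSummaryStat:
    def test_constant_mean(self):
        assert summary_stat(np.full(100, 7.0), (10, 60), "mean") == 7.0

    def test_rms_square_wave(self):
        sq = 3.0 * np.tile([1.0, -1.0], 50)
        assert summary_stat(sq, (0, 100), "rms") == pytest.approx(3.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_all_nine_stats_against_brute_force(self, seed):
        x = np.random.default_rng(seed).normal(0, 5, 200)
        w = (20, 170)
        seg = x[20:170]
        n = seg.size
        sd = np.sqrt(np.sum((seg - seg.mean()) ** 2) / (n - 1))
        sem = sd / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        brute = {
            "mean": seg.sum() / n,
            "sd": sd,
            "sem": sem,
            "min": sorted(seg)[0],
            "max": sorted(seg)[-1],
            "rms": np.sqrt(np.sum(seg**2) / n),
            "median": np.median(seg),
            "iqr": np.percentile(seg, 75) - np.percentile(seg, 25),
        }
        for stat, expected in brute.items():
            assert summary_stat(x, w, stat) == pytest.approx(expected, abs=1e-9)
        lo, hi = summary_stat(x, w, "ci95")
        assert lo == pytest.approx(seg.mean() - tcrit * sem, abs=1e-9)
        assert hi == pytest.approx(seg.mean() + tcrit * sem, abs=1e-9)

    def test_unknown_selector(self):
        with pytest.raises(ConfigError):
            summary_stat(np.ones(10), (0, 10), "mode")


class TestInfer:
    def test_degenerate_identical_values(self):
        res = infer(np.full(10, 4.0), "t_one")
        assert res.degenerate
        assert res.p == 0.0
        assert np.isinf(res.statistic)
        assert np.isnan(res.effect_size)

    def test_symmetric_values_not_significant(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        res = infer(x, "t_one")
        assert res.p == pytest.approx(1.0)
        assert res.effect_size == pytest.approx(0.0)
        res_w = infer(x, "wilcoxon_one")
        assert res_w.p > 0.9

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_t_statistic_brute_force(self, seed):
        x = np.random.default_rng(seed).normal(1, 2, 15)
        res = infer(x, "t_one")
        brute = x.mean() / (x.std(ddof=1) / np.sqrt(15))
        assert res.statistic == pytest.approx(brute, abs=1e-9)
        assert res.effect_size == pytest.approx(x.mean() / x.std(ddof=1), abs=1e-9)

    def test_paired_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(6)
        l, r = rng.normal(5, 1, 12), rng.normal(3, 1, 12)
        assert infer(l, "t_paired", paired_with=r).statistic == pytest.approx(
            infer(l - r, "t_one").statistic, abs=1e-9
        )

    def test_n_below_two_raises(self):
        with pytest.raises(InsufficientDataError):
            infer(np.array([1.0]), "t_one")


class TestAnalyze:
    def _epochs(self, n=8, li=4.0, seed=7):
        rng = np.random.default_rng(seed)
        t = (OFFSET + np.arange(EPOCH_LEN)) / RATE
        resp = np.where((t > 2) & (t < 14), 1.0, 0.0)
        eps = []
        for _ in range(n):
            l = corrected(100 + 8 * resp + li / 2 * resp + rng.normal(0, 0.3, EPOCH_LEN))
            r = corrected(100 + 8 * resp - li / 2 * resp + rng.normal(0, 0.3, EPOCH_LEN))
            eps.append(make_epoch(l, r))
        return eps

    def test_ci95_halfwidth_brute_force(self):
        eps = self._epochs()
        res = analyze(eps, TimingSpec())
        tcrit = stats.t.ppf(0.975, res.n_epochs - 1)
        lo, hi = res.ci95
        assert hi - lo == pytest.approx(2 * tcrit * res.li_se, abs=1e-9)
        assert lo <= res.li <= hi

    def test_translation_invariance(self):
        eps = self._epochs()
        shifted = [
            make_epoch(e.left.copy(), e.right.copy()) for e in eps
        ]
        # adding a constant to both channels before baseline correction
        # changes nothing: correction removes it
        t = (OFFSET + np.arange(EPOCH_LEN)) / RATE
        for e in shifted:
            e.left[:] = baseline_correct(e.left + 11.5, BASELINE)
            e.right[:] = baseline_correct(e.right + 11.5, BASELINE)
        r1, r2 = analyze(eps, TimingSpec()), analyze(shifted, TimingSpec())
        assert r1.li == pytest.approx(r2.li, abs=1e-9)
        np.testing.assert_allclose(r1.per_epoch_li, r2.per_epoch_li, atol=1e-9)

    def test_antisymmetry_under_channel_swap(self):
        eps = self._epochs()
        swapped = [make_epoch(e.right, e.left) for e in eps]
        r1, r2 = analyze(eps, TimingSpec()), analyze(swapped, TimingSpec())
        assert r2.li == -r1.li
        assert r2.peak_latency == r1.peak_latency
        np.testing.assert_array_equal(r2.per_epoch_li, -r1.per_epoch_li)

    def test_recovers_injected_difference(self):
        res = analyze(self._epochs(li=4.0), TimingSpec())
        assert 3.5 < res.li < 4.5
        assert res.n_epochs == 8
        assert res.tests["t_one"].p < 0.01
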