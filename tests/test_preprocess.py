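import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftcd.errors import ConfigError, DegenerateSignalError, NoEpochsError
from ftcd.io import VelocityRecording
from ftcd.preprocess import (
    detect_heart_cycles,
    downsample,
    integrate_heart_cycles,
    normalize,
    trim_to_epochs,
)


def _rec(n=1000, rate=100.0, event=True):
    rng = np.random.default_rng(0)
    return VelocityRecording(
        left=rng.uniform(40, 60, n),
        right=rng.uniform(40, 60, n),
        event_channels=[np.zeros(n)] if event else [],
        sample_rate=rate,
    )


class TestDownsample:
    def test_100_to_25_keeps_every_4th(self):
        rec = _rec()
        out = downsample(rec, 25.0)
        assert np.array_equal(out.left, rec.left[::4])
        assert np.array_equal(out.right, rec.right[::4])
        assert np.array_equal(out.event_channels[0], rec.event_channels[0][::4])
        assert out.sample_rate == 25.0

    def test_identity(self):
        rec = _rec()
        out = downsample(rec, 100.0)
        assert np.array_equal(out.left, rec.left)

    def test_non_integer_stride_rejected(self):
        with pytest.raises(ConfigError):
            downsample(_rec(), 30.0)


class TestNormalize:
    def test_printed_formula_example(self):
        np.testing.assert_allclose(normalize([1, 2, 3]), [50, 100, 150])

    def test_constant_maps_to_100(self):
        np.testing.assert_allclose(normalize(np.full(10, 7.3)), 100.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mean_is_100_for_random_positive_signals(self, seed):
        x = np.random.default_rng(seed).uniform(1, 200, 500)
        assert abs(normalize(x).mean() - 100.0) < 1e-9

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).uniform(1, 200, 300)
        once = normalize(x)
        np.testing.assert_allclose(normalize(once), once, atol=1e-9)

    def test_degenerate_mean_raises(self):
        with pytest.raises(DegenerateSignalError):
            normalize(np.zeros(10))


class TestTrim:
    def test_single_marker_window_arithmetic(self):
        rec = _rec(n=20000, rate=100.0)
        trimmed, new_times = trim_to_epochs(rec, (-20, 30), np.array([100.0]))
        # retained span [80 s, 130 s) -> 5000 samples
        assert trimmed.n_samples == 5000
        assert np.array_equal(trimmed.left, rec.left[8000:13000])
        assert new_times[0] == pytest.approx(20.0)  # 100 s -> 20 s after trim

    def test_overlapping_windows_union_once(self):
        rec = _rec(n=20000, rate=100.0)
        trimmed, _ = trim_to_epochs(rec, (-20, 30), np.array([100.0, 120.0]))
        # union [80, 150) -> 7000 samples, not 10000
        assert trimmed.n_samples == 7000

    def test_trim_shields_normalization_from_excursions(self):
        # a huge excursion outside every epoch window must not bias the
        # normalized in-epoch level once trimming is applied
        rate = 100.0
        n = 20000
        left = np.full(n, 50.0)
        left[:2000] = 500.0  # excursion in the first 20 s, epochs start at 80 s
        rec = VelocityRecording(left, np.full(n, 50.0), [np.zeros(n)], rate)
        trimmed, _ = trim_to_epochs(rec, (-20, 30), np.array([100.0]))
        np.testing.assert_allclose(normalize(trimmed.left), 100.0)
        assert normalize(rec.left).mean() == pytest.approx(100.0)
        assert np.median(normalize(rec.left)) < 100.0  # untrimmed is biased

    def test_no_markers_raises(self):
        with pytest.raises(NoEpochsError):
            trim_to_epochs(_rec(), (-20, 30), np.array([]))


class TestHeartCycles:
    def test_two_sample_cycle_mean_replacement(self):
        np.testing.assert_allclose(
            integrate_heart_cycles(np.array([80.0, 120.0]), np.array([0])),
            [100.0, 100.0],
        )

    def test_constant_signal_unchanged(self):
        x = np.full(50, 42.0)
        np.testing.assert_allclose(
            integrate_heart_cycles(x, np.array([10, 20, 30])), x
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_per_cycle_means_conserved(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(100, 10, 200)
        bounds = np.sort(rng.choice(np.arange(1, 199), size=6, replace=False))
        out = integrate_heart_cycles(x, bounds)
        edges = np.concatenate(([0], bounds, [200]))
        for a, b in zip(edges[:-1], edges[1:]):
            assert out[a:b].mean() == pytest.approx(x[a:b].mean(), abs=1e-9)
            assert np.ptp(out[a:b]) == 0  # piecewise constant
        assert out.sum() == pytest.approx(x.sum(), abs=1e-6)

    def test_empty_boundaries_error(self):
        with pytest.raises(ValueError):
            integrate_heart_cycles(np.ones(10), np.array([]))

    def test_cycle_count_on_simulated_cardiac_signal(self):
        from ftcd.simulate import SimulationSpec, simulate_recording

        spec = SimulationSpec(
            n_epochs=1, cardiac_rate=1.2, noise_sd=0.0, drift_amplitude=0.0,
            response_amplitude=0.0, injected_li=0.0, li_epoch_sd=0.0,
            first_marker=25.0, tail=35.0, seed=3,
        )
        rec, _ = simulate_recording(spec)
        seg = rec.left[: int(60 * rec.sample_rate)]
        peaks = detect_heart_cycles(seg, rec.sample_rate)
        assert abs(len(peaks) - 72) <= 2

    def test_flat_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = detect_heart_cycles(np.full(1000, 100.0), 25.0)
        assert out.size == 0
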