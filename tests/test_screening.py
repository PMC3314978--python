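import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftcd.errors import ConfigError
from ftcd.events import EpochIndex
from ftcd.screening import (
    ScreeningConfig,
    apply_manual_exclusions,
    dropout_fraction,
    goodness_of_recording,
    screen_range,
    screen_separation,
)


class TestRange:
    def test_in_band_passes(self):
        rng = np.random.default_rng(0)
        l = rng.uniform(90, 110, 100)
        ok, why = screen_range(l, l, (50, 150))
        assert ok and why is None

    def test_single_excursion_fails(self):
        l = np.full(100, 100.0)
        l[3] = 160.0
        ok, why = screen_range(l, np.full(100, 100.0), (50, 150))
        assert not ok and why == "range"

    def test_bounds_inclusive(self):
        l = np.array([50.0, 150.0, 100.0])
        ok, _ = screen_range(l, l, (50, 150))
        assert ok


class TestSeparation:
    def test_identical_channels_pass(self):
        x = np.random.default_rng(1).uniform(60, 140, 50)
        assert screen_separation(x, x, 0.001)[0]

    def test_constant_offset_fails(self):
        l = np.full(50, 100.0)
        ok, why = screen_separation(l, l + 25.0, 20.0)
        assert not ok and why == "separation"

    def test_unilateral_drop_caught_by_separation_not_range(self):
        # one channel drops to 70 (inside the 50-150 band) while the other
        # stays at 100: the range rule passes, separation catches it
        l, r = np.full(50, 70.0), np.full(50, 100.0)
        assert screen_range(l, r, (50, 150))[0]
        assert not screen_separation(l, r, 20.0)[0]


class TestDropout:
    @pytest.mark.parametrize(
        "n_zero,expected", [(0, 0.0), (50, 0.05), (1000, 1.0)]
    )
    def test_fraction(self, n_zero, expected):
        x = np.full(1000, 80.0)
        x[:n_zero] = 0.0
        assert dropout_fraction(x, 0.0) == pytest.approx(expected)


class TestGoodnessOfRecording:
    def test_flat_baseline_passes(self):
        flat = np.full(250, 100.0)
        gl, gr, excl = goodness_of_recording([(flat, flat)] * 5, 2.0)
        assert gl == 0.0 and gr == 0.0 and not excl

    @pytest.mark.parametrize("amp,excluded", [(3.0, True), (1.0, False)])
    def test_square_wave_closed_form(self, amp, excluded):
        # RMS of a +/-a square wave about its mean is exactly a
        sq = 100.0 + amp * np.tile([1.0, -1.0], 125)
        gl, gr, excl = goodness_of_recording([(sq, sq)] * 3, 2.0)
        assert gl == pytest.approx(amp, abs=1e-9)
        assert excl is excluded

    def test_sinusoid_rms_closed_form(self):
        a = 2.5
        t = np.arange(1000) / 1000.0
        sine = 100.0 + a * np.sin(2 * np.pi * 10 * t)  # whole periods
        gl, _, _ = goodness_of_recording([(sine, sine)], 100.0)
        assert gl == pytest.approx(a / np.sqrt(2), abs=1e-6)

    def test_no_epochs_flags_file(self):
        gl, gr, excl = goodness_of_recording([], 2.0)
        assert np.isnan(gl) and excl


class TestManualExclusions:
    def _index(self, n=23):
        return EpochIndex(accepted=np.arange(n) * 60.0 + 25.0)

    def test_empty_is_identity(self):
        idx = self._index()
        out = apply_manual_exclusions(idx, [])
        assert np.array_equal(out.accepted, idx.accepted)

    def test_exclude_one_of_23(self):
        out = apply_manual_exclusions(self._index(), [2])
        assert out.n_accepted == 22
        assert (145.0, "manual") in out.rejected

    def test_out_of_range_index_is_config_error(self):
        with pytest.raises(ConfigError, match="99"):
            apply_manual_exclusions(self._index(), [99])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"accept_range": (110.0, 150.0)},
            {"max_separation": 0.0},
            {"gor_limit": -1.0},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ConfigError):
            ScreeningConfig(**kw)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_screening_verdicts_are_per_epoch_independent(seed):
    rng = np.random.default_rng(seed)
    epochs = [
        (rng.uniform(40, 170, 30), rng.uniform(40, 170, 30)) for _ in range(6)
    ]
    solo = [screen_range(l, r)[0] for l, r in epochs]
    # dropping any epoch never changes another's verdict
    for drop in range(6):
        rest = [e for i, e in enumerate(epochs) if i != drop]
        verdicts = [screen_range(l, r)[0] for l, r in rest]
        assert verdicts == [v for i, v in enumerate(solo) if i != drop]


def test_planted_contamination_detected_exactly(default_cfg):
    """Simulator epochs contaminated well past threshold are rejected;
    clean epochs well inside the limits are kept."""
    from ftcd.pipeline import process_recording
    from ftcd.simulate import SimulationSpec, simulate_recording

    m = lambda e: 25.0 + 60.0 * e  # marker time of epoch e
    spec = SimulationSpec(
        n_epochs=10,
        seed=21,
        dropout_segments=[
            ("left", m(2) + 4, 5, 0.3),   # range violation (and separation)
            ("right", m(2) + 4, 5, 0.3),  # both channels -> pure range case
            ("left", m(6) + 4, 5, 0.3),
            ("right", m(6) + 4, 5, 0.3),
        ],
    )
    rec, truth = simulate_recording(spec)
    import ftcd

    cfg = ftcd.load_config({})
    cfg.events[0].timing.n_epochs = 10
    fr = process_recording(rec, cfg)
    assert fr.quality.rejected_epochs == truth.contaminated_epochs == [2, 6]
    for e in truth.contaminated_epochs:
        assert "range" in fr.quality.epoch_reasons[e]
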