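"""Synthetic dual-probe fTCD recordings with known ground truth.

The generator produces left/right cerebral blood-flow-velocity channels of
the form::

    level * (1 + cardiac + response (+/- lateral/2) + drift + noise)

* **cardiac** — a zero-mean, asymmetric pulse (fast systolic rise, slow
  decay) built from a half-rectified harmonic sum, repeating at the
  cardiac rate with an independent phase per channel;
* **response** — a trapezoidal evoked rise locked to each task marker
  (rise, plateau, fall), with the left/right channels split by half the
  injected lateral difference; trial-to-trial lateral variability is
  drawn per epoch;
* **drift** — a slow sinusoid per channel emulating gradual probe
  movement; its period is deliberately incommensurate with the trial
  spacing so it does not alias into the epoch average;
* **noise** — white Gaussian noise, independent per channel;
* **dropouts** — configurable segments multiplied by an attenuation
  factor (0 = lost signal), emulating probe disturbance;
* the marker channel carries rectangular pulses at every true epoch onset
  plus any requested spurious markers.

Defaults emulate the word-generation protocol: 23 trials of 60 s at
100 Hz, an 8% evoked velocity rise, a +4% sustained left−right
difference (left-dominant), 10% cardiac pulsatility at 1.2 Hz, 1% drift
and 1% noise. Everything is reproducible from the seed, and the returned
ground truth lists true/spurious marker times, the per-epoch injected
lateral difference, analytic per-epoch design means and the epochs
contaminated by dropouts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import VelocityRecording

__all__ = ["SimulationSpec", "GroundTruth", "simulate_recording", "write_fixture"]


@dataclass
class SimulationSpec:
    """Ground-truth parameters of one simulated session.

    Percentages are relative to each channel's baseline level.
    ``dropout_segments`` entries are ``(channel, start_s, duration_s)`` or
    ``(channel, start_s, duration_s, attenuation)`` with channel "left" or
    "right" and attenuation 0 by default (total signal loss).
    """

    sample_rate: float = 100.0
    n_epochs: int = 23
    inter_marker_interval: float = 60.0
    first_marker: float = 25.0
    epoch_window: tuple[float, float] = (-20.0, 30.0)

    cardiac_rate: float = 1.2          # Hz
    cardiac_amplitude: float = 10.0    # % of mean level

    response_onset: float = 2.0        # s after the marker
    response_duration: float = 12.0    # total s, including rise and fall
    response_rise: float = 2.0
    response_fall: float = 3.0
    response_amplitude: float = 8.0    # % evoked velocity rise
    injected_li: float = 4.0           # % left-minus-right during response
    li_epoch_sd: float = 0.75          # % SD of trial-to-trial lateral jitter

    baseline_level_left: float = 55.0  # cm/s
    baseline_level_right: float = 50.0
    drift_amplitude: float = 1.0       # %
    drift_period: float = 127.0        # s
    noise_sd: float = 1.0              # %

    dropout_segments: list = field(default_factory=list)
    spurious_markers: list = field(default_factory=list)
    marker_pulse_height: float = 5.0
    marker_pulse_width: float = 0.5    # s
    tail: float = 35.0                 # s of recording after the last marker
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ConfigError("n_epochs must be >= 1")
        lo, hi = self.epoch_window
        if self.inter_marker_interval <= hi - lo:
            raise ConfigError(
                f"inter_marker_interval ({self.inter_marker_interval} s) must "
                f"exceed the epoch length ({hi - lo} s)"
            )
        if not 0.5 < self.cardiac_rate < 3.0:
            raise ConfigError("cardiac_rate must lie in (0.5, 3) Hz")
        if self.response_rise + self.response_fall > self.response_duration:
            raise ConfigError("response rise + fall exceed the response duration")
        if self.first_marker + lo < 0:
            raise ConfigError("first_marker leaves no room for the epoch window")

    @property
    def marker_times(self) -> np.ndarray:
        return self.first_marker + self.inter_marker_interval * np.arange(
            self.n_epochs, dtype=float
        )

    @property
    def duration(self) -> float:
        return float(self.marker_times[-1] + self.tail)


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle-style tests."""

    marker_times: list
    spurious_markers: list
    per_epoch_li: list          # injected left-minus-right % per epoch
    design_epoch_means: list    # [n_epochs][2]: noise/cardiac-free epoch means
    contaminated_epochs: list   # sorted epoch indices touched by a dropout
    contamination_detail: list  # (epoch, channel, attenuation)
    cardiac_rate: float
    seed: int

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _cardiac_waveform(phase: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-peak asymmetric cardiac pulse.

    Half-rectified sum of the first four harmonics: steep systolic upstroke
    followed by a slow decay, which yields realistic step levels under
    heart-cycle integration without modelling real hemodynamics.
    """
    grid = np.linspace(0.0, 1.0, 4096, endpoint=False)

    def raw(p):
        s = np.zeros_like(p)
        for h in range(1, 5):
            s += np.sin(2 * np.pi * h * p) / h
        return np.maximum(s, 0.0)

    ref = raw(grid)
    peak = ref.max()
    mean = ref.mean()
    return (raw(np.mod(phase, 1.0)) - mean) / peak


def _trapezoid(tau: np.ndarray, rise: float, duration: float, fall: float) -> np.ndarray:
    """Evoked-response envelope: 0 before onset, linear rise, plateau,
    linear fall back to 0 at ``duration``."""
    env = np.zeros_like(tau)
    up = (tau >= 0) & (tau < rise)
    env[up] = tau[up] / rise
    flat = (tau >= rise) & (tau <= duration - fall)
    env[flat] = 1.0
    down = (tau > duration - fall) & (tau < duration)
    env[down] = (duration - tau[down]) / fall
    return env


def _sin_mean(amp: float, period: float, phase: float, t0: float, t1: float) -> float:
    """Exact mean of amp*sin(2*pi*t/period + phase) over [t0, t1]."""
    w = 2 * np.pi / period
    return float(amp * (np.cos(w * t0 + phase) - np.cos(w * t1 + phase)) / (w * (t1 - t0)))


def simulate_recording(spec: SimulationSpec) -> tuple[VelocityRecording, GroundTruth]:
    """Generate one recording and its ground truth. Fully seed-determined."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    markers = spec.marker_times

    jitter = (
        rng.normal(0.0, spec.li_epoch_sd, spec.n_epochs)
        if spec.li_epoch_sd > 0
        else np.zeros(spec.n_epochs)
    )
    epoch_li = spec.injected_li + jitter

    cardiac_phase = rng.uniform(0, 1, size=2)
    drift_phase = rng.uniform(0, 2 * np.pi, size=2)
    levels = (spec.baseline_level_left, spec.baseline_level_right)
    signals = []
    design_means = np.zeros((spec.n_epochs, 2))
    e_lo, e_hi = spec.epoch_window

    for ci, level in enumerate(levels):
        side = +1.0 if ci == 0 else -1.0
        frac = np.zeros(n)
        if spec.cardiac_amplitude > 0:
            frac += (spec.cardiac_amplitude / 100.0) * _cardiac_waveform(
                t * spec.cardiac_rate + cardiac_phase[ci]
            )
        for e, tm in enumerate(markers):
            amp = (spec.response_amplitude + side * epoch_li[e] / 2.0) / 100.0
            env = _trapezoid(
                t - tm - spec.response_onset,
                spec.response_rise,
                spec.response_duration,
                spec.response_fall,
            )
            frac += amp * env
            # analytic epoch mean of the deterministic part (no cardiac/noise:
            # the cardiac term is zero-mean over every full cycle)
            area = amp * (
                spec.response_duration
                - spec.response_rise / 2.0
                - spec.response_fall / 2.0
            )
            drift_mean = (
                _sin_mean(
                    spec.drift_amplitude / 100.0,
                    spec.drift_period,
                    drift_phase[ci],
                    tm + e_lo,
                    tm + e_hi,
                )
                if spec.drift_amplitude > 0
                else 0.0
            )
            design_means[e, ci] = level * (1.0 + area / (e_hi - e_lo) + drift_mean)
        if spec.drift_amplitude > 0:
            frac += (spec.drift_amplitude / 100.0) * np.sin(
                2 * np.pi * t / spec.drift_period + drift_phase[ci]
            )
        if spec.noise_sd > 0:
            frac += rng.normal(0.0, spec.noise_sd / 100.0, n)
        signals.append(level * (1.0 + frac))

    left, right = signals
    contaminated: list[tuple[int, str, float]] = []
    for seg in spec.dropout_segments:
        ch, start, dur, *rest = seg
        atten = float(rest[0]) if rest else 0.0
        a = max(0, int(round(start * fs)))
        b = min(n, int(round((start + dur) * fs)))
        target = left if ch == "left" else right
        target[a:b] *= atten
        for e, tm in enumerate(markers):
            if start < tm + e_hi and start + dur > tm + e_lo:
                contaminated.append((e, ch, atten))

    left = np.maximum(left, 0.0)
    right = np.maximum(right, 0.0)

    event = np.zeros(n)
    w = max(1, int(round(spec.marker_pulse_width * fs)))
    for tm in list(markers) + list(spec.spurious_markers):
        a = int(round(tm * fs))
        event[a : min(n, a + w)] = spec.marker_pulse_height

    rec = VelocityRecording(
        left=left,
        right=right,
        event_channels=[event],
        sample_rate=fs,
        channel_map={"left": 1, "right": 2, "event": 3},
        source_id=f"sim(seed={spec.seed})",
    )
    truth = GroundTruth(
        marker_times=[float(x) for x in markers],
        spurious_markers=[float(x) for x in spec.spurious_markers],
        per_epoch_li=[float(x) for x in epoch_li],
        design_epoch_means=design_means.tolist(),
        contaminated_epochs=sorted({e for e, _, _ in contaminated}),
        contamination_detail=[[e, ch, a] for e, ch, a in contaminated],
        cardiac_rate=spec.cardiac_rate,
        seed=spec.seed,
    )
    return rec, truth


def write_fixture(spec: SimulationSpec, stem) -> dict[str, Path]:
    """Simulate and write the recording in both supported text dialects.

    Writes ``<stem>.exp`` (header + TSV dialect, sample rate declared in
    the header), ``<stem>.tsv`` (generic delimited table with a column-name
    row) and ``<stem>_truth.json``. Values are written with shortest
    round-trip float formatting, so reading reproduces the simulated
    channels exactly.
    """
    rec, truth = simulate_recording(spec)
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    cols = np.column_stack([rec.left, rec.right, rec.event_channels[0]])

    rows = "\n".join(
        "\t".join(repr(float(v)) for v in row) for row in cols
    )
    exp = stem.with_suffix(".exp")
    exp.write_text(
        "source: synthetic fTCD session\n"
        f"seed: {spec.seed}\n"
        f"sample_rate: {spec.sample_rate!r}\n"
        "columns: left right event\n"
        "\n" + rows + "\n"
    )
    tsv = stem.with_suffix(".tsv")
    tsv.write_text("left\tright\tevent\n" + rows + "\n")
    truth_path = truth.to_json(stem.parent / (stem.name + "_truth.json"))
    return {"exp": exp, "tsv": tsv, "truth": truth_path}
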