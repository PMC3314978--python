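"""Downsampling, trimming, normalization and heart-cycle integration.

The velocity signal carries three nuisance components on top of the evoked
response: the cardiac pulse (~1 Hz), respiratory/arousal drift (< 0.1 Hz),
and probe-angle scale differences between the two channels. This module
removes them in the canonical order: decimate, (optionally) trim to the
task epochs, normalize each channel to a mean of 100, then replace every
sample within a cardiac cycle by the cycle mean ("heart-cycle integration"),
which leaves a step-like trace free of pulsatile variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigError, DegenerateSignalError, NoEpochsError
from .io import VelocityRecording

__all__ = [
    "ProcessingConfig",
    "downsample",
    "normalize",
    "trim_to_epochs",
    "detect_heart_cycles",
    "integrate_heart_cycles",
]


@dataclass
class ProcessingConfig:
    """Signal-conditioning settings.

    target_rate
        Output rate in Hz; must divide the recording rate exactly (samples
        are dropped, never interpolated).
    normalization_scope
        ``"whole-record"``, ``"trimmed"`` or ``"per-epoch"``: which stretch
        of data supplies the mean that is scaled to 100.
    heart_cycle_integration
        Whether to replace samples by per-cardiac-cycle means.
    min_cycle_s
        Minimum credible cardiac period in seconds (0.25–2 s, i.e. 240–30
        bpm); enforces a refractory distance in peak detection.
    prominence
        Required systolic-peak prominence as a fraction of the robust
        signal range (10th–90th percentile).
    """

    target_rate: float = 25.0
    normalization_scope: str = "whole-record"
    heart_cycle_integration: bool = True
    min_cycle_s: float = 0.33
    prominence: float = 0.25

    def __post_init__(self) -> None:
        if not 0.25 <= self.min_cycle_s <= 2.0:
            raise ConfigError(
                f"min_cycle_s must lie in [0.25, 2] s, got {self.min_cycle_s}"
            )
        if self.normalization_scope not in ("whole-record", "trimmed", "per-epoch"):
            raise ConfigError(
                f"unknown normalization_scope {self.normalization_scope!r}"
            )


def downsample(rec: VelocityRecording, target_rate: float) -> VelocityRecording:
    """Decimate all channels by keeping every k-th sample (no filtering).

    k = sample_rate / target_rate must be an exact integer; e.g. 100 Hz
    reduced to 25 Hz keeps every 4th sample, starting with the first. The
    event channels are decimated with the same stride so markers stay
    aligned with the velocity samples.
    """
    stride = rec.sample_rate / target_rate
    if abs(stride - round(stride)) > 1e-9 or stride < 1:
        raise ConfigError(
            f"target rate {target_rate} Hz does not divide the recording "
            f"rate {rec.sample_rate} Hz (no resampling interpolation is done)"
        )
    k = int(round(stride))
    return rec.copy(
        left=rec.left[::k].copy(),
        right=rec.right[::k].copy(),
        event_channels=[e[::k].copy() for e in rec.event_channels],
        sample_rate=float(target_rate),
    )


def normalize(channel: np.ndarray) -> np.ndarray:
    """Scale a channel to a mean of 100: output = 100 * data / mean(data).

    This equates the average level of the left and right channels (probe
    angle makes the raw scales incomparable) while preserving relative
    variation.
    """
    x = np.asarray(channel, dtype=float)
    m = x.mean()
    if not np.isfinite(m) or m <= 0:
        raise DegenerateSignalError(
            f"cannot normalize channel with mean {m!r} (must be positive)"
        )
    return 100.0 * x / m


def trim_to_epochs(
    rec: VelocityRecording,
    epoch_window: tuple[float, float],
    marker_times: np.ndarray,
) -> tuple[VelocityRecording, np.ndarray]:
    """Drop samples outside the union of per-marker epoch windows.

    Applied *before* normalization so that wild excursions during rest
    breaks or at the start/end of a session cannot bias the channel mean.
    Overlapping windows are retained once. Returns the trimmed recording
    and the marker times re-expressed on the trimmed sample axis.
    """
    marker_times = np.asarray(marker_times, dtype=float)
    if marker_times.size == 0:
        raise NoEpochsError("no markers: cannot trim to epoch windows")
    lo, hi = epoch_window
    if not lo < hi:
        raise ConfigError(f"epoch window must satisfy lower < upper, got {epoch_window}")
    rate = rec.sample_rate
    keep = np.zeros(rec.n_samples, dtype=bool)
    for t in marker_times:
        a = max(0, int(np.floor((t + lo) * rate)))
        b = min(rec.n_samples, int(np.floor((t + hi) * rate)))
        keep[a:b] = True
    new_index = np.cumsum(keep) - 1  # old sample -> new sample
    marker_samples = np.round(marker_times * rate).astype(int)
    marker_samples = np.clip(marker_samples, 0, rec.n_samples - 1)
    new_times = new_index[marker_samples] / rate
    trimmed = rec.copy(
        left=rec.left[keep].copy(),
        right=rec.right[keep].copy(),
        event_channels=[e[keep].copy() for e in rec.event_channels],
    )
    return trimmed, new_times


def detect_heart_cycles(
    channel: np.ndarray,
    sample_rate: float,
    min_cycle_s: float = 0.33,
    prominence: float = 0.25,
) -> np.ndarray:
    """Locate cardiac-cycle boundaries at successive systolic peaks.

    The channel is lightly smoothed (~0.1 s moving average) and systolic
    peaks found with a refractory distance of ``min_cycle_s``. Returns peak
    sample indices; fewer than two detectable peaks yields an empty array
    and a warning (downstream integration then degrades to the identity).

    The boundaries detected on one channel should be applied to both: the
    cardiac rhythm is common to the two arteries, and channel-specific
    boundaries would desynchronize the left−right difference.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 2 * int(min_cycle_s * sample_rate):
        warnings.warn("signal too short for cardiac-cycle detection")
        return np.array([], dtype=int)
    w = max(1, int(round(0.1 * sample_rate)))
    kernel = np.ones(w) / w
    smooth = np.convolve(x, kernel, mode="same")
    lo_q, hi_q = np.percentile(smooth, [10, 90])
    span = hi_q - lo_q
    if span <= 0:
        warnings.warn("flat signal: no cardiac periodicity detectable")
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        smooth,
        distance=max(1, int(min_cycle_s * sample_rate)),
        prominence=prominence * span,
    )
    if peaks.size < 2:
        warnings.warn("no cardiac periodicity detected; integration skipped")
        return np.array([], dtype=int)
    return peaks.astype(int)


def integrate_heart_cycles(
    channel: np.ndarray, boundaries: np.ndarray
) -> np.ndarray:
    """Replace every sample within a cardiac cycle by that cycle's mean.

    Produces a piecewise-constant, step-like trace. Segments are the
    half-open intervals between successive boundaries; the partial stretches
    before the first and after the last boundary are likewise replaced by
    their own means, so the whole output is piecewise constant and the
    global sum is conserved exactly.
    """
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries.size == 0:
        raise ValueError("empty cycle-boundary list")
    x = np.asarray(channel, dtype=float)
    out = x.copy()
    edges = np.concatenate(([0], boundaries, [x.size]))
    edges = np.unique(np.clip(edges, 0, x.size))
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            out[a:b] = x[a:b].mean()
    return out
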