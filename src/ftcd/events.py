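"""Event-marker detection, epoch selection and window resolution.

Task cues arrive as rectangular pulses on a marker channel. Everything
downstream is locked to the rising edge of those pulses: each accepted
marker defines one epoch, with baseline and period-of-interest (POI)
windows expressed in seconds relative to the marker (time 0).

Spurious markers — practice-phase cues, parallel-port glitches — typically
precede the real sequence, so the selector walks the detected markers in
*reverse* order, trusting the final marker, and drops any candidate closer
than the minimum separation to the last accepted (later) one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, NoEpochsError

__all__ = [
    "TimingSpec",
    "EpochIndex",
    "EpochWindows",
    "detect_markers",
    "select_epochs",
    "resolve_windows",
]


@dataclass
class TimingSpec:
    """Epoch / baseline / POI timings in seconds relative to the lock marker.

    Defaults follow the standard word-generation protocol: a −20..30 s
    epoch around letter presentation, baseline −15..−5 s (end of the rest
    period), POI 3..13 s (silent word generation), and a 2 s activation
    window over which the LI is computed. ``baseline_lock`` / ``poi_lock``
    select which marker of a multi-marker trial each window attaches to
    (1 = the epoch marker itself).
    """

    epoch_window: tuple[float, float] = (-20.0, 30.0)
    baseline_window: tuple[float, float] = (-15.0, -5.0)
    poi_window: tuple[float, float] = (3.0, 13.0)
    activation_window: float = 2.0
    baseline_lock: int = 1
    poi_lock: int = 1
    n_epochs: int = 23
    min_separation: float = 50.0
    marker_height: float = 2.5

    def __post_init__(self) -> None:
        for name in ("epoch_window", "baseline_window", "poi_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must satisfy lower < upper, got ({lo}, {hi})")
        if self.activation_window <= 0:
            raise ConfigError("activation_window must be > 0")
        if self.n_epochs < 1:
            raise ConfigError("n_epochs must be >= 1")
        if self.min_separation <= 0:
            raise ConfigError("min_separation must be > 0")
        if self.baseline_lock == 1:
            e_lo, e_hi = self.epoch_window
            b_lo, b_hi = self.baseline_window
            if b_lo < e_lo or b_hi > e_hi:
                raise ConfigError("baseline_window must lie within epoch_window")
        if (
            self.poi_lock == self.baseline_lock
            and self.poi_window[0] < self.baseline_window[1]
        ):
            warnings.warn(
                "period of interest starts before the baseline ends "
                "(allowed, but usually a configuration mistake)"
            )


@dataclass
class EpochIndex:
    """Outcome of the marker selection scan.

    ``accepted`` marker times are strictly increasing with pairwise
    separation >= min_separation; ``rejected`` pairs each skipped marker
    time with its reason.
    """

    accepted: np.ndarray
    rejected: list[tuple[float, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


@dataclass
class EpochWindows:
    """Half-open sample ranges for one epoch on the record axis."""

    epoch: tuple[int, int]
    baseline: tuple[int, int]
    poi: tuple[int, int]
    marker_time: float
    short: bool = False


def detect_markers(
    event_channel: np.ndarray, marker_height: float, sample_rate: float
) -> np.ndarray:
    """Rising-edge onset times of supra-threshold marker pulses.

    One onset per contiguous run of samples strictly above
    ``marker_height``; pulse width is irrelevant (a 1-sample glitch and a
    10-sample cue both count once). A value exactly at the threshold is
    ignored — only values *above* the set height are treated as markers.
    """
    x = np.asarray(event_channel, dtype=float)
    above = x > marker_height
    if not above.any():
        return np.array([], dtype=float)
    rising = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    return rising / float(sample_rate)


def select_epochs(
    marker_times: np.ndarray, n_epochs: int, min_separation: float
) -> EpochIndex:
    """Reverse-order scan keeping markers separated by >= min_separation.

    The final marker is assumed true and accepted outright. Walking
    backwards, a candidate whose gap to the previously accepted (later)
    marker is smaller than ``min_separation`` is skipped in favour of the
    next; the scan stops once ``n_epochs`` markers are accepted or the list
    is exhausted. Finding fewer than requested is recorded as a warning,
    not an error.
    """
    times = np.sort(np.asarray(marker_times, dtype=float))
    if times.size == 0:
        raise NoEpochsError("no event markers detected")
    accepted: list[float] = [float(times[-1])]
    rejected: list[tuple[float, str]] = []
    for t in times[-2::-1]:
        if len(accepted) >= n_epochs:
            break
        gap = accepted[-1] - t
        if gap < min_separation:
            rejected.append((float(t), "separation"))
        else:
            accepted.append(float(t))
    warns: list[str] = []
    if len(accepted) < n_epochs:
        warns.append(
            f"only {len(accepted)} of {n_epochs} requested epochs found"
        )
    return EpochIndex(
        accepted=np.array(accepted[::-1], dtype=float),
        rejected=rejected[::-1],
        warnings=warns,
    )


def _offsets(window: tuple[float, float], rate: float) -> tuple[int, int]:
    return int(np.floor(window[0] * rate)), int(np.floor(window[1] * rate))


def resolve_windows(
    index: EpochIndex,
    spec: TimingSpec,
    sample_rate: float,
    n_samples: int,
    lock_markers: dict[int, np.ndarray] | None = None,
) -> list[EpochWindows]:
    """Convert marker times into half-open sample ranges per epoch.

    Offsets are ``floor(bound * rate)`` added to the integer marker sample,
    so every epoch has the identical sample count — a precondition for
    pointwise averaging. With ``baseline_lock`` / ``poi_lock`` other than 1,
    ``lock_markers[lock]`` must supply one marker time per accepted epoch
    (e.g. response-locked POIs whose latency varies trial by trial); both
    windows then attach to their own markers within the same trial.

    Epochs whose range leaves the record bounds are flagged ``short``;
    whether they are kept is the caller's (configurable) decision.
    """
    if index.n_accepted == 0:
        raise NoEpochsError("no accepted epochs to resolve")
    rate = float(sample_rate)
    e_lo, e_hi = _offsets(spec.epoch_window, rate)
    b_lo, b_hi = _offsets(spec.baseline_window, rate)
    p_lo, p_hi = _offsets(spec.poi_window, rate)

    def lock_times(lock: int) -> np.ndarray:
        if lock == 1:
            return np.asarray(index.accepted, dtype=float)
        if not lock_markers or lock not in lock_markers:
            raise ConfigError(
                f"timings locked to marker {lock} but no such marker times given"
            )
        times = np.asarray(lock_markers[lock], dtype=float)
        if times.size != index.n_accepted:
            raise ConfigError(
                f"marker-{lock} times must provide one value per accepted epoch "
                f"({times.size} != {index.n_accepted})"
            )
        return times

    base_times = lock_times(spec.baseline_lock)
    poi_times = lock_times(spec.poi_lock)

    out: list[EpochWindows] = []
    for t, tb, tp in zip(index.accepted, base_times, poi_times):
        m = int(round(t * rate))
        mb = int(round(tb * rate))
        mp = int(round(tp * rate))
        epoch = (m + e_lo, m + e_hi)
        baseline = (mb + b_lo, mb + b_hi)
        poi = (mp + p_lo, mp + p_hi)
        short = (
            epoch[0] < 0
            or epoch[1] > n_samples
            or baseline[0] < 0
            or baseline[1] > n_samples
            or poi[0] < 0
            or poi[1] > n_samples
        )
        out.append(
            EpochWindows(
                epoch=epoch, baseline=baseline, poi=poi,
                marker_time=float(t), short=short,
            )
        )
    return out
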