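"""Artifact screening: range/separation rejection, dropout, recording quality.

Two automatic per-epoch rules catch measurement artifacts in the
normalized signals (mean-100 units):

* **range** — any left or right sample outside an acceptance band around
  the normalized mean (default 50–150, i.e. ±50%);
* **separation** — the left and right channels drifting apart by more than
  a set limit, which catches unilateral probe disturbances that stay
  inside the acceptance band.

File-level quality is summarised by the signal-dropout fraction and the
Goodness of Recording (GOR): the root-mean-square variability of the
baseline period, with recordings above a threshold (default 2% of the
normalized baseline level) flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .events import EpochIndex

__all__ = [
    "ScreeningConfig",
    "QualityReport",
    "screen_range",
    "screen_separation",
    "dropout_fraction",
    "goodness_of_recording",
    "apply_manual_exclusions",
]


@dataclass
class ScreeningConfig:
    """Thresholds for automatic epoch and file screening.

    accept_range
        Inclusive (lower, upper) bounds on normalized sample values;
        common practice excludes excursions beyond 30–50% of the mean
        activation — the default band of 100 ± 50 is the permissive end.
    max_separation
        Largest tolerated |left − right| in % units. Physiological
        left–right differences sit around 5–10; unilateral dropouts
        separate the channels far more.
    gor_limit
        GOR exclusion criterion, % of average baseline activity.
    dropout_value
        Sample value treated as lost signal.
    """

    accept_range: tuple[float, float] = (50.0, 150.0)
    max_separation: float = 20.0
    gor_limit: float = 2.0
    dropout_value: float = 0.0
    manual_exclusions: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.accept_range
        if not lo < 100.0 < hi:
            raise ConfigError(
                f"accept_range must straddle the normalized mean 100, got {self.accept_range}"
            )
        if self.max_separation <= 0:
            raise ConfigError("max_separation must be > 0")
        if self.gor_limit <= 0:
            raise ConfigError("gor_limit must be > 0")


@dataclass
class QualityReport:
    """Per-file data-quality summary."""

    epoch_reasons: dict[int, list[str]] = field(default_factory=dict)
    dropout_left: float = 0.0
    dropout_right: float = 0.0
    gor_left: float = float("nan")
    gor_right: float = float("nan")
    file_excluded: bool = False

    @property
    def rejected_epochs(self) -> list[int]:
        return sorted(i for i, r in self.epoch_reasons.items() if r)


def screen_range(
    left: np.ndarray,
    right: np.ndarray,
    accept_range: tuple[float, float] = (50.0, 150.0),
) -> tuple[bool, str | None]:
    """Pass/fail the range rule. Bounds are inclusive: a sample exactly at
    the limit passes. Returns (passed, reason)."""
    lo, hi = accept_range
    for ch in (left, right):
        x = np.asarray(ch, dtype=float)
        if (x < lo).any() or (x > hi).any():
            return False, "range"
    return True, None


def screen_separation(
    left: np.ndarray, right: np.ndarray, max_separation: float = 20.0
) -> tuple[bool, str | None]:
    """Fail iff max |left − right| exceeds ``max_separation``."""
    sep = np.abs(np.asarray(left, dtype=float) - np.asarray(right, dtype=float))
    if sep.size and sep.max() > max_separation:
        return False, "separation"
    return True, None


def dropout_fraction(channel: np.ndarray, dropout_value: float = 0.0) -> float:
    """Fraction of samples equal to the dropout value (within 1e-12)."""
    x = np.asarray(channel, dtype=float)
    if x.size == 0:
        return 0.0
    return float(np.mean(np.abs(x - dropout_value) <= 1e-12))


def goodness_of_recording(
    baseline_epochs: list[tuple[np.ndarray, np.ndarray]],
    gor_limit: float = 2.0,
) -> tuple[float, float, bool]:
    """Goodness of Recording per channel, and the exclusion verdict.

    For each accepted epoch, the RMS deviation of the baseline samples
    about that epoch's baseline mean is computed per channel; the GOR is
    the across-epoch average, in % of the normalized (mean-100) level.
    Left or right variation above ``gor_limit`` flags the file for
    exclusion. With no accepted epochs the GOR is undefined (NaN) and the
    file is flagged.
    """
    if not baseline_epochs:
        return float("nan"), float("nan"), True

    def rms_about_mean(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(np.sqrt(np.mean((x - x.mean()) ** 2)))

    gl = float(np.mean([rms_about_mean(l) for l, _ in baseline_epochs]))
    gr = float(np.mean([rms_about_mean(r) for _, r in baseline_epochs]))
    return gl, gr, (gl > gor_limit or gr > gor_limit)


def apply_manual_exclusions(
    index: EpochIndex, exclusions: list[int]
) -> EpochIndex:
    """Mark the listed accepted-epoch indices (0-based) rejected: "manual".

    Used when, e.g., the participant demonstrably disengaged during
    particular trials. Indices outside the accepted range raise a
    configuration error naming the offending index.
    """
    n = index.n_accepted
    for i in exclusions:
        if not 0 <= i < n:
            raise ConfigError(
                f"manual exclusion index {i} out of range (file has {n} accepted epochs)"
            )
    if not exclusions:
        return index
    drop = set(exclusions)
    kept = np.array(
        [t for i, t in enumerate(index.accepted) if i not in drop], dtype=float
    )
    rejected = list(index.rejected) + [
        (float(index.accepted[i]), "manual") for i in sorted(drop)
    ]
    return replace(index, accepted=kept, rejected=rejected)
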