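"""Baseline correction, epoch averaging, and the laterality index (LI).

The LI summarises hemispheric dominance: after baseline correction the
left−right velocity difference is averaged across accepted epochs, the
peak difference is located within the period of interest (POI), and the
LI is the mean difference over a short activation window (default 2 s)
centred on that peak. Positive values indicate left-hemisphere dominance,
negative values right-hemisphere dominance.

Numerical conventions
---------------------
* ``li_mode="mean"`` (default) reports the mean of the difference over the
  activation window; this is sampling-rate independent and on the % scale
  of the normalized signals. ``"sum"`` (the windowed sum) is available for
  strict replication of the classical description, but its magnitude
  scales with the sampling rate.
* ``peak_mode="abs"`` (default) locates the maximum |difference| within
  the POI, so the analysis is exactly antisymmetric under swapping the
  left and right channels (the LI negates, the peak latency is unchanged)
  and right-dominant responses are found as reliably as left-dominant
  ones. ``"max"`` (signed maximum) and ``"min"`` are provided for
  replication of pipelines that fix the search direction. Ties break to
  the earliest sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, InsufficientDataError, NoDataError
from .events import TimingSpec

__all__ = [
    "Epoch",
    "AveragedSignals",
    "InferenceResult",
    "LateralityResult",
    "baseline_correct",
    "extract_epoch",
    "average_epochs",
    "compute_li",
    "per_epoch_li",
    "summary_stat",
    "infer",
    "analyze",
]

SUMMARY_STATS = (
    "mean", "sd", "sem", "ci95", "min", "max", "rms", "median", "iqr",
)


@dataclass
class Epoch:
    """One marker-locked, baseline-corrected slice of both channels.

    ``left``/``right`` are % change from each channel's own baseline mean
    (the baseline-window mean of the corrected signal is 0). ``offset`` is
    the epoch's first sample expressed relative to the lock marker, so
    sample *i* sits at time ``(offset + i) / sample_rate`` seconds.
    ``baseline`` and ``poi`` are half-open index ranges *within* the epoch.
    """

    left: np.ndarray
    right: np.ndarray
    offset: int
    baseline: tuple[int, int]
    poi: tuple[int, int]
    sample_rate: float
    marker_time: float = 0.0
    status: str = "accepted"
    reasons: list[str] = field(default_factory=list)

    @property
    def difference(self) -> np.ndarray:
        return self.left - self.right

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds relative to the lock marker."""
        return (self.offset + np.arange(len(self.left))) / self.sample_rate


@dataclass
class AveragedSignals:
    """Pointwise averages across accepted epochs, with per-sample SE."""

    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    difference: np.ndarray
    lr_average: np.ndarray
    se_left: np.ndarray
    se_right: np.ndarray
    se_difference: np.ndarray
    n_epochs: int


@dataclass
class InferenceResult:
    test: str
    statistic: float
    p: float
    effect_size: float
    n: int
    degenerate: bool = False


@dataclass
class LateralityResult:
    """Full laterality summary for one file / epoch selection."""

    li: float
    peak_latency: float
    n_epochs: int
    per_epoch_li: np.ndarray
    li_sd: float
    li_se: float
    ci95: tuple[float, float]
    cohens_d: float
    average: AveragedSignals
    tests: dict[str, InferenceResult] = field(default_factory=dict)
    peak_stats: dict[str, float] = field(default_factory=dict)
    li_mode: str = "mean"
    peak_mode: str = "abs"


def baseline_correct(
    channel: np.ndarray, baseline: tuple[int, int]
) -> np.ndarray:
    """Subtract the baseline-window mean from every sample of the channel.

    After correction, deviations from zero read directly as increases or
    decreases relative to the pre-task resting level. Idempotent.
    """
    a, b = baseline
    x = np.asarray(channel, dtype=float)
    if not 0 <= a < b <= x.size:
        raise ConfigError(
            f"baseline sample range ({a}, {b}) not within epoch of {x.size} samples"
        )
    return x - x[a:b].mean()


def extract_epoch(
    left: np.ndarray,
    right: np.ndarray,
    windows,
    sample_rate: float,
    per_epoch_normalize: bool = False,
) -> Epoch:
    """Slice one epoch out of the (record-axis) channels and baseline-correct.

    ``windows`` is an :class:`~ftcd.events.EpochWindows`. With
    ``per_epoch_normalize`` the slice is first rescaled to a mean of 100
    using its own mean — the per-epoch guard against slow probe drift.
    """
    from .preprocess import normalize

    a, b = windows.epoch
    n = len(left)
    ca, cb = max(a, 0), min(b, n)
    ls = np.asarray(left, dtype=float)[ca:cb]
    rs = np.asarray(right, dtype=float)[ca:cb]
    if per_epoch_normalize:
        ls = normalize(ls)
        rs = normalize(rs)
    if (ca, cb) != (a, b):
        # short epoch kept by configuration: NaN-pad to the full window so
        # all epochs stay pointwise comparable
        pad_l = np.full(b - a, np.nan)
        pad_r = np.full(b - a, np.nan)
        pad_l[ca - a: cb - a] = ls
        pad_r[ca - a: cb - a] = rs
        ls, rs = pad_l, pad_r
    rel = lambda rng: (rng[0] - a, rng[1] - a)
    baseline = rel(windows.baseline)
    poi = rel(windows.poi)
    if not (a <= windows.baseline[0] and windows.baseline[1] <= b):
        raise ConfigError("baseline window outside the epoch window")
    m = int(round(windows.marker_time * sample_rate))
    return Epoch(
        left=baseline_correct(ls, baseline),
        right=baseline_correct(rs, baseline),
        offset=a - m,
        baseline=baseline,
        poi=poi,
        sample_rate=sample_rate,
        marker_time=windows.marker_time,
        status="accepted",
        reasons=[],
    )


def average_epochs(epochs: list[Epoch]) -> AveragedSignals:
    """Pointwise mean of accepted epochs, with per-sample standard errors.

    SE is the across-epoch sample SD (ddof=1) divided by sqrt(n); for a
    single epoch the SE is reported as 0.
    """
    acc = [e for e in epochs if e.accepted]
    if not acc:
        raise NoDataError("zero accepted epochs: nothing to average")
    lengths = {len(e.left) for e in acc}
    if len(lengths) != 1:
        raise ConfigError(f"epochs have unequal lengths {sorted(lengths)}")
    L = np.stack([e.left for e in acc])
    R = np.stack([e.right for e in acc])
    n = L.shape[0]
    # short epochs included by configuration carry NaN padding at the
    # record edges; averages there use whichever epochs have data
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if n > 1:
            counts = np.maximum((~np.isnan(L)).sum(axis=0), 1)
            se = lambda M: np.nanstd(M, axis=0, ddof=1) / np.sqrt(counts)
            se_l, se_r, se_d = se(L), se(R), se(L - R)
        else:
            se_l = se_r = se_d = np.zeros(L.shape[1])
        left = np.nanmean(L, axis=0)
        right = np.nanmean(R, axis=0)
    return AveragedSignals(
        time=acc[0].time,
        left=left,
        right=right,
        difference=left - right,
        lr_average=(left + right) / 2.0,
        se_left=se_l,
        se_right=se_r,
        se_difference=se_d,
        n_epochs=n,
    )


def _locate_peak(
    signal: np.ndarray, window: tuple[int, int], peak_mode: str
) -> int:
    a, b = window
    seg = signal[a:b]
    if seg.size == 0:
        raise ConfigError(f"empty search window ({a}, {b})")
    if peak_mode == "abs":
        return a + int(np.argmax(np.abs(seg)))
    if peak_mode == "max":
        return a + int(np.argmax(seg))
    if peak_mode == "min":
        return a + int(np.argmin(seg))
    raise ConfigError(f"unknown peak_mode {peak_mode!r}")


def compute_li(
    difference: np.ndarray,
    poi: tuple[int, int],
    activation_window: float,
    sample_rate: float,
    offset: int = 0,
    li_mode: str = "mean",
    peak_mode: str = "abs",
) -> tuple[float, float, int]:
    """LI and peak latency from a (usually averaged) difference signal.

    The peak of the difference is located within the POI (see module notes
    for peak modes; ties break to the earliest sample), and the LI is the
    mean (or sum) of the difference over the ``activation_window`` seconds
    centred on the peak. An activation window that would extend past the
    epoch bounds is a configuration error, never silently truncated.

    Returns ``(li, peak_latency_s, peak_index)`` with the latency in
    seconds relative to the lock marker.
    """
    d = np.asarray(difference, dtype=float)
    a, b = poi
    if not 0 <= a < b <= d.size:
        raise ConfigError(f"POI sample range ({a}, {b}) outside the epoch")
    peak = _locate_peak(d, poi, peak_mode)
    w = int(round(activation_window * sample_rate))
    if w < 1:
        raise ConfigError("activation window shorter than one sample")
    start = peak - w // 2
    end = start + w
    if start < 0 or end > d.size:
        raise ConfigError(
            "activation window extends past the epoch bounds "
            f"(samples [{start}, {end}) of {d.size})"
        )
    seg = d[start:end]
    li = float(seg.mean()) if li_mode == "mean" else float(seg.sum())
    if li_mode not in ("mean", "sum"):
        raise ConfigError(f"unknown li_mode {li_mode!r}")
    latency = (offset + peak) / float(sample_rate)
    return li, latency, peak


def per_epoch_li(
    epochs: list[Epoch],
    activation_window: float,
    li_mode: str = "mean",
    peak_mode: str = "abs",
) -> np.ndarray:
    """LI of each accepted epoch, peak located on that epoch's own
    difference signal."""
    acc = [e for e in epochs if e.accepted]
    if not acc:
        raise NoDataError("zero accepted epochs")
    return np.array(
        [
            compute_li(
                e.difference, e.poi, activation_window, e.sample_rate,
                offset=e.offset, li_mode=li_mode, peak_mode=peak_mode,
            )[0]
            for e in acc
        ]
    )


def summary_stat(signal: np.ndarray, window: tuple[int, int], stat: str):
    """One of the nine descriptive statistics over a sample window.

    Selectors: mean, sd, sem, ci95, min, max, rms, median, iqr. ``ci95``
    returns a (lo, hi) tuple (mean ± t-critical × SEM, Student t with
    n − 1 df); every other selector returns a float. Windows may be fixed
    (e.g. the baseline) or produced by a peak search — the caller supplies
    sample indices either way.
    """
    a, b = window
    x = np.asarray(signal, dtype=float)[a:b]
    if x.size == 0:
        raise ConfigError(f"empty window ({a}, {b})")
    if stat == "mean":
        return float(x.mean())
    if stat == "sd":
        return float(x.std(ddof=1)) if x.size > 1 else 0.0
    if stat == "sem":
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    if stat == "ci95":
        m = float(x.mean())
        if x.size < 2:
            return (m, m)
        half = stats.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
        return (m - float(half), m + float(half))
    if stat == "min":
        return float(x.min())
    if stat == "max":
        return float(x.max())
    if stat == "rms":
        return float(np.sqrt(np.mean(x**2)))
    if stat == "median":
        return float(np.median(x))
    if stat == "iqr":
        q1, q3 = np.percentile(x, [25, 75])
        return float(q3 - q1)
    raise ConfigError(f"unknown summary statistic {stat!r}")


def infer(values, test: str = "t_one", paired_with=None) -> InferenceResult:
    """Inferential test on per-epoch LIs (vs 0) or paired window means.

    ``test`` selects: ``t_one`` / ``wilcoxon_one`` (single-sample against
    0 on ``values``) or ``t_paired`` / ``wilcoxon_paired`` (``values`` vs
    ``paired_with``, e.g. per-epoch left vs right POI means). The effect
    size is Cohen's d of the tested (difference) values, d = mean/SD.

    Degenerate input (zero SD) is reported as such: identical nonzero
    values give statistic ±inf with the p → 0 convention; an all-zero
    difference gives statistic 0, p = 1.
    """
    x = np.asarray(values, dtype=float)
    if test in ("t_paired", "wilcoxon_paired"):
        if paired_with is None:
            raise ConfigError(f"{test} requires a second sample")
        y = np.asarray(paired_with, dtype=float)
        if y.shape != x.shape:
            raise ConfigError("paired samples must have equal length")
        diffs = x - y
    else:
        diffs = x
    n = diffs.size
    if n < 2:
        raise InsufficientDataError(f"{test} requires n >= 2, got {n}")

    sd = diffs.std(ddof=1)
    mean = diffs.mean()
    if sd == 0.0:
        if mean == 0.0:
            return InferenceResult(test, 0.0, 1.0, 0.0, n, degenerate=True)
        s = float(np.sign(mean)) * float("inf")
        return InferenceResult(test, s, 0.0, float("nan"), n, degenerate=True)

    d = float(mean / sd)
    if test == "t_one":
        res = stats.ttest_1samp(diffs, 0.0)
    elif test == "t_paired":
        res = stats.ttest_rel(x, y)
    elif test in ("wilcoxon_one", "wilcoxon_paired"):
        nz = diffs[diffs != 0]
        if nz.size == 0:
            return InferenceResult(test, 0.0, 1.0, 0.0, n, degenerate=True)
        res = stats.wilcoxon(nz)
    else:
        raise ConfigError(f"unknown test {test!r}")
    return InferenceResult(test, float(res.statistic), float(res.pvalue), d, n)


def analyze(
    epochs: list[Epoch],
    spec: TimingSpec,
    li_mode: str = "mean",
    peak_mode: str = "abs",
    tests: tuple[str, ...] = ("t_one", "wilcoxon_one"),
) -> LateralityResult:
    """Full laterality summary from a set of baseline-corrected epochs.

    Averages the accepted epochs, computes the LI on the averaged
    difference, per-epoch LIs (each with its own peak search), their
    dispersion, the 95% CI (centred on the averaged-signal LI, using the
    per-epoch SE and a Student-t critical value), Cohen's d
    (mean/SD of the per-epoch LIs), the requested inferential tests, and
    descriptive peak statistics of the averaged signals.
    """
    avg = average_epochs(epochs)
    acc = [e for e in epochs if e.accepted]
    sample_rate = acc[0].sample_rate
    poi = acc[0].poi
    offset = acc[0].offset
    li, latency, peak = compute_li(
        avg.difference, poi, spec.activation_window, sample_rate,
        offset=offset, li_mode=li_mode, peak_mode=peak_mode,
    )
    e_li = per_epoch_li(epochs, spec.activation_window, li_mode, peak_mode)
    n = e_li.size
    sd = float(e_li.std(ddof=1)) if n > 1 else 0.0
    se = sd / np.sqrt(n) if n > 1 else 0.0
    if n > 1 and se > 0:
        tcrit = float(stats.t.ppf(0.975, n - 1))
        ci = (li - tcrit * se, li + tcrit * se)
    else:
        ci = (li, li)
    d = float(e_li.mean() / sd) if sd > 0 else float("nan")

    test_results: dict[str, InferenceResult] = {}
    for t in tests:
        if n < 2:
            continue
        if t.endswith("_paired"):
            lm = np.array([e.left[slice(*e.poi)].mean() for e in acc])
            rm = np.array([e.right[slice(*e.poi)].mean() for e in acc])
            test_results[t] = infer(lm, test=t, paired_with=rm)
        else:
            test_results[t] = infer(e_li, test=t)

    # peak of the hemisphere-average response, e.g. where the overall
    # haemodynamic response is greatest within the POI
    lr_peak = _locate_peak(avg.lr_average, poi, "max")
    peak_stats = {
        "difference_peak": float(avg.difference[peak]),
        "lr_average_peak": float(avg.lr_average[lr_peak]),
        "lr_average_peak_latency": (offset + lr_peak) / sample_rate,
        "left_poi_mean": summary_stat(avg.left, poi, "mean"),
        "right_poi_mean": summary_stat(avg.right, poi, "mean"),
    }
    return LateralityResult(
        li=li,
        peak_latency=latency,
        n_epochs=n,
        per_epoch_li=e_li,
        li_sd=sd,
        li_se=float(se),
        ci95=ci,
        cohens_d=d,
        average=avg,
        tests=test_results,
        peak_stats=peak_stats,
        li_mode=li_mode,
        peak_mode=peak_mode,
    )
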