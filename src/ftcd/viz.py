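"""Diagnostic plots: raw data, matched (normalized + markers), epoch average.

Rendering is a pure side effect: nothing passed in is mutated. Alongside
each average plot the plotted series can be written via
:func:`ftcd.io.write_graph_data`, giving a format-neutral record of the
figure contents.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np

from .errors import ConfigError
from .events import EpochIndex, TimingSpec
from .io import VelocityRecording
from .laterality import LateralityResult
from .screening import ScreeningConfig

__all__ = ["plot_raw", "plot_matched", "plot_average", "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = ("png", "jpeg", "jpg", "tiff", "bmp", "pdf", "svg")


def _check(path, fmt: str | None) -> tuple[Path, str]:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".") or "png").lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ConfigError(
            f"unknown image format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    if path.suffix.lstrip(".").lower() != fmt:
        path = path.with_suffix("." + fmt)
    return path, fmt


def _save(fig, path: Path, fmt: str) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="jpeg" if fmt == "jpg" else fmt, dpi=110)
    plt.close(fig)
    return path


def plot_raw(rec: VelocityRecording, path, fmt: str | None = None) -> Path:
    """Raw left/right velocity and event-marker channels against time."""
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    path, fmt = _check(path, fmt)
    fig, ax = plt.subplots(figsize=(10, 4))
    t = rec.time
    ax.plot(t, rec.left, lw=0.5, label="left", color="tab:blue")
    ax.plot(t, rec.right, lw=0.5, label="right", color="tab:red")
    for i, ev in enumerate(rec.event_channels):
        ax.plot(t, ev, lw=0.6, label=f"event {i + 1}", color="tab:green", alpha=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("velocity (arb. units)")
    ax.set_title(f"raw data: {rec.source_id}")
    ax.legend(loc="upper right", fontsize=8)
    return _save(fig, path, fmt)


def plot_matched(
    rec: VelocityRecording,
    index: EpochIndex,
    spec: TimingSpec,
    screening: ScreeningConfig,
    path,
    fmt: str | None = None,
) -> Path:
    """Normalized channels with epoch/baseline shading, accepted vs
    spurious markers, and the activation rejection range."""
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    path, fmt = _check(path, fmt)
    fig, ax = plt.subplots(figsize=(10, 4))
    t = rec.time
    ax.plot(t, rec.left, lw=0.5, label="left (norm.)", color="tab:blue")
    ax.plot(t, rec.right, lw=0.5, label="right (norm.)", color="tab:red")
    lo, hi = screening.accept_range
    ax.axhline(lo, color="k", ls="--", lw=0.8, label="rejection range")
    ax.axhline(hi, color="k", ls="--", lw=0.8)
    e_lo, e_hi = spec.epoch_window
    b_lo, b_hi = spec.baseline_window
    for k, tm in enumerate(index.accepted):
        ax.axvspan(tm + e_lo, tm + e_hi, color="tab:green", alpha=0.08)
        ax.axvspan(tm + b_lo, tm + b_hi, color="tab:gray", alpha=0.18)
        ax.axvline(tm, color="tab:green", lw=0.9,
                   label="accepted marker" if k == 0 else None)
    for k, (tm, _) in enumerate(index.rejected):
        ax.axvline(tm, color="tab:orange", ls=":", lw=0.9,
                   label="spurious marker" if k == 0 else None)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("% of mean velocity")
    ax.set_title(f"matched data: {rec.source_id}")
    ax.legend(loc="upper right", fontsize=8)
    return _save(fig, path, fmt)


def plot_average(
    result: LateralityResult,
    spec: TimingSpec,
    path,
    fmt: str | None = None,
    title: str = "averaged epochs",
) -> Path:
    """Two panels: baseline-corrected left/right averages, and the
    left−right difference with the POI, peak, activation window and the
    LI ± CI annotated."""
    avg = result.average
    if avg.n_epochs < 1:
        raise ValueError("no accepted epochs to plot")
    path, fmt = _check(path, fmt)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    t = avg.time

    for ax in (ax1, ax2):
        ax.axvspan(*spec.baseline_window, color="tab:gray", alpha=0.18)
        ax.axvspan(*spec.poi_window, color="tab:green", alpha=0.10)
        ax.axhline(0, color="k", lw=0.6)
        ax.axvline(result.peak_latency, color="tab:purple", lw=0.9, ls="--")
        w = spec.activation_window / 2.0
        ax.axvspan(result.peak_latency - w, result.peak_latency + w,
                   color="tab:purple", alpha=0.15)

    ax1.plot(t, avg.left, color="tab:blue", label="left")
    ax1.fill_between(t, avg.left - avg.se_left, avg.left + avg.se_left,
                     color="tab:blue", alpha=0.2)
    ax1.plot(t, avg.right, color="tab:red", label="right")
    ax1.fill_between(t, avg.right - avg.se_right, avg.right + avg.se_right,
                     color="tab:red", alpha=0.2)
    ax1.set_ylabel("% change from baseline")
    ax1.legend(loc="upper left", fontsize=8)
    ax1.set_title(title)

    ax2.plot(t, avg.difference, color="tab:purple", label="left − right")
    ax2.fill_between(
        t,
        avg.difference - avg.se_difference,
        avg.difference + avg.se_difference,
        color="tab:purple",
        alpha=0.2,
    )
    lo, hi = result.ci95
    ax2.set_xlabel("time relative to marker (s)")
    ax2.set_ylabel("difference (%)")
    ax2.annotate(
        f"LI = {result.li:.2f}  (SE {result.li_se:.2f}, "
        f"95% CI [{lo:.2f}, {hi:.2f}], n = {result.n_epochs})\n"
        f"peak at {result.peak_latency:.2f} s",
        xy=(0.02, 0.95), xycoords="axes fraction", va="top", fontsize=9,
    )
    return _save(fig, path, fmt)
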