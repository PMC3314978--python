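"""Batch driver: config -> io -> preprocess -> events -> screening ->
laterality -> reliability -> summaries -> viz.

Every input file is processed independently; a failure is logged and the
file skipped, never fatal to the batch. A batch run over files
[f1, f2, ...] produces exactly the same rows as running each file alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import viz
from .config import EventConfig, RunConfig
from .errors import FtcdError
from .events import EpochIndex, detect_markers, resolve_windows, select_epochs
from .laterality import Epoch, LateralityResult, analyze, extract_epoch
from .preprocess import (
    detect_heart_cycles,
    downsample,
    integrate_heart_cycles,
    normalize,
    trim_to_epochs,
)
from .reliability import complete_case_matrix, cronbach_alpha, split_half
from .screening import (
    QualityReport,
    dropout_fraction,
    goodness_of_recording,
    screen_range,
    screen_separation,
)

__all__ = ["FileResult", "process_recording", "run_single", "run_batch"]

log = logging.getLogger("ftcd")


@dataclass
class FileResult:
    """Everything the pipeline produced for one file x event definition."""

    file: str
    event: str
    index: EpochIndex
    epochs: list[Epoch]
    result: LateralityResult | None
    quality: QualityReport
    reliability: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def accepted_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.accepted]


def _derive_seed(seed: int, file_id: str) -> int:
    """Stable per-file RNG seed below 2**31 for the random half-split."""
    h = hashlib.sha256(f"{seed}:{file_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def process_recording(
    rec: fio.VelocityRecording,
    cfg: RunConfig,
    event: EventConfig | None = None,
) -> FileResult:
    """Run the full pipeline on one loaded recording for one event spec.

    Order of operations: downsample -> marker detection/selection ->
    (optional) trim -> normalization (configured scope) -> heart-cycle
    integration -> epoch extraction with baseline correction -> screening
    -> laterality statistics -> split-half reliability.
    """
    event = event or cfg.events[0]
    spec = event.timing
    warnings_log: list[str] = []

    proc = cfg.processing
    if abs(rec.sample_rate - proc.target_rate) > 1e-9:
        rec = downsample(rec, proc.target_rate)
    rate = rec.sample_rate

    if not rec.event_channels:
        raise FtcdError(f"{rec.source_id}: no event channel present")
    if not 1 <= event.channel <= len(rec.event_channels):
        raise FtcdError(
            f"{rec.source_id}: event channel {event.channel} not in file "
            f"({len(rec.event_channels)} available)"
        )
    marker_times = detect_markers(
        rec.event_channels[event.channel - 1], spec.marker_height, rate
    )
    index = select_epochs(marker_times, spec.n_epochs, spec.min_separation)
    warnings_log.extend(index.warnings)

    if cfg.trim:
        rec, new_times = trim_to_epochs(rec, spec.epoch_window, index.accepted)
        index = EpochIndex(
            accepted=new_times, rejected=[], warnings=index.warnings
        )

    left, right = rec.left, rec.right
    if proc.normalization_scope in ("whole-record", "trimmed"):
        left, right = normalize(left), normalize(right)
    per_epoch_norm = proc.normalization_scope == "per-epoch"

    if proc.heart_cycle_integration:
        boundaries = detect_heart_cycles(
            left, rate, proc.min_cycle_s, proc.prominence
        )
        if boundaries.size:
            # boundaries from the left channel applied to both keeps the
            # channels sample-aligned (shared cardiac rhythm)
            left = integrate_heart_cycles(left, boundaries)
            right = integrate_heart_cycles(right, boundaries)
        else:
            warnings_log.append("heart-cycle integration skipped: no periodicity")

    windows = resolve_windows(index, spec, rate, rec.n_samples)
    epochs: list[Epoch] = []
    scr = cfg.screening
    manual = set(scr.manual_exclusions.get(rec.source_id, []))
    quality = QualityReport(
        dropout_left=dropout_fraction(rec.left, scr.dropout_value),
        dropout_right=dropout_fraction(rec.right, scr.dropout_value),
    )
    n_rec = rec.n_samples
    for i, w in enumerate(windows):
        clipped = (max(w.epoch[0], 0), min(w.epoch[1], n_rec))
        core_ok = (
            w.baseline[0] >= clipped[0]
            and w.baseline[1] <= clipped[1]
            and w.poi[0] >= clipped[0]
            and w.poi[1] <= clipped[1]
        )
        if w.short and not (cfg.include_short_epochs and core_ok):
            reasons = ["short"]
            epochs.append(
                Epoch(
                    left=np.zeros(0), right=np.zeros(0), offset=0,
                    baseline=(0, 0), poi=(0, 0), sample_rate=rate,
                    marker_time=w.marker_time, status="rejected",
                    reasons=reasons,
                )
            )
            quality.epoch_reasons[i] = reasons
            continue
        ls = left[clipped[0]: clipped[1]]
        rs = right[clipped[0]: clipped[1]]
        if per_epoch_norm:
            ls, rs = normalize(ls), normalize(rs)
        reasons: list[str] = []
        ok, why = screen_range(ls, rs, scr.accept_range)
        if not ok:
            reasons.append(why)
        ok, why = screen_separation(ls, rs, scr.max_separation)
        if not ok:
            reasons.append(why)
        if i in manual:
            reasons.append("manual")
        ep = extract_epoch(left, right, w, rate, per_epoch_normalize=per_epoch_norm)
        if reasons:
            ep.status = "rejected"
            ep.reasons = reasons
        epochs.append(ep)
        quality.epoch_reasons[i] = reasons

    accepted = [e for e in epochs if e.accepted]
    gl, gr, excl = goodness_of_recording(
        [(e.left[slice(*e.baseline)], e.right[slice(*e.baseline)]) for e in accepted],
        scr.gor_limit,
    )
    quality.gor_left, quality.gor_right, quality.file_excluded = gl, gr, excl

    result: LateralityResult | None = None
    rel: dict[str, float] = {}
    if accepted:
        result = analyze(
            epochs, spec, li_mode=cfg.li_mode, peak_mode=cfg.peak_mode,
            tests=cfg.tests,
        )
        if len(accepted) >= 2:
            a, b, _, _ = split_half(
                epochs, spec, mode="odd-even",
                li_mode=cfg.li_mode, peak_mode=cfg.peak_mode,
            )
            rel["li_odd"], rel["li_even"] = a, b
            rseed = _derive_seed(cfg.seed, rec.source_id)
            ra, rb, _, _ = split_half(
                epochs, spec, mode="random", seed=rseed,
                li_mode=cfg.li_mode, peak_mode=cfg.peak_mode,
            )
            rel["li_rand_a"], rel["li_rand_b"], rel["rand_seed"] = ra, rb, rseed
    else:
        warnings_log.append("no accepted epochs")

    return FileResult(
        file=rec.source_id,
        event=event.name,
        index=index,
        epochs=epochs,
        result=result,
        quality=quality,
        reliability=rel,
        warnings=warnings_log,
    )


def _result_row(fr: FileResult, group: str) -> dict:
    r = fr.result
    row = {
        "file": fr.file,
        "event": fr.event,
        "group": group,
        "n_markers_accepted": fr.index.n_accepted,
        "n_epochs_accepted": len(fr.accepted_epochs),
        "n_epochs_rejected": len(fr.epochs) - len(fr.accepted_epochs),
        "dropout_left": fr.quality.dropout_left,
        "dropout_right": fr.quality.dropout_right,
        "gor_left": fr.quality.gor_left,
        "gor_right": fr.quality.gor_right,
        "gor_excluded": fr.quality.file_excluded,
    }
    if r is not None:
        row.update(
            li=r.li,
            peak_latency_s=r.peak_latency,
            li_sd=r.li_sd,
            li_se=r.li_se,
            ci95_lo=r.ci95[0],
            ci95_hi=r.ci95[1],
            cohens_d=r.cohens_d,
        )
        for name, t in r.tests.items():
            row[f"{name}_stat"] = t.statistic
            row[f"{name}_p"] = t.p
        row.update({f"peak_{k}": v for k, v in r.peak_stats.items()})
        row.update(fr.reliability)
    return row


def _epoch_rows(fr: FileResult) -> list[dict]:
    rows = []
    acc_iter = iter(fr.result.per_epoch_li if fr.result is not None else [])
    for i, e in enumerate(fr.epochs):
        rows.append(
            {
                "file": fr.file,
                "event": fr.event,
                "epoch": i,
                "marker_time_s": e.marker_time,
                "status": e.status,
                "reasons": "|".join(e.reasons),
                "li": next(acc_iter) if e.accepted else float("nan"),
            }
        )
    return rows


def run_single(path, cfg: RunConfig) -> list[FileResult]:
    """Process one file; one result per configured event definition."""
    rec = fio.read_recording(path, cfg.channel_map, cfg.sample_rate)
    return [process_recording(rec, cfg, ev) for ev in cfg.events]


def run_batch(
    paths: list,
    cfg: RunConfig,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[FileResult], dict[str, str]]:
    """Process many files; collate summary, per-epoch and reliability tables.

    Per-file failures are logged and skipped. When ``out_dir`` is given the
    tab-delimited tables, per-file graph data and any configured plots are
    written there. Returns (summary table, per-epoch table, results,
    failures by file).
    """
    results: list[FileResult] = []
    failures: dict[str, str] = {}
    for p in paths:
        try:
            results.extend(run_single(p, cfg))
        except (FtcdError, OSError, ValueError) as exc:
            log.warning("skipping %s: %s", p, exc)
            failures[str(p)] = str(exc)

    rows = [_result_row(fr, cfg.groups.get(fr.file, "ungrouped")) for fr in results]
    summary = pd.DataFrame(rows)
    epoch_table = pd.DataFrame(
        [row for fr in results for row in _epoch_rows(fr)]
    )

    if out_dir is not None and len(summary):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fio.write_results(summary, out_dir / "summary.tsv")
        if len(epoch_table):
            fio.write_results(epoch_table, out_dir / "epoch_li.tsv")
        _write_alpha(results, out_dir)
        for fr in results:
            if fr.result is None:
                continue
            avg = fr.result.average
            stem = Path(fr.file).stem
            fio.write_graph_data(
                {
                    "time": avg.time,
                    "left": avg.left,
                    "right": avg.right,
                    "difference": avg.difference,
                    "lr_average": avg.lr_average,
                },
                out_dir / f"{stem}_{fr.event}_graph.tsv",
            )
            if "average" in cfg.plots:
                viz.plot_average(
                    fr.result, _event_timing(cfg, fr.event),
                    out_dir / f"{stem}_{fr.event}_average.{cfg.plot_format}",
                    cfg.plot_format, title=f"{fr.file} [{fr.event}]",
                )
    return summary, epoch_table, results, failures


def _event_timing(cfg: RunConfig, name: str):
    return next(e.timing for e in cfg.events if e.name == name)


def _write_alpha(results: list[FileResult], out_dir: Path) -> None:
    """Group-level Cronbach's alpha over the complete-case LI matrix."""
    by_event: dict[str, list[np.ndarray]] = {}
    for fr in results:
        if fr.result is not None and fr.result.per_epoch_li.size >= 2:
            by_event.setdefault(fr.event, []).append(fr.result.per_epoch_li)
    rows = []
    for event, lis in by_event.items():
        if len(lis) < 2:
            continue
        matrix, k = complete_case_matrix(lis)
        rows.append(
            {
                "event": event,
                "n_files": len(lis),
                "k_epochs": k,
                "cronbach_alpha": cronbach_alpha(matrix),
            }
        )
    if rows:
        fio.write_results(pd.DataFrame(rows), out_dir / "reliability.tsv")
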