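"""Group, behavioural (epoch-subset) and multi-session summaries."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, NoDataError
from .events import TimingSpec
from .laterality import Epoch, LateralityResult, analyze

__all__ = ["group_summary", "behavioural_summary", "session_summary"]


def group_summary(
    results: dict[str, LateralityResult],
    groups: dict[str, str] | None = None,
) -> tuple[dict[str, dict[str, np.ndarray]], pd.DataFrame]:
    """Per-group averages of the per-file averaged signals.

    ``groups`` maps file id to a group label; unlabelled files fall into
    ``"ungrouped"``. Returns the per-group averaged left/right/difference
    signals (unweighted mean across files) and a table of group sizes; the
    group label also travels into the batch result table.
    """
    groups = groups or {}
    by_label: dict[str, list[str]] = {}
    for fid in results:
        by_label.setdefault(groups.get(fid, "ungrouped"), []).append(fid)

    averages: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for label, fids in sorted(by_label.items()):
        stacks = {
            name: np.mean(
                [getattr(results[f].average, name) for f in fids], axis=0
            )
            for name in ("left", "right", "difference", "lr_average")
        }
        stacks["time"] = results[fids[0]].average.time
        averages[label] = stacks
        rows.append(
            {
                "group": label,
                "n_files": len(fids),
                "mean_li": float(np.mean([results[f].li for f in fids])),
            }
        )
    return averages, pd.DataFrame(rows)


def behavioural_summary(
    epochs: list[Epoch],
    selections: dict[str, list[int]],
    spec: TimingSpec,
    **analyze_kw,
) -> dict[str, LateralityResult]:
    """Laterality results for named epoch subsets within one file.

    ``selections`` maps a label (e.g. an experimental condition) to
    accepted-epoch indices (0-based, in accepted order). Epochs rejected
    by screening stay excluded: a selection naming a rejected or absent
    epoch triggers a warning and that epoch is skipped; a selection with
    no usable epochs raises for that selection only.
    """
    acc = [e for e in epochs if e.accepted]
    out: dict[str, LateralityResult] = {}
    for label, idx in selections.items():
        usable = []
        for i in idx:
            if 0 <= i < len(acc):
                usable.append(acc[i])
            else:
                warnings.warn(
                    f"selection {label!r}: epoch {i} is rejected or absent; skipped"
                )
        if not usable:
            raise NoDataError(f"selection {label!r} has no usable epochs")
        out[label] = analyze(usable, spec, **analyze_kw)
    return out


def session_summary(
    sessions: dict[str, list[Epoch]],
    spec: TimingSpec,
    **analyze_kw,
) -> tuple[dict[str, LateralityResult], LateralityResult]:
    """Per-session results plus a combined result from pooled epochs.

    All sessions must share the epoch timing (equal epoch sample counts);
    the combined LI is recomputed from the pooled accepted epochs — not
    averaged from per-session LIs — so the peak search runs on the pooled
    average.
    """
    if len(sessions) < 2:
        raise ConfigError("session summary needs >= 2 sessions")
    lengths = {
        len(e.left) for eps in sessions.values() for e in eps if e.accepted
    }
    if len(lengths) > 1:
        raise ConfigError(
            f"sessions have mismatched epoch windows (lengths {sorted(lengths)})"
        )
    per_session = {
        name: analyze(eps, spec, **analyze_kw) for name, eps in sessions.items()
    }
    pooled = [e for eps in sessions.values() for e in eps]
    combined = analyze(pooled, spec, **analyze_kw)
    return per_session, combined
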