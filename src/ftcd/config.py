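"""Declarative run configuration (YAML) and its defaults.

One file covers everything the processing run needs: data handling
(channel roles, downsampling, normalization scope, trimming, heart-cycle
integration), screening thresholds, one or more named event definitions
with their timings, optional groups / manual exclusions / behavioural
selections, and output options. Defaults mirror standard practice for the
word-generation protocol: velocity channels 1/2, 25 Hz analysis rate,
2 s activation window, 50–150 acceptance range, GOR limit 2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .events import TimingSpec
from .preprocess import ProcessingConfig
from .screening import ScreeningConfig

__all__ = ["EventConfig", "RunConfig", "load_config"]


@dataclass
class EventConfig:
    """One named event definition: which marker channel, and its timings."""

    name: str = "event"
    channel: int = 1  # 1-based index into the recording's event channels
    timing: TimingSpec = field(default_factory=TimingSpec)


@dataclass
class RunConfig:
    channel_map: dict = field(
        default_factory=lambda: {"left": 1, "right": 2, "event": 3}
    )
    sample_rate: float | None = None  # fallback when the file has no header
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    trim: bool = False
    include_short_epochs: bool = False
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    events: list[EventConfig] = field(default_factory=lambda: [EventConfig()])
    groups: dict[str, str] = field(default_factory=dict)
    selections: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    li_mode: str = "mean"
    peak_mode: str = "abs"
    tests: tuple[str, ...] = ("t_one", "wilcoxon_one")
    plots: list[str] = field(default_factory=list)
    plot_format: str = "png"
    seed: int = 1


def _timing_from_dict(d: dict) -> TimingSpec:
    kw = {}
    mapping = {
        "epoch_s": "epoch_window",
        "baseline_s": "baseline_window",
        "poi_s": "poi_window",
        "activation_window_s": "activation_window",
        "n_epochs": "n_epochs",
        "min_separation_s": "min_separation",
        "marker_height": "marker_height",
        "baseline_lock": "baseline_lock",
        "poi_lock": "poi_lock",
    }
    for key, attr in mapping.items():
        if key in d:
            v = d[key]
            kw[attr] = tuple(v) if isinstance(v, list) else v
    return TimingSpec(**kw)


def load_config(source) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path or a dict.

    Unknown top-level keys are a schema error (caught before any file is
    processed), so typos fail fast rather than silently using defaults.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source) if source else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")

    known = {
        "data", "screening", "events", "groups", "selections",
        "li_mode", "peak_mode", "tests", "output", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    cfg = RunConfig()
    data = raw.get("data", {}) or {}
    if "channel_map" in data:
        cfg.channel_map = dict(data["channel_map"])
    if "sample_rate" in data:
        cfg.sample_rate = float(data["sample_rate"])
    proc_kw = {}
    if "target_rate_hz" in data:
        proc_kw["target_rate"] = float(data["target_rate_hz"])
    if "normalization_scope" in data:
        proc_kw["normalization_scope"] = data["normalization_scope"]
    hc = data.get("heart_cycle", {}) or {}
    if "enabled" in hc:
        proc_kw["heart_cycle_integration"] = bool(hc["enabled"])
    if "min_cycle_s" in hc:
        proc_kw["min_cycle_s"] = float(hc["min_cycle_s"])
    if "prominence" in hc:
        proc_kw["prominence"] = float(hc["prominence"])
    try:
        cfg.processing = ProcessingConfig(**proc_kw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.trim = bool(data.get("trim", cfg.trim))
    cfg.include_short_epochs = bool(
        data.get("include_short_epochs", cfg.include_short_epochs)
    )

    scr = raw.get("screening", {}) or {}
    scr_kw = {}
    if "accept_lower" in scr or "accept_upper" in scr:
        scr_kw["accept_range"] = (
            float(scr.get("accept_lower", 50.0)),
            float(scr.get("accept_upper", 150.0)),
        )
    for key in ("max_separation", "gor_limit", "dropout_value"):
        if key in scr:
            scr_kw[key] = float(scr[key])
    if "manual_exclusions" in scr:
        scr_kw["manual_exclusions"] = {
            str(k): [int(i) for i in v]
            for k, v in (scr["manual_exclusions"] or {}).items()
        }
    cfg.screening = ScreeningConfig(**scr_kw)

    if "events" in raw and raw["events"]:
        cfg.events = []
        for i, ev in enumerate(raw["events"]):
            ev = dict(ev)
            cfg.events.append(
                EventConfig(
                    name=str(ev.get("name", f"event{i + 1}")),
                    channel=int(ev.get("channel", 1)),
                    timing=_timing_from_dict(ev),
                )
            )
    names = [e.name for e in cfg.events]
    if len(set(names)) != len(names):
        raise ConfigError(f"event names must be unique, got {names}")

    cfg.groups = {str(k): str(v) for k, v in (raw.get("groups", {}) or {}).items()}
    cfg.selections = {
        str(f): {str(lbl): [int(i) for i in idx] for lbl, idx in sel.items()}
        for f, sel in (raw.get("selections", {}) or {}).items()
    }
    cfg.li_mode = raw.get("li_mode", cfg.li_mode)
    cfg.peak_mode = raw.get("peak_mode", cfg.peak_mode)
    if "tests" in raw:
        cfg.tests = tuple(raw["tests"])
    out = raw.get("output", {}) or {}
    cfg.plots = list(out.get("plots", []))
    cfg.plot_format = str(out.get("plot_format", cfg.plot_format))
    cfg.seed = int(raw.get("seed", cfg.seed))
    return cfg
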