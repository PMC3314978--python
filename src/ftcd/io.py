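"""Reading velocity recordings and writing tab-delimited result tables.

Two input dialects are supported:

* a header + TSV dialect modelled on the text exports of clinical Doppler
  monitoring software: ``key: value`` header lines, a blank line, then
  tab-separated sample rows;
* a generic delimited table (TSV/CSV, with or without a column-name row)
  whose column roles are declared through a ``channel_map``.

All outputs are tab-delimited text with "." decimal separators and Unix
newlines, so they re-import losslessly into R, pandas or a spreadsheet.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, CorruptFileError, FormatError

__all__ = [
    "VelocityRecording",
    "read_recording",
    "list_batch",
    "write_results",
    "write_graph_data",
]

#: default column roles: left and right blood-flow velocity in columns 1 and 2
DEFAULT_CHANNEL_MAP: dict[str, object] = {"left": 1, "right": 2, "event": 3}


@dataclass
class VelocityRecording:
    """Dual-probe blood-flow-velocity recording with event-marker channels.

    Parameters
    ----------
    left, right
        Velocity samples (cm/s or an arbitrary positive scale) for the left
        and right probes. Equal length.
    event_channels
        One or more marker-signal channels, each sample-aligned with the
        velocity channels.
    sample_rate
        Sampling rate in Hz (> 0).
    channel_map
        The column-role declaration the channels were read with.
    source_id
        Identifier of the originating file (or ``"<memory>"``).
    """

    left: np.ndarray
    right: np.ndarray
    event_channels: list[np.ndarray]
    sample_rate: float
    channel_map: dict = field(default_factory=dict)
    source_id: str = "<memory>"

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.event_channels = [np.asarray(e, dtype=float) for e in self.event_channels]
        n = len(self.left)
        if len(self.right) != n or any(len(e) != n for e in self.event_channels):
            raise CorruptFileError(
                f"{self.source_id}: channels have unequal lengths"
            )
        if self.sample_rate <= 0:
            raise ConfigError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def copy(self, **updates) -> "VelocityRecording":
        kw = dict(
            left=self.left.copy(),
            right=self.right.copy(),
            event_channels=[e.copy() for e in self.event_channels],
            sample_rate=self.sample_rate,
            channel_map=dict(self.channel_map),
            source_id=self.source_id,
        )
        kw.update(updates)
        return VelocityRecording(**kw)


def _split_dialect(text: str) -> tuple[dict[str, str], str]:
    """Split a header+TSV file into (header dict, data block)."""
    lines = text.splitlines()
    header: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.strip():
            i += 1
            break
        if ":" not in line:
            raise FormatError(f"malformed header line (no ':'): {line!r}")
        key, _, value = line.partition(":")
        header[key.strip().lower()] = value.strip()
    return header, "\n".join(lines[i:])


def _looks_like_dialect(text: str) -> bool:
    for line in text.splitlines():
        if not line.strip():
            continue
        first = line.split("\t")[0]
        return ":" in first
    return False


def _resolve_column(sel: object, df: pd.DataFrame, role: str) -> np.ndarray:
    """Resolve a 1-based index or column name to a data column."""
    if isinstance(sel, str):
        if sel not in df.columns:
            raise FormatError(f"declared {role} column {sel!r} not found")
        col = df[sel]
    else:
        idx = int(sel) - 1
        if not 0 <= idx < df.shape[1]:
            raise FormatError(
                f"declared {role} column {sel} out of range (file has "
                f"{df.shape[1]} columns)"
            )
        col = df.iloc[:, idx]
    try:
        return col.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise CorruptFileError(f"non-numeric data in {role} column: {exc}") from exc


def read_recording(
    path,
    channel_map: Mapping[str, object] | None = None,
    sample_rate: float | None = None,
) -> VelocityRecording:
    """Read a recording from either supported text dialect.

    ``channel_map`` declares column roles as 1-based column indices or
    column names: ``{"left": 1, "right": 2, "event": 3}``; ``"event"`` may
    be a list for multiple marker channels. Header metadata (``sample_rate``,
    ``columns``) is honoured when present; explicit arguments override a
    missing header, and a ``sample_rate`` argument is required when the file
    carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()

    header: dict[str, str] = {}
    if _looks_like_dialect(text):
        header, data_block = _split_dialect(text)
    else:
        data_block = text

    sep = "\t" if "\t" in data_block.splitlines()[0] else ","
    first_fields = data_block.splitlines()[0].split(sep)
    has_names = not all(_is_number(f) for f in first_fields if f.strip())
    names = None
    if "columns" in header:
        names = header["columns"].replace(",", " ").split()
    from io import StringIO

    try:
        df = pd.read_csv(
            StringIO(data_block),
            sep=sep,
            header=0 if (has_names and names is None) else None,
            names=names,
            dtype=float,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise CorruptFileError(f"{path.name}: {exc}") from exc
    if df.isna().any().any():
        raise CorruptFileError(f"{path.name}: missing values / ragged rows")

    cmap = dict(channel_map) if channel_map else dict(DEFAULT_CHANNEL_MAP)
    for role in ("left", "right"):
        if role not in cmap:
            raise ConfigError(f"channel_map missing required role {role!r}")

    left = _resolve_column(cmap["left"], df, "left")
    right = _resolve_column(cmap["right"], df, "right")
    if (left < 0).any() or (right < 0).any():
        raise FormatError(
            f"{path.name}: negative velocity values on import "
            "(velocity channels are magnitudes)"
        )
    event_sel = cmap.get("event", [])
    if event_sel is None:
        event_sel = []
    if not isinstance(event_sel, (list, tuple)):
        event_sel = [event_sel]
    events = [_resolve_column(s, df, "event") for s in event_sel]

    rate = sample_rate
    if "sample_rate" in header:
        rate = float(header["sample_rate"].split()[0])
    if rate is None:
        raise ConfigError(f"{path.name}: no sample rate in header or arguments")
    if rate <= 0:
        raise ConfigError(f"{path.name}: nonpositive sample rate {rate}")

    if "time" in (c.lower() for c in map(str, df.columns)):
        tcol = next(c for c in df.columns if str(c).lower() == "time")
        t = df[tcol].to_numpy(dtype=float)
        if len(t) > 2 and not np.allclose(np.diff(t), np.diff(t)[0], rtol=1e-6):
            warnings.warn(
                f"{path.name}: non-uniform time stamps ignored; "
                "uniform sampling at the declared rate is assumed"
            )

    return VelocityRecording(
        left=left,
        right=right,
        event_channels=events,
        sample_rate=float(rate),
        channel_map=cmap,
        source_id=path.name,
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def list_batch(directory, pattern: str = "*") -> list[Path]:
    """Deterministic (lexicographically sorted) list of files matching
    ``pattern`` in ``directory``. An empty list is allowed."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    hits = [
        p
        for p in directory.iterdir()
        if p.is_file() and fnmatch.fnmatch(p.name, pattern)
    ]
    return sorted(hits, key=lambda p: p.name)


def write_results(table: pd.DataFrame, path) -> Path:
    """Write a result table as tab-delimited text with one header row.

    Floats are written with Python's shortest round-trip representation so
    re-reading reproduces every value exactly.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("refusing to write a degenerate (empty) table")
    if len(set(table.columns)) != len(table.columns):
        raise ValueError("column names must be unique")
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def write_graph_data(averages: Mapping[str, Sequence[float]], path) -> Path:
    """Write averaged epoch signals for external graphing.

    ``averages`` must provide ``time`` (s, relative to the event marker),
    ``left`` and ``right``; ``difference`` (left − right) and ``lr_average``
    ((left + right)/2) are derived if absent. One row per epoch-window
    sample.
    """
    if "left" not in averages or len(np.atleast_1d(averages["left"])) == 0:
        raise ValueError("no accepted epochs: nothing to write")
    cols = dict(averages)
    left = np.asarray(cols["left"], dtype=float)
    right = np.asarray(cols["right"], dtype=float)
    cols.setdefault("difference", left - right)
    cols.setdefault("lr_average", (left + right) / 2.0)
    order = ["time", "left", "right", "difference", "lr_average"]
    extra = [c for c in cols if c not in order]
    df = pd.DataFrame({c: np.asarray(cols[c], dtype=float) for c in order + extra})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return Path(path)
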