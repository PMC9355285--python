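"""File dialects: raw sensor traces, lick-event CSVs, configs, manifests.

Raw traces are tab-separated with header
``timestamp_iso\tcage_id\tbottle_id\tvalue`` — one row per channel per
frame, ISO-8601 timestamps with millisecond precision, values printed with
3 decimals (the writer/reader round-trip is exact on that representation).
Event files are comma-separated ``timestamp_iso,cage_id,bottle_id``.
Internal time is milliseconds from session start; the session start
timestamp anchors conversion to wall clock.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .detection import LickEvents
from .errors import DataError, FormatError
from .sensor import SensorTrace
from .signals import LickTrain

logger = logging.getLogger("lickometry")

Channel = Tuple[int, str]

RAW_TRACE_HEADER = ["timestamp_iso", "cage_id", "bottle_id", "value"]
EVENTS_HEADER = ["timestamp_iso", "cage_id", "bottle_id"]
GROUND_TRUTH_HEADER = ["cage_id", "bottle_id", "onset_ms", "contact_ms"]

_ISO_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def format_iso_ms(start: dt.datetime, offset_ms: float) -> str:
    # the dialect carries millisecond precision; round rather than truncate
    t = start + dt.timedelta(milliseconds=round(float(offset_ms)))
    return t.strftime(_ISO_FMT)[:-3]  # microseconds -> milliseconds


def parse_iso_ms(text: str) -> dt.datetime:
    try:
        return dt.datetime.fromisoformat(text)
    except ValueError as exc:
        raise FormatError(f"bad ISO timestamp {text!r}") from exc


def write_raw_trace(
    path: Union[str, Path],
    traces: Iterable[SensorTrace],
    session_start: dt.datetime,
) -> None:
    """Write one or more channel traces to the tab-separated raw dialect."""
    rows: List[Tuple[float, str, int, str, float]] = []
    for trace in traces:
        for t, v in zip(trace.times, trace.values):
            rows.append((t, format_iso_ms(session_start, t), trace.cage_id, trace.bottle_id, v))
    rows.sort(key=lambda r: (r[0], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write("\t".join(RAW_TRACE_HEADER) + "\n")
        for _, iso, cage, bottle, value in rows:
            fh.write(f"{iso}\t{cage}\t{bottle}\t{value:.3f}\n")


def read_raw_trace(
    path: Union[str, Path],
) -> Tuple[Dict[Channel, SensorTrace], Optional[dt.datetime]]:
    """Parse a raw trace file into per-channel :class:`SensorTrace` objects.

    Returns ``(traces, session_start)`` where times are converted to ms
    offsets from the earliest timestamp in the file.  Malformed rows raise
    :class:`FormatError` with their line number; non-monotonic timestamps
    within a channel raise :class:`DataError`.
    """
    per_channel: Dict[Channel, List[Tuple[dt.datetime, float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != RAW_TRACE_HEADER:
            raise FormatError(f"{path}: expected header {RAW_TRACE_HEADER}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                ts = parse_iso_ms(parts[0])
                cage = int(parts[1])
                bottle = parts[2]
                value = float(parts[3])
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if bottle not in ("A", "B"):
                raise FormatError(f"{path}:{lineno}: bottle must be A or B")
            per_channel.setdefault((cage, bottle), []).append((ts, value))

    if not per_channel:
        return {}, None
    session_start = min(rows[0][0] for rows in per_channel.values())
    traces: Dict[Channel, SensorTrace] = {}
    for (cage, bottle), rows in per_channel.items():
        times = np.round(
            [(ts - session_start).total_seconds() * 1000.0 for ts, _ in rows]
        )
        if times.size > 1:
            diffs = np.diff(times)
            if np.any(diffs <= 0):
                raise DataError(
                    f"{path}: non-monotonic timestamps in channel ({cage},{bottle})"
                )
            period = float(np.median(diffs))
        else:
            period = 60.0
        values = np.array([v for _, v in rows])
        traces[(cage, bottle)] = SensorTrace(
            cage_id=cage,
            bottle_id=bottle,  # type: ignore[arg-type]
            sample_period=period,
            start_time=float(times[0]),
            values=values,
        )
    return traces, session_start


def write_events(
    path: Union[str, Path],
    events: Mapping[Channel, LickEvents],
    session_start: dt.datetime,
) -> None:
    """Write detected licks as ``timestamp_iso,cage_id,bottle_id`` CSV."""
    rows: List[Tuple[float, int, str]] = []
    for (cage, bottle), ev in events.items():
        rows.extend((t, cage, bottle) for t in ev.timestamps)
    rows.sort()
    with open(path, "w") as fh:
        fh.write(",".join(EVENTS_HEADER) + "\n")
        for t, cage, bottle in rows:
            fh.write(f"{format_iso_ms(session_start, t)},{cage},{bottle}\n")


def read_events(
    path: Union[str, Path],
) -> Tuple[Dict[Channel, LickEvents], Optional[dt.datetime]]:
    """Read an events CSV; out-of-order rows are sorted with a warning."""
    frame = pd.read_csv(path)
    if list(frame.columns) != EVENTS_HEADER:
        raise FormatError(f"{path}: expected header {EVENTS_HEADER}")
    if frame.empty:
        return {}, None
    frame["ts"] = frame["timestamp_iso"].map(parse_iso_ms)
    session_start = frame["ts"].min()
    out: Dict[Channel, LickEvents] = {}
    for (cage, bottle), sub in frame.groupby(["cage_id", "bottle_id"]):
        offsets = np.round(
            [(ts - session_start).total_seconds() * 1000.0 for ts in sub["ts"]]
        )
        if offsets.size > 1 and np.any(np.diff(offsets) < 0):
            logger.warning(
                "events in %s channel (%s,%s) out of order; sorting", path, cage, bottle
            )
            offsets = np.sort(offsets)
        # collapse exact duplicates produced by e.g. duplicated packets
        offsets = np.unique(offsets)
        out[(int(cage), str(bottle))] = LickEvents(int(cage), str(bottle), offsets)  # type: ignore[arg-type]
    return out, session_start


def write_ground_truth(
    path: Union[str, Path], trains: Mapping[Channel, LickTrain]
) -> None:
    """Export ground-truth lick trains as CSV, sorted by onset per channel."""
    with open(path, "w") as fh:
        fh.write(",".join(GROUND_TRUTH_HEADER) + "\n")
        for (cage, bottle), train in sorted(trains.items()):
            for onset, contact in zip(train.onsets, train.contact_durations):
                fh.write(f"{cage},{bottle},{onset:.3f},{contact:.3f}\n")


def read_ground_truth(path: Union[str, Path]) -> Dict[Channel, LickTrain]:
    frame = pd.read_csv(path)
    if list(frame.columns) != GROUND_TRUTH_HEADER:
        raise FormatError(f"{path}: expected header {GROUND_TRUTH_HEADER}")
    out: Dict[Channel, LickTrain] = {}
    for (cage, bottle), sub in frame.groupby(["cage_id", "bottle_id"]):
        sub = sub.sort_values("onset_ms")
        out[(int(cage), str(bottle))] = LickTrain(
            int(cage),
            str(bottle),  # type: ignore[arg-type]
            sub["onset_ms"].to_numpy(float),
            sub["contact_ms"].to_numpy(float),
        )
    return out


def load_config(path: Union[str, Path]) -> Dict[str, object]:
    """Flat key-value configuration (YAML mapping, module-prefixed keys)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    return data


def save_config(path: Union[str, Path], config: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, default_flow_style=False, sort_keys=True)


def write_manifest(
    path: Union[str, Path],
    config: Mapping[str, object],
    seed: int,
) -> None:
    """Echo the effective configuration + seed + version for reproducibility."""
    from . import __version__

    manifest = dict(config)
    manifest["run.seed"] = int(seed)
    manifest["run.lickometry_version"] = __version__
    manifest["run.written_at"] = dt.datetime.now().isoformat(timespec="seconds")
    save_config(path, manifest)
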