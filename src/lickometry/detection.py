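"""Lick detectors: bench prototype polling and wireless multiplexed frames.

Two acquisition schemes are modelled.  The *prototype* detector polls one
channel every 50 ms and counts rising threshold crossings, with a 5 ms
post-count delay against duplicate counts.  The *wireless* detector scans a
16-channel multiplexer once per 60 ms frame (per-channel rate
16.67 samples/s); each channel is read at a fixed offset within the frame.
Wireless counting is either ``edge`` (rising crossings of the sampled
values) or ``latched`` (the multiplexer front-end accumulates pulse events
between reads and each read drains the counter — the scheme that lets a
16.67 Hz scan register 10 Hz pulses without aliasing losses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, ParameterError
from .sensor import BaselineStats, ContinuousSignal, SensorTrace
from .signals import CHANNEL_ORDER, Bottle

Channel = Tuple[int, str]

#: timestamp spacer for multiple latched counts drained at one read instant
_LATCH_EPS_MS = 1e-3


@dataclass(frozen=True)
class DetectorConfig:
    """Configuration shared by both detectors.

    ``threshold`` is in sensor a.u.; when derived from baseline statistics
    it is ``mean + threshold_k * sd``.  ``miss_prob`` is the residual
    per-event miss probability of the latched front-end (default 5e-4,
    reproducing a reading error on the order of 0.05 %).
    """

    mode: Literal["prototype", "wireless"] = "wireless"
    poll_period: float = 50.0    # ms, prototype
    refractory: float = 5.0      # ms, prototype post-count delay
    frame_period: float = 60.0   # ms, wireless
    threshold: Optional[float] = None
    threshold_k: float = 5.0
    miss_prob: float = 5e-4

    def __post_init__(self) -> None:
        if self.poll_period <= 0:
            raise ParameterError("poll_period must be > 0")
        if self.refractory < 0:
            raise ParameterError("refractory must be >= 0")
        if self.frame_period <= 0:
            raise ParameterError("frame_period must be > 0")
        if not 0 <= self.miss_prob < 1:
            raise ParameterError("miss_prob must be in [0, 1)")


@dataclass(frozen=True)
class LickEvents:
    """Detected lick timestamps (ms) for one channel, strictly increasing."""

    cage_id: int
    bottle_id: Bottle
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.size:
            if ts[0] < 0:
                raise ParameterError("timestamps must be >= 0")
            if np.any(np.diff(ts) <= 0):
                raise ParameterError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass(frozen=True)
class FrameSequence:
    """Multiplexer output: one row of 16 channel reads per frame.

    ``values[f, c]`` is the sampled sensor value of channel ``channels[c]``
    at read instant ``read_times[f, c] = frame_times[f] + scan_offsets[c]``.
    ``latch_counts[f, c]`` is the number of signal onsets latched between
    the previous read and this one (used by latched-mode detection).
    """

    frame_times: np.ndarray          # (n_frames,) frame start instants, ms
    values: np.ndarray               # (n_frames, 16)
    latch_counts: np.ndarray         # (n_frames, 16) int
    scan_offsets: np.ndarray         # (16,) ms within frame
    frame_period: float
    channels: Tuple[Channel, ...] = tuple(CHANNEL_ORDER)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ConfigurationError("values must be (n_frames, n_channels)")
        if self.frame_times.size > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ConfigurationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def per_channel_rate(self) -> float:
        """Effective per-channel sampling rate, samples/s."""
        return 1000.0 / self.frame_period

    def read_times(self, channel_index: int) -> np.ndarray:
        return self.frame_times + self.scan_offsets[channel_index]


def estimate_threshold(baseline: BaselineStats, k: float = 5.0) -> float:
    """Lick threshold from mouse-free baseline statistics: mean + k*sd."""
    if k <= 0:
        raise ParameterError("k must be > 0")
    if baseline.sd < 0:
        raise ParameterError("baseline sd must be >= 0")
    return float(baseline.mean + k * baseline.sd)


def detect_prototype(
    signal: ContinuousSignal,
    config: DetectorConfig,
    duration: Optional[float] = None,
    phase_offset: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> LickEvents:
    """Poll a single channel at ``poll_period`` and count rising crossings.

    A lick is counted when a poll reads above threshold and the previous
    poll read at or below it; polls within ``refractory`` ms after a count
    are skipped entirely.  Timestamps are the counting poll instants.
    """
    if config.threshold is None:
        raise ConfigurationError("detect_prototype requires a threshold")
    if duration is None:
        duration = signal.duration
    n = int(math.floor(duration / config.poll_period))
    times = phase_offset + np.arange(n) * config.poll_period
    values = signal.baseline + signal.elevation_at(times)
    if signal.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        values = values + rng.normal(0.0, signal.noise_sd, size=n)

    events: List[float] = []
    prev_above = False
    resume = -math.inf
    for t, v in zip(times, values):
        if t < resume:
            continue
        above = v > config.threshold
        if above and not prev_above:
            events.append(t)
            resume = t + config.refractory
        prev_above = above
    return LickEvents(signal.cage_id, signal.bottle_id, np.asarray(events))


def _resolve_channels(
    signals: Mapping[Channel, Optional[ContinuousSignal]] | Iterable[ContinuousSignal],
) -> Dict[Channel, Optional[ContinuousSignal]]:
    if isinstance(signals, Mapping):
        resolved = dict(signals)
    else:
        resolved = {}
        for sig in signals:
            key = (sig.cage_id, sig.bottle_id)
            if key in resolved:
                raise ConfigurationError(f"duplicate channel {key}")
            resolved[key] = sig
    for key in resolved:
        if key not in CHANNEL_ORDER:
            raise ConfigurationError(f"unknown channel {key}")
    return {ch: resolved.get(ch) for ch in CHANNEL_ORDER}


def multiplex(
    signals: Mapping[Channel, Optional[ContinuousSignal]] | Iterable[ContinuousSignal],
    frame_period: float = 60.0,
    duration: Optional[float] = None,
    scan_offsets: Optional[Sequence[float]] = None,
    baseline_level: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FrameSequence:
    """Scan 16 channels into frames, one frame per ``frame_period``.

    Channel ``c`` (in fixed order 1A, 1B, ..., 8B) is read at
    ``frame_start + scan_offsets[c]``; the default sequential scan uses
    ``c * frame_period / 16``, so the last channel trails the first by
    15/16 of a frame.  Channels absent from ``signals`` read as flat
    baseline.  Latch counters record signal onsets between consecutive
    reads of each channel.
    """
    if frame_period <= 0:
        raise ParameterError("frame_period must be > 0")
    chans = _resolve_channels(signals)
    if duration is None:
        durations = [s.duration for s in chans.values() if s is not None]
        if not durations:
            raise ConfigurationError("duration required when all channels empty")
        duration = max(durations)
    n_ch = len(CHANNEL_ORDER)
    if scan_offsets is None:
        offsets = np.arange(n_ch) * frame_period / n_ch
    else:
        offsets = np.asarray(scan_offsets, dtype=float)
        if offsets.size != n_ch:
            raise ConfigurationError("scan_offsets must have 16 entries")

    n_frames = int(math.floor(duration / frame_period))
    frame_times = np.arange(n_frames) * frame_period
    values = np.empty((n_frames, n_ch))
    latch = np.zeros((n_frames, n_ch), dtype=int)
    rng = np.random.default_rng(seed)
    for c, ch in enumerate(CHANNEL_ORDER):
        sig = chans[ch]
        reads = frame_times + offsets[c]
        if sig is None:
            values[:, c] = baseline_level
        else:
            values[:, c] = sig.baseline + sig.elevation_at(reads)
            if sig.n_intervals:
                # onsets latched in (previous read, this read]
                hi = np.searchsorted(np.sort(sig.starts), reads, side="right")
                latch[:, c] = np.diff(np.concatenate([[0], hi]))
        ch_noise = noise_sd if sig is None else max(noise_sd, sig.noise_sd)
        if ch_noise > 0:
            values[:, c] += rng.normal(0.0, ch_noise, size=n_frames)
    return FrameSequence(
        frame_times=frame_times,
        values=values,
        latch_counts=latch,
        scan_offsets=offsets,
        frame_period=float(frame_period),
    )


def detect_wireless(
    frames: FrameSequence,
    threshold: Optional[float] = None,
    mode: Literal["edge", "latched"] = "edge",
    miss_prob: float = 0.0,
    seed: int = 0,
) -> Dict[Channel, LickEvents]:
    """Count licks on every channel of a frame sequence.

    ``edge``: a lick is counted at reads whose value crosses from at-or-
    below to above ``threshold``; ``latched``: each read drains the
    channel's latch counter, each drained event counted once, thinned by
    the per-event ``miss_prob``.  Timestamps are read instants.
    """
    if mode not in ("edge", "latched"):
        raise ConfigurationError(f"unknown wireless mode {mode!r}")
    if mode == "edge" and threshold is None:
        raise ConfigurationError("edge mode requires a threshold")
    rng = np.random.default_rng(seed)
    out: Dict[Channel, LickEvents] = {}
    for c, ch in enumerate(frames.channels):
        reads = frames.read_times(c)
        if mode == "edge":
            above = frames.values[:, c] > threshold
            rising = above & ~np.concatenate([[False], above[:-1]])
            ts = reads[rising]
        else:
            counts = frames.latch_counts[:, c].copy()
            if miss_prob > 0:
                counts = rng.binomial(counts, 1.0 - miss_prob)
            ts_list: List[float] = []
            for f in np.nonzero(counts)[0]:
                t = reads[f]
                ts_list.extend(t + j * _LATCH_EPS_MS for j in range(counts[f]))
            ts = np.asarray(ts_list)
        out[ch] = LickEvents(ch[0], ch[1], ts)
    return out


def detect_trace(
    trace: SensorTrace,
    threshold: float,
    refractory: float = 0.0,
) -> LickEvents:
    """Rising-edge detection directly on a stored trace's sample grid.

    Used for post-hoc analysis of raw trace files (already sampled at the
    acquisition rate); semantics match the prototype detector with the
    trace's own sample period as the poll period.
    """
    times = trace.times
    events: List[float] = []
    prev_above = False
    resume = -math.inf
    for t, v in zip(times, trace.values):
        if t < resume:
            continue
        above = v > threshold
        if above and not prev_above:
            events.append(t)
            resume = t + refractory
        prev_above = above
    return LickEvents(trace.cage_id, trace.bottle_id, np.asarray(events))
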