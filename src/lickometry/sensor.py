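"""Capacitive-style sensor trace modeling.

A lick train is rendered into a piecewise-constant continuous-time signal:
baseline level plus one elevated interval per tongue contact, optionally
plus Poisson "confuser" elevations that emulate approach-without-lick
events (the failure mode of beam-break sensors).  The continuous signal is
then sampled as instantaneous point reads with additive Gaussian baseline
noise — the 60 ms frame period gives the 16.67 samples/s of the wireless
acquisition chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ParameterError
from .signals import Bottle, LickTrain


@dataclass(frozen=True)
class SensorParams:
    """Abstract sensor units ("a.u."); defaults give SNR = amplitude/noise-sd = 25."""

    baseline_level: float = 100.0
    baseline_noise_sd: float = 2.0
    touch_amplitude: float = 50.0
    confuser_rate: float = 0.0            # events per minute
    confuser_amplitude: float = 50.0
    confuser_duration_mean: float = 150.0  # ms, exponential dwell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_noise_sd < 0:
            raise ParameterError("baseline_noise_sd must be >= 0")
        if self.touch_amplitude <= 0:
            raise ParameterError("touch_amplitude must be > 0")
        if self.confuser_rate < 0:
            raise ParameterError("confuser_rate must be >= 0")
        if self.confuser_duration_mean <= 0:
            raise ParameterError("confuser_duration_mean must be > 0")


@dataclass(frozen=True)
class ContinuousSignal:
    """Piecewise description of one channel's sensor activity.

    ``starts``/``ends``/``amplitudes`` describe elevated intervals
    [start, end) in ms; intervals may overlap (lick + confuser), in which
    case amplitudes add.  ``noise_sd`` is the Gaussian baseline noise to be
    drawn at sampling time.
    """

    baseline: float
    noise_sd: float
    starts: np.ndarray
    ends: np.ndarray
    amplitudes: np.ndarray
    duration: float
    cage_id: int = 1
    bottle_id: Bottle = "A"

    @property
    def n_intervals(self) -> int:
        return int(np.asarray(self.starts).size)

    def elevation_at(self, times: np.ndarray) -> np.ndarray:
        """Summed elevation amplitude at each query instant (no noise).

        Start-inclusive, end-exclusive; overlap-safe via a sorted
        boundary/step decomposition.
        """
        times = np.asarray(times, dtype=float)
        if self.n_intervals == 0:
            return np.zeros(times.shape)
        bounds = np.concatenate([self.starts, self.ends])
        steps = np.concatenate([self.amplitudes, -np.asarray(self.amplitudes)])
        order = np.argsort(bounds, kind="stable")
        bounds, steps = bounds[order], steps[order]
        level = np.cumsum(steps)
        idx = np.searchsorted(bounds, times, side="right") - 1
        out = np.where(idx >= 0, level[np.maximum(idx, 0)], 0.0)
        # clamp tiny negatives from float cancellation
        return np.where(np.abs(out) < 1e-9, 0.0, out)


@dataclass(frozen=True)
class SensorTrace:
    """Uniformly sampled sensor values for one channel."""

    cage_id: int
    bottle_id: Bottle
    sample_period: float     # ms
    start_time: float        # ms from session start
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.sample_period <= 0:
            raise ParameterError("sample_period must be > 0")
        if values.size and not np.all(np.isfinite(values)):
            raise ParameterError("trace values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) * self.sample_period


@dataclass(frozen=True)
class BaselineStats:
    mean: float
    sd: float
    n_samples: int


def render_continuous(
    train: LickTrain,
    params: SensorParams,
    duration: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> ContinuousSignal:
    """Render a lick train as a continuous sensor signal.

    One elevated interval per lick at ``touch_amplitude``; confuser
    intervals, if ``confuser_rate > 0``, arrive as a homogeneous Poisson
    process over [0, duration) with exponential dwell times at
    ``confuser_amplitude``.
    """
    if duration is None:
        if train.n_licks:
            duration = float(train.onsets[-1] + train.contact_durations[-1])
        else:
            duration = 0.0
    if duration < 0:
        raise ParameterError("duration must be >= 0")

    starts = np.asarray(train.onsets, dtype=float)
    ends = starts + np.asarray(train.contact_durations, dtype=float)
    amps = np.full(starts.size, params.touch_amplitude)

    if params.confuser_rate > 0 and duration > 0:
        rng = rng if rng is not None else np.random.default_rng(params.seed)
        expected = params.confuser_rate * duration / 60_000.0
        n_conf = rng.poisson(expected)
        c_starts = np.sort(rng.uniform(0.0, duration, size=n_conf))
        c_durs = rng.exponential(params.confuser_duration_mean, size=n_conf)
        starts = np.concatenate([starts, c_starts])
        ends = np.concatenate([ends, c_starts + c_durs])
        amps = np.concatenate([amps, np.full(n_conf, params.confuser_amplitude)])
        order = np.argsort(starts, kind="stable")
        starts, ends, amps = starts[order], ends[order], amps[order]

    return ContinuousSignal(
        baseline=params.baseline_level,
        noise_sd=params.baseline_noise_sd,
        starts=starts,
        ends=ends,
        amplitudes=amps,
        duration=float(duration),
        cage_id=train.cage_id,
        bottle_id=train.bottle_id,
    )


def sample_trace(
    signal: ContinuousSignal,
    sample_period: float,
    duration: Optional[float] = None,
    params: Optional[SensorParams] = None,
    phase_offset: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> SensorTrace:
    """Point-sample a continuous signal into a :class:`SensorTrace`.

    Sample k reads at ``k * sample_period + phase_offset`` and sees
    baseline + elevation + N(0, noise_sd).  ``floor(duration/sample_period)``
    samples are produced.
    """
    if sample_period <= 0:
        raise ParameterError("sample_period must be > 0")
    if duration is None:
        duration = signal.duration
    if duration < 0:
        raise ParameterError("duration must be >= 0")
    n = int(math.floor(duration / sample_period))
    times = phase_offset + np.arange(n) * sample_period
    values = signal.baseline + signal.elevation_at(times)
    noise_sd = params.baseline_noise_sd if params is not None else signal.noise_sd
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed if params is not None else 0)
        values = values + rng.normal(0.0, noise_sd, size=n)
    return SensorTrace(
        cage_id=signal.cage_id,
        bottle_id=signal.bottle_id,
        sample_period=float(sample_period),
        start_time=float(phase_offset),
        values=values,
    )


def flat_signal(
    params: SensorParams, duration: float, cage_id: int = 1, bottle_id: Bottle = "A"
) -> ContinuousSignal:
    """A lick-free (mouse-free) channel at baseline."""
    return ContinuousSignal(
        baseline=params.baseline_level,
        noise_sd=params.baseline_noise_sd,
        starts=np.empty(0),
        ends=np.empty(0),
        amplitudes=np.empty(0),
        duration=float(duration),
        cage_id=cage_id,
        bottle_id=bottle_id,
    )


def capture_baseline(
    params: SensorParams,
    duration: float = 60_000.0,
    sample_period: float = 60.0,
) -> BaselineStats:
    """Sample a mouse-free trace (default 1 min at 60 ms) and return its stats.

    Mirrors the bench procedure of recording each cage without an animal
    before a session to establish the per-channel baseline.
    """
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    trace = sample_trace(
        flat_signal(params, duration), sample_period, duration, params=params
    )
    values = trace.values
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return BaselineStats(mean=float(np.mean(values)), sd=sd, n_samples=len(values))
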