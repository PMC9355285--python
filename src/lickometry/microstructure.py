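"""Drinking-microstructure analytics over detected lick timestamps.

From a list of lick times one can derive interlick intervals (ILIs),
licking bouts (runs of licks separated by pauses longer than a bout-break
criterion, 1 s by convention), within-bout lick frequency, two-bottle
preference, circadian time-binned counts, and — with per-session bottle
weights — the correlation between lick counts and fluid intake that
validates a lickometer in vivo.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .detection import LickEvents
from .errors import ParameterError, UndefinedMetricError
from .signals import LickGenParams, generate_lick_train, with_seed

TimesLike = Union[LickEvents, np.ndarray, Sequence[float]]

WATER_DENSITY_G_PER_ML = 1.0
ETHANOL10_DENSITY_G_PER_ML = 0.984  # 10 % v/v ethanol in water


def _times(events: TimesLike) -> np.ndarray:
    if isinstance(events, LickEvents):
        return events.timestamps
    return np.asarray(events, dtype=float)


def interlick_intervals(events: TimesLike) -> np.ndarray:
    """Successive differences of lick times, ms; empty for < 2 licks."""
    t = _times(events)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ParameterError("events must be sorted")
    return np.diff(t)


@dataclass(frozen=True)
class BoutSummary:
    """Partition of a lick train into bouts.

    Every lick belongs to exactly one bout; ``sum(licks_per_bout)`` equals
    the total lick count.  Within-bout ILIs exclude the between-bout gaps.
    """

    bout_onsets: np.ndarray          # ms, first lick of each bout
    bout_offsets: np.ndarray         # ms, last lick of each bout
    licks_per_bout: np.ndarray       # int per bout
    inter_bout_intervals: np.ndarray  # ms, offset[i] -> onset[i+1]
    within_bout_ilis: np.ndarray     # ms, pooled over bouts

    @property
    def n_bouts(self) -> int:
        return int(self.bout_onsets.size)

    @property
    def within_bout_ili_mean(self) -> float:
        return float(np.mean(self.within_bout_ilis)) if self.within_bout_ilis.size else float("nan")

    @property
    def within_bout_ili_sd(self) -> float:
        return float(np.std(self.within_bout_ilis, ddof=1)) if self.within_bout_ilis.size > 1 else float("nan")

    @property
    def within_bout_frequency(self) -> float:
        """Licks/s inside bouts: 1000 / mean within-bout ILI."""
        m = self.within_bout_ili_mean
        return 1000.0 / m if m and not np.isnan(m) else float("nan")


def segment_bouts(events: TimesLike, bout_break: float = 1000.0) -> BoutSummary:
    """Partition licks into bouts: a new bout starts after any ILI > bout_break."""
    if bout_break <= 0:
        raise ParameterError("bout_break must be > 0")
    t = _times(events)
    if t.size == 0:
        empty = np.empty(0)
        return BoutSummary(empty, empty, np.empty(0, dtype=int), empty, empty)
    ilis = np.diff(t)
    breaks = np.nonzero(ilis > bout_break)[0]  # lick i ends a bout
    bout_starts_idx = np.concatenate([[0], breaks + 1])
    bout_ends_idx = np.concatenate([breaks, [t.size - 1]])
    licks_per_bout = bout_ends_idx - bout_starts_idx + 1
    within_mask = np.ones(ilis.size, dtype=bool)
    within_mask[breaks] = False
    return BoutSummary(
        bout_onsets=t[bout_starts_idx],
        bout_offsets=t[bout_ends_idx],
        licks_per_bout=licks_per_bout.astype(int),
        inter_bout_intervals=ilis[breaks],
        within_bout_ilis=ilis[within_mask],
    )


@dataclass(frozen=True)
class FrequencyProfile:
    bin_edges: np.ndarray        # ms
    rates: np.ndarray            # licks/s per bin
    overall_rate: float          # licks/s over the whole session
    within_bout_rate: float      # licks/s inside bouts


def lick_frequency(
    events: TimesLike,
    window: float,
    session_duration: Optional[float] = None,
    bout_break: float = 1000.0,
) -> FrequencyProfile:
    """Lick rate per fixed window plus overall and within-bout rates.

    ``window`` and times are in ms; rates are licks/s.  Empty inputs give
    zero rates everywhere (within-bout rate 0 with no bouts).
    """
    if window <= 0:
        raise ParameterError("window must be > 0")
    t = _times(events)
    if session_duration is None:
        session_duration = float(t[-1]) + 1e-9 if t.size else window
    n_bins = max(1, int(np.ceil(session_duration / window)))
    edges = np.arange(n_bins + 1) * window
    counts, _ = np.histogram(t, bins=edges)
    rates = counts / (window / 1000.0)
    overall = t.size / (session_duration / 1000.0) if session_duration > 0 else 0.0
    if t.size:
        wb = segment_bouts(t, bout_break).within_bout_frequency
        if np.isnan(wb):
            wb = 0.0
    else:
        wb = 0.0
    return FrequencyProfile(edges, rates, float(overall), float(wb))


def preference_index(events_a: TimesLike, events_b: TimesLike) -> float:
    """Fraction of total licks given to bottle A, in [0, 1]."""
    n_a, n_b = _times(events_a).size, _times(events_b).size
    if n_a + n_b == 0:
        raise UndefinedMetricError("preference undefined with zero licks")
    return n_a / (n_a + n_b)


DEFAULT_LIGHTS_ON = dt.time(7, 0)
DEFAULT_LIGHTS_OFF = dt.time(19, 0)


def _is_dark(t: dt.datetime, lights_on: dt.time, lights_off: dt.time) -> bool:
    tt = t.time()
    if lights_off > lights_on:  # dark wraps midnight
        return tt >= lights_off or tt < lights_on
    return lights_off <= tt < lights_on


def time_binned_counts(
    events: TimesLike,
    bin_minutes: float,
    session_start: dt.datetime,
    session_duration_ms: float,
    lights_on: dt.time = DEFAULT_LIGHTS_ON,
    lights_off: dt.time = DEFAULT_LIGHTS_OFF,
) -> pd.DataFrame:
    """Histogram of licks over the session with light/dark annotation.

    Bins are tagged by their start instant against a 12/12 h light cycle
    (lights on 07:00 by default).  Columns: ``bin_start_ms``,
    ``bin_start_time``, ``count``, ``is_dark``.
    """
    if bin_minutes <= 0:
        raise ParameterError("bin_minutes must be > 0")
    t = _times(events)
    bin_ms = bin_minutes * 60_000.0
    n_bins = max(1, int(np.ceil(session_duration_ms / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(t, bins=edges)
    starts = [session_start + dt.timedelta(milliseconds=float(e)) for e in edges[:-1]]
    dark = [_is_dark(s, lights_on, lights_off) for s in starts]
    return pd.DataFrame(
        {
            "bin_start_ms": edges[:-1],
            "bin_start_time": starts,
            "count": counts,
            "is_dark": dark,
        }
    )


@dataclass(frozen=True)
class SessionIntake:
    """One bottle in one overnight session: weights before/after + lick count."""

    animal_id: int
    session_id: int
    bottle_id: str
    liquid: str                  # water | ethanol | other
    weight_before: float         # g
    weight_after: float          # g
    total_licks: int

    @property
    def intake_g(self) -> float:
        return self.weight_before - self.weight_after


@dataclass(frozen=True)
class CorrelationResult:
    spearman_rho: float
    p_value: float
    r_squared: float
    n: int


def _sessions_frame(sessions) -> pd.DataFrame:
    if isinstance(sessions, pd.DataFrame):
        return sessions
    return pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in sessions],
            "session_id": [s.session_id for s in sessions],
            "bottle_id": [s.bottle_id for s in sessions],
            "liquid": [s.liquid for s in sessions],
            "weight_before": [s.weight_before for s in sessions],
            "weight_after": [s.weight_after for s in sessions],
            "total_licks": [s.total_licks for s in sessions],
        }
    )


def _correlate(intake: np.ndarray, licks: np.ndarray, seed: int) -> CorrelationResult:
    n = intake.size
    if n < 3:
        raise ParameterError("need at least 3 sessions")
    if np.all(intake == intake[0]) or np.all(licks == licks[0]):
        raise UndefinedMetricError("correlation undefined on a constant vector")
    rho, p = stats.spearmanr(intake, licks)
    if n <= 20:
        # small-sample p by pairing permutations instead of the asymptotic t
        res = stats.permutation_test(
            (intake, licks),
            lambda x, y: stats.spearmanr(x, y).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            alternative="two-sided",
            rng=np.random.default_rng(seed),
        )
        p = float(res.pvalue)
    fit = stats.linregress(intake, licks)
    return CorrelationResult(float(rho), float(p), float(fit.rvalue**2), int(n))


def intake_correlation(
    sessions,
    by_liquid: bool = False,
    seed: int = 0,
) -> Union[CorrelationResult, Dict[str, CorrelationResult]]:
    """Spearman correlation of fluid intake (g) against total lick counts.

    Intake is ``weight_before - weight_after`` per bottle-session.  Pooled
    by default; with ``by_liquid`` one result per liquid.  A descriptive
    least-squares R² accompanies the rank correlation.
    """
    frame = _sessions_frame(sessions)
    intake = (frame["weight_before"] - frame["weight_after"]).to_numpy(float)
    licks = frame["total_licks"].to_numpy(float)
    if not by_liquid:
        return _correlate(intake, licks, seed)
    out: Dict[str, CorrelationResult] = {}
    for liquid, sub in frame.groupby("liquid"):
        sub_intake = (sub["weight_before"] - sub["weight_after"]).to_numpy(float)
        out[str(liquid)] = _correlate(sub_intake, sub["total_licks"].to_numpy(float), seed)
    return out


def simulate_intake_sessions(
    n_animals: int = 24,
    n_sessions: int = 2,
    lick_params: Optional[LickGenParams] = None,
    ul_per_lick: float = 1.5,
    ul_per_lick_sigma: float = 0.1,
    weighing_noise_sd: float = 0.05,
    weight_before: float = 45.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for an overnight two-bottle intake dataset.

    For every animal × session × bottle a lick train is generated (bottle
    A water, bottle B 10 % ethanol); consumed grams are
    ``licks × µL-per-lick / 1000 × density`` plus Gaussian weighing noise.
    Animals differ in appetite (per-animal inter-bout-interval mean drawn
    uniformly from 20-60 s) and in per-lick volume (lognormal around
    ``ul_per_lick`` with log-sd ``ul_per_lick_sigma``).
    """
    if n_animals <= 0 or n_sessions <= 0:
        raise ParameterError("n_animals and n_sessions must be > 0")
    if ul_per_lick < 0 or weighing_noise_sd < 0:
        raise ParameterError("volumes and noise must be >= 0")
    base = lick_params if lick_params is not None else LickGenParams()
    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    for animal in range(1, n_animals + 1):
        ibi = rng.uniform(20.0, 60.0)
        ul_animal = ul_per_lick * rng.lognormal(0.0, ul_per_lick_sigma) if ul_per_lick > 0 else 0.0
        for session in range(1, n_sessions + 1):
            for bottle, liquid, density in (
                ("A", "water", WATER_DENSITY_G_PER_ML),
                ("B", "ethanol", ETHANOL10_DENSITY_G_PER_ML),
            ):
                train_seed = int(rng.integers(0, 2**31 - 1))
                params = with_seed(
                    LickGenParams(
                        mean_within_bout_rate=base.mean_within_bout_rate,
                        within_bout_rate_range=base.within_bout_rate_range,
                        licks_per_bout_mean=base.licks_per_bout_mean,
                        inter_bout_interval_mean=ibi,
                        session_duration=base.session_duration,
                        contact_duration_mean=base.contact_duration_mean,
                        contact_duration_sd=base.contact_duration_sd,
                        refractory_floor=base.refractory_floor,
                        ili_shape=base.ili_shape,
                    ),
                    train_seed,
                )
                licks = generate_lick_train(params).n_licks
                grams = licks * ul_animal / 1000.0 * density
                noise = rng.normal(0.0, weighing_noise_sd) if weighing_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "animal_id": animal,
                        "session_id": session,
                        "bottle_id": bottle,
                        "liquid": liquid,
                        "weight_before": weight_before,
                        "weight_after": weight_before - grams - noise,
                        "total_licks": licks,
                    }
                )
    return pd.DataFrame(rows)


def channel_summary(
    events_by_channel: Dict[Tuple[int, str], LickEvents],
    bout_break: float = 1000.0,
) -> pd.DataFrame:
    """Per-channel microstructure report plus per-cage A-preference."""
    rows = []
    pref: Dict[int, Dict[str, int]] = {}
    for (cage, bottle), ev in sorted(events_by_channel.items()):
        bouts = segment_bouts(ev, bout_break)
        pref.setdefault(cage, {})[bottle] = len(ev)
        rows.append(
            {
                "cage_id": cage,
                "bottle_id": bottle,
                "total_licks": len(ev),
                "n_bouts": bouts.n_bouts,
                "mean_licks_per_bout": float(np.mean(bouts.licks_per_bout))
                if bouts.n_bouts
                else 0.0,
                "mean_within_bout_ili_ms": bouts.within_bout_ili_mean,
                "within_bout_frequency_hz": bouts.within_bout_frequency
                if bouts.within_bout_ilis.size
                else float("nan"),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        def _pref(row):
            counts = pref.get(row["cage_id"], {})
            a, b = counts.get("A", 0), counts.get("B", 0)
            return a / (a + b) if a + b else float("nan")

        frame["cage_preference_a"] = frame.apply(_pref, axis=1)
    return frame
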