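"""Ground-truth lick trains and emulated pulse protocols.

Two generators live here.  :func:`generate_lick_train` draws a mouse-like
lick train from an alternating-renewal process (bouts of licks separated by
pauses), parameterised around the C57Bl/6 within-bout licking rate of
8.5 licks/s (physiological range 6-9 Hz).  :func:`generate_pulse_trains`
produces the deterministic square-pulse protocols used for in-silico
validation of the acquisition chain: three phases (bottle A only, bottle B
only, A/B alternating) at 5 or 10 Hz, 12,000 pulses per pulsed output, over
1-8 simultaneously active cages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Tuple

import numpy as np
from scipy import optimize, special

from .errors import ParameterError

#: fixed channel order used everywhere a 16-channel layout is needed:
#: (1A, 1B, 2A, 2B, ..., 8A, 8B)
CHANNEL_ORDER: List[Tuple[int, str]] = [
    (cage, bottle) for cage in range(1, 9) for bottle in ("A", "B")
]

Bottle = Literal["A", "B"]


@dataclass(frozen=True)
class LickTrain:
    """Ground-truth lick onsets for one channel (cage, bottle).

    Times are milliseconds from session start, real-valued.  ``onsets`` are
    strictly increasing; ``contact_durations`` hold the tongue-contact
    duration of each lick and never reach into the following lick.
    """

    cage_id: int
    bottle_id: Bottle
    onsets: np.ndarray
    contact_durations: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        contacts = np.asarray(self.contact_durations, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "contact_durations", contacts)
        if not 1 <= int(self.cage_id) <= 8:
            raise ParameterError(f"cage_id must be in 1..8, got {self.cage_id}")
        if self.bottle_id not in ("A", "B"):
            raise ParameterError(f"bottle_id must be 'A' or 'B', got {self.bottle_id}")
        if onsets.shape != contacts.shape:
            raise ParameterError("onsets and contact_durations must have equal length")
        if onsets.size:
            if onsets[0] < 0:
                raise ParameterError("onsets must be >= 0")
            if np.any(np.diff(onsets) <= 0):
                raise ParameterError("onsets must be strictly increasing")
            if np.any(contacts <= 0):
                raise ParameterError("contact durations must be > 0")
            if onsets.size > 1 and np.any(contacts[:-1] >= np.diff(onsets)):
                raise ParameterError("contacts must end before the next lick")

    def __len__(self) -> int:
        return int(self.onsets.size)

    @property
    def n_licks(self) -> int:
        return len(self)


@dataclass(frozen=True)
class LickGenParams:
    """Parameters of the mouse-lick generator.

    ``mean_within_bout_rate`` is the target licks/s inside bouts (default
    8.5, the typical C57Bl/6 rate); within-bout interlick intervals are
    gamma-distributed (shape ``ili_shape``) truncated below at
    ``refractory_floor`` ms, with the gamma scale calibrated so that the
    truncated mean equals ``1000 / mean_within_bout_rate``.  Bout lengths
    are geometric, pauses between bouts exponential.
    """

    mean_within_bout_rate: float = 8.5            # licks/s
    within_bout_rate_range: Tuple[float, float] = (6.0, 9.0)
    licks_per_bout_mean: float = 20.0             # licks
    inter_bout_interval_mean: float = 30.0        # s
    session_duration: float = 600.0               # s
    contact_duration_mean: float = 40.0           # ms
    contact_duration_sd: float = 10.0             # ms
    refractory_floor: float = 60.0                # ms
    ili_shape: float = 10.0                       # gamma shape of within-bout ILI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_within_bout_rate <= 0:
            raise ParameterError("mean_within_bout_rate must be > 0")
        lo, hi = self.within_bout_rate_range
        if not 0 < lo <= hi:
            raise ParameterError("within_bout_rate_range must be positive and ordered")
        for name in (
            "licks_per_bout_mean",
            "inter_bout_interval_mean",
            "contact_duration_mean",
            "contact_duration_sd",
            "refractory_floor",
            "ili_shape",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.session_duration < 0:
            raise ParameterError("session_duration must be >= 0")
        if 1000.0 / self.mean_within_bout_rate <= self.refractory_floor:
            raise ParameterError(
                "target mean ILI must exceed the refractory floor"
            )


@dataclass(frozen=True)
class PulseProtocol:
    """One cell of the three-phase in-silico validation design.

    Phase 1 pulses bottle A of each active cage, phase 2 bottle B, phase 3
    both bottles with B offset by half a period ("alternating").  Each
    pulsed output emits exactly ``n_pulses`` square pulses at exactly
    ``1000 / frequency`` ms period with ``duty`` high fraction.
    """

    phase: int
    frequency: float                       # Hz; 5 or 10 in replication mode
    n_pulses: int = 12_000
    active_cages: int = 1
    duty: float = 0.5
    high_duration_mode: Literal["fixed", "latched"] = "latched"

    def __post_init__(self) -> None:
        if self.phase not in (1, 2, 3):
            raise ParameterError(f"phase must be 1, 2 or 3, got {self.phase}")
        if self.frequency <= 0:
            raise ParameterError("frequency must be > 0")
        if self.n_pulses <= 0:
            raise ParameterError("n_pulses must be > 0")
        if not 1 <= self.active_cages <= 8:
            raise ParameterError("active_cages must be in 1..8")
        if not 0 < self.duty < 1:
            raise ParameterError("duty must be in (0, 1)")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency

    @property
    def pulsed_bottles(self) -> Tuple[str, ...]:
        return {1: ("A",), 2: ("B",), 3: ("A", "B")}[self.phase]


def _calibrated_gamma_scale(shape: float, floor: float, target_mean: float) -> float:
    """Gamma scale whose floor-truncated mean equals ``target_mean``.

    E[X | X > a] for X ~ Gamma(k, s) has the closed form
    ``k*s * Q(k+1, a/s) / Q(k, a/s)`` with Q the regularised upper
    incomplete gamma function; solved for s by bracketing.
    """

    def truncated_mean(scale: float) -> float:
        a = floor / scale
        upper_k1 = special.gammaincc(shape + 1.0, a)
        upper_k = special.gammaincc(shape, a)
        return shape * scale * upper_k1 / upper_k

    naive = target_mean / shape
    lo, hi = naive * 0.2, naive * 1.0
    # truncated mean is increasing in scale and >= target at the naive scale
    return optimize.brentq(lambda s: truncated_mean(s) - target_mean, lo, hi)


def _lognormal_mu_sigma(mean: float, sd: float) -> Tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_truncated_gamma(
    rng: np.random.Generator, n: int, shape: float, scale: float, floor: float
) -> np.ndarray:
    """Rejection-sample n gamma variates conditioned on exceeding floor."""
    out = rng.gamma(shape, scale, size=n)
    bad = out < floor
    while np.any(bad):
        out[bad] = rng.gamma(shape, scale, size=int(bad.sum()))
        bad = out < floor
    return out


def generate_lick_train(
    params: LickGenParams, cage_id: int = 1, bottle_id: Bottle = "A"
) -> LickTrain:
    """Draw one session-long lick train from the alternating-renewal model.

    The session alternates pauses (exponential, mean
    ``inter_bout_interval_mean`` s) with bouts whose length is geometric
    (mean ``licks_per_bout_mean``) and whose interlick intervals are
    truncated-gamma with mean ``1000 / mean_within_bout_rate`` ms.
    Reproducible under a fixed seed.
    """

    rng = np.random.default_rng(params.seed)
    session_end = params.session_duration * 1000.0  # ms
    if session_end == 0:
        return LickTrain(cage_id, bottle_id, np.empty(0), np.empty(0))

    mean_ili = 1000.0 / params.mean_within_bout_rate
    scale = _calibrated_gamma_scale(params.ili_shape, params.refractory_floor, mean_ili)
    geo_p = 1.0 / params.licks_per_bout_mean
    pause_mean_ms = params.inter_bout_interval_mean * 1000.0

    onsets: List[np.ndarray] = []
    t = rng.exponential(pause_mean_ms)
    while t < session_end:
        n_licks = rng.geometric(geo_p)
        ilis = _draw_truncated_gamma(
            rng, n_licks - 1, params.ili_shape, scale, params.refractory_floor
        )
        bout = t + np.concatenate(([0.0], np.cumsum(ilis)))
        bout = bout[bout < session_end]
        if bout.size:
            onsets.append(bout)
        t = (bout[-1] if bout.size else t) + rng.exponential(pause_mean_ms)

    all_onsets = np.concatenate(onsets) if onsets else np.empty(0)
    mu, sigma = _lognormal_mu_sigma(
        params.contact_duration_mean, params.contact_duration_sd
    )
    contacts = rng.lognormal(mu, sigma, size=all_onsets.size)
    if all_onsets.size > 1:
        gaps = np.diff(all_onsets)
        contacts[:-1] = np.minimum(contacts[:-1], gaps - 1.0)
    contacts = np.maximum(contacts, 1.0)
    return LickTrain(cage_id, bottle_id, all_onsets, contacts)


def generate_pulse_trains(protocol: PulseProtocol) -> Dict[Tuple[int, str], LickTrain]:
    """Emulated pulse trains for one protocol cell, keyed by (cage, bottle).

    All 16 channels are present; channels not pulsed in the given phase
    carry empty trains.  Pulse onsets are exact multiples of the period
    (phase-3 bottle B shifted by half a period); pulse high time is
    ``duty * period``.
    """

    period = protocol.period_ms
    high = protocol.duty * period
    base = np.arange(protocol.n_pulses, dtype=float) * period
    trains: Dict[Tuple[int, str], LickTrain] = {}
    for cage, bottle in CHANNEL_ORDER:
        pulsed = (
            cage <= protocol.active_cages and bottle in protocol.pulsed_bottles
        )
        if not pulsed:
            trains[(cage, bottle)] = LickTrain(cage, bottle, np.empty(0), np.empty(0))
            continue
        offset = period / 2.0 if (protocol.phase == 3 and bottle == "B") else 0.0
        onsets = base + offset
        contacts = np.full(onsets.size, high)
        trains[(cage, bottle)] = LickTrain(cage, bottle, onsets, contacts)
    return trains


def with_seed(params: LickGenParams, seed: int) -> LickGenParams:
    """Copy of ``params`` with a different seed (convenience for sweeps)."""
    return replace(params, seed=int(seed))
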