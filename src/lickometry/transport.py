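"""Lossy wireless-link model and the reading/transmission error metrics.

The radio link is connectionless (UDP-style): frame packets may silently
vanish.  Loss is modelled per packet, either independently (Bernoulli) or
with a two-state good/bad burst channel (Gilbert–Elliott) emulating busy
network periods.  Optional duplicate delivery is supported.

Two error metrics summarise the acquisition chain:

* reading error — percent of emitted events the central unit failed to
  register before transmission: ``(emitted - detected) / emitted * 100``;
* transmission error — signed percent change of the event count through
  the link: ``(received - sent) / sent * 100`` (negative = net loss).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple, TypeVar

import numpy as np

from .errors import ParameterError, UndefinedMetricError

T = TypeVar("T")


@dataclass(frozen=True)
class LossModel:
    """Per-packet loss model.

    ``bernoulli``: each packet independently lost with ``loss_prob``
    (default 0.008, giving a mean transmission error around -0.8 %, the
    order of magnitude of a busy shared-bandwidth link).  ``burst``: a
    two-state Markov channel; packets sent in the bad state are lost with
    ``bad_loss_prob``.  Delivered packets are duplicated with
    ``duplicate_prob``.
    """

    kind: Literal["bernoulli", "burst"] = "bernoulli"
    loss_prob: float = 0.008
    good_to_bad: float = 0.01
    bad_to_good: float = 0.2
    bad_loss_prob: float = 0.5
    duplicate_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "loss_prob",
            "good_to_bad",
            "bad_to_good",
            "bad_loss_prob",
            "duplicate_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if self.kind not in ("bernoulli", "burst"):
            raise ParameterError(f"unknown loss model kind {self.kind!r}")


@dataclass(frozen=True)
class TransmissionReport:
    sent_count: int
    received_count: int

    @property
    def transmission_error(self) -> float:
        return transmission_error(self.sent_count, self.received_count)


@dataclass(frozen=True)
class ReadingReport:
    emitted_count: int
    detected_count: int

    @property
    def reading_error(self) -> float:
        return reading_error(self.emitted_count, self.detected_count)


def delivery_counts(
    n: int, model: LossModel, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Copies delivered of each of ``n`` packets (0 = lost, 2 = duplicated).

    The building block of :func:`transmit`; exposed so that event-level
    accounting (which events rode in which frame packet) can reuse the
    same draw.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if model.kind == "bernoulli":
        lost = rng.random(n) < model.loss_prob
    else:
        # two-state Markov channel, start in the good state
        u_state = rng.random(n)
        u_loss = rng.random(n)
        lost = np.zeros(n, dtype=bool)
        bad = False
        for i in range(n):
            if bad:
                if u_state[i] < model.bad_to_good:
                    bad = False
            else:
                if u_state[i] < model.good_to_bad:
                    bad = True
            lost[i] = bad and (u_loss[i] < model.bad_loss_prob)
    copies = (~lost).astype(np.int64)
    if model.duplicate_prob > 0:
        dup = (rng.random(n) < model.duplicate_prob) & ~lost
        copies += dup.astype(np.int64)
    return copies


def transmit(
    units: Sequence[T], model: LossModel, rng: Optional[np.random.Generator] = None
) -> List[T]:
    """Push a sequence of units through the lossy link, order preserved."""
    copies = delivery_counts(len(units), model, rng)
    out: List[T] = []
    for unit, c in zip(units, copies):
        out.extend([unit] * int(c))
    return out


def transmission_error(sent_count: int, received_count: int) -> float:
    """Signed percent change through the link; negative = net loss."""
    if sent_count <= 0:
        raise UndefinedMetricError("transmission error undefined for sent_count 0")
    if received_count < 0:
        raise ParameterError("received_count must be >= 0")
    return (received_count - sent_count) / sent_count * 100.0


def reading_error(emitted_count: int, detected_count: int) -> float:
    """Percent of emitted events the central unit failed to register."""
    if emitted_count <= 0:
        raise UndefinedMetricError("reading error undefined for emitted_count 0")
    if detected_count < 0:
        raise ParameterError("detected_count must be >= 0")
    return (emitted_count - detected_count) / emitted_count * 100.0
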