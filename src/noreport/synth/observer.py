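"""Sigmoidal psychometric observer for simulating detection responses."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .._rng import substream
from ..paradigm import StimulusEvent

__all__ = ["ObserverModel", "generate_observer_responses", "apply_overt_reports"]


@dataclass(frozen=True)
class ObserverModel:
    """Logistic psychometric observer with lapse and guess rates.

    P(seen | opacity) = guess + (1 - guess - lapse) * logistic(slope * (opacity - threshold)).

    With lapse = guess = 0 the detection probability at ``threshold_opacity``
    is exactly 0.5 and the curve is non-decreasing in opacity.  ``slope`` may
    be ``inf`` for a step-function (noiseless) observer.
    """

    threshold_opacity: float
    slope: float = 40.0
    lapse_rate: float = 0.0
    guess_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_opacity < 1:
            raise ValueError("threshold_opacity must lie in (0, 1)")
        if not (0 <= self.lapse_rate < 0.5 and 0 <= self.guess_rate < 0.5):
            raise ValueError("lapse and guess rates must lie in [0, 0.5)")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def p_seen(self, opacity) -> np.ndarray:
        op = np.asarray(opacity, dtype=float)
        if np.any((op < 0) | (op > 1)):
            raise ValueError("opacity must lie in [0, 1]")
        if np.isinf(self.slope):
            core = np.where(op > self.threshold_opacity, 1.0,
                            np.where(op == self.threshold_opacity, 0.5, 0.0))
        else:
            core = expit(self.slope * (op - self.threshold_opacity))
        return self.guess_rate + (1 - self.guess_rate - self.lapse_rate) * core


def generate_observer_responses(
    schedule: Sequence[StimulusEvent],
    observer: ObserverModel,
    seed: int,
) -> list[tuple[StimulusEvent, bool]]:
    """Draw independent seen/not-seen flags from the psychometric function.

    Blank presentations (opacity 0 / condition 'blank') contain no stimulus,
    so they are "seen" only at the observer's guess rate.
    """
    rng = substream(seed, "observer_responses")
    out = []
    for event in schedule:
        if event.opacity_condition == "blank" or event.opacity == 0:
            p = observer.guess_rate
        else:
            p = float(observer.p_seen(event.opacity))
        out.append((event, bool(rng.random() < p)))
    return out


def apply_overt_reports(
    labeled: Sequence[tuple[StimulusEvent, bool]],
    seed: int,
    n_locations: int = 4,
) -> None:
    """Fill overt responses on report events in place from their seen flags.

    A seen report stimulus is answered "yes" with the correct location; an
    unseen one is answered "no" with a uniformly guessed location (as
    instructed in the task).  No-report events are left untouched.
    """
    rng = substream(seed, "overt_reports")
    for event, seen in labeled:
        if event.relevance != "report":
            continue
        event.response_seen = bool(seen)
        event.response_location = (
            event.location if seen else int(rng.integers(1, n_locations + 1))
        )
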