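"""Simulated 2AFC observers on the audio-visual motion trial design.

This is the synthetic-data stage standing in for human subjects: it
reproduces the experimental schedule -- nine signed spatial offsets per
velocity, ten repeats each in a 90-trial block, motion direction strictly
alternating trial to trial -- and fills it with responses drawn from a
decision-level observer whose true psychometric parameters are known.

The response convention matches the analysis convention throughout:
the modelled probability is P(respond "vision leads") as a function of the
signed offset mu (positive = auditory lag), so an observer with a positive
generating PSE yields data whose fitted PSE is positive (an auditory lead
bias at spatiotemporal equality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychometrics import LAPSE_MAX, psychometric_function

__all__ = [
    "CONDITIONS",
    "OFFSET_SETS",
    "VISION_LEADS",
    "AUDITION_LEADS",
    "ObserverModel",
    "TrialRecord",
    "ResponseSet",
    "offsets_for",
    "build_schedule",
    "simulate_response",
    "run_block",
]

#: the three acoustic conditions: anechoic 1 deg, anechoic 5 deg, reverberant 5 deg
CONDITIONS = ("anechoic1", "anechoic5", "reverberant5")

#: per-velocity signed offsets (degrees); positive = auditory lag
OFFSET_SETS = {
    25.0: (-10.0, -5.0, -2.5, -1.25, 0.0, 1.25, 2.5, 5.0, 10.0),
    50.0: (-10.0, -7.5, -5.0, -2.5, 0.0, 2.5, 5.0, 7.5, 10.0),
    100.0: (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0),
}

VISION_LEADS = "vision_leads"
AUDITION_LEADS = "audition_leads"


def offsets_for(velocity: float) -> tuple[float, ...]:
    """The nine-element offset set of a study velocity (25, 50, 100 deg/s)."""
    try:
        return OFFSET_SETS[float(velocity)]
    except KeyError:
        raise ValueError(
            f"no offset set for velocity {velocity:g}; "
            f"supported: {sorted(OFFSET_SETS)}"
        ) from None


@dataclass
class TrialRecord:
    """One 2AFC trial of the motion experiment."""

    velocity: float
    condition: str
    offset: float  # signed degrees, positive = auditory lag
    direction: str  # leftward | rightward
    repeat_index: int  # 1..repeats
    response: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.direction not in ("leftward", "rightward"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class ObserverModel:
    """Decision-level observer with known psychometric parameters.

    Responds "vision leads" with probability
    psi(mu) = lapse + (1 - 2 lapse) Phi((mu - pse) / sigma); the rendered
    waveforms are not passed through an auditory model -- the observer acts
    directly on the programmed offset.
    """

    pse: float
    sigma: float
    lapse: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.lapse <= LAPSE_MAX:
            raise ValueError(f"lapse must lie in [0, {LAPSE_MAX}]")

    def prob_vision_leads(self, mu) -> np.ndarray:
        return psychometric_function(mu, self.pse, self.sigma, self.lapse)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def build_schedule(
    velocity: float,
    condition: str,
    repeats: int = 10,
    seed: int = 0,
    offsets: tuple[float, ...] | None = None,
) -> list[TrialRecord]:
    """Randomized block schedule: ``repeats`` x 9 trials, responses empty.

    Offsets are shuffled uniformly without replacement within each repeat
    cycle; motion direction strictly alternates from a seed-chosen start,
    which balances directions across offsets by construction.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    offsets = offsets_for(velocity) if offsets is None else tuple(offsets)
    rng = np.random.default_rng(seed)
    order: list[tuple[float, int]] = []
    for cycle in range(1, repeats + 1):
        order.extend((mu, cycle) for mu in rng.permutation(offsets))
    direction = rng.choice(["leftward", "rightward"])
    trials = []
    for mu, cycle in order:
        trials.append(
            TrialRecord(velocity=float(velocity), condition=condition,
                        offset=float(mu), direction=direction,
                        repeat_index=cycle)
        )
        direction = "leftward" if direction == "rightward" else "rightward"
    return trials


def simulate_response(
    obs: ObserverModel, mu: float, rng: np.random.Generator | None = None
) -> str:
    """Draw one 2AFC response at offset ``mu``.

    Passing an explicit generator threads one reproducible stream through
    a whole block; without one, the observer's own seed is used.
    """
    rng = obs.rng() if rng is None else rng
    p = float(obs.prob_vision_leads(mu))
    return VISION_LEADS if rng.random() < p else AUDITION_LEADS


@dataclass
class ResponseSet:
    """A completed block of trials."""

    trials: list[TrialRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                trial=np.arange(1, len(self.trials) + 1),
                velocity=[t.velocity for t in self.trials],
                condition=[t.condition for t in self.trials],
                offset_deg=[t.offset for t in self.trials],
                direction=[t.direction for t in self.trials],
                repeat_index=[t.repeat_index for t in self.trials],
                response=[t.response for t in self.trials],
            )
        )

    def aggregate(self) -> pd.DataFrame:
        """Per-offset counts: n_trials and n_vision_leads, sorted by offset."""
        df = self.to_frame()
        agg = (
            df.groupby("offset_deg")
            .agg(
                n_trials=("response", "size"),
                n_vision_leads=("response", lambda r: int((r == VISION_LEADS).sum())),
            )
            .reset_index()
            .sort_values("offset_deg", ignore_index=True)
        )
        return agg


def run_block(obs: ObserverModel, schedule: list[TrialRecord]) -> ResponseSet:
    """Fill every trial of a schedule with a simulated response."""
    if any(t.response is not None for t in schedule):
        raise ValueError("schedule already contains responses")
    rng = obs.rng()
    done = []
    for t in schedule:
        done.append(
            TrialRecord(t.velocity, t.condition, t.offset, t.direction,
                        t.repeat_index, simulate_response(obs, t.offset, rng))
        )
    return ResponseSet(done)
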