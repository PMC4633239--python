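"""Adaptive 1-up/1-down staircases with step halving/doubling and interleaving.

The stimulus magnitude starts at the platform maximum and, after every
counted response, moves by the current step in the direction *opposite* the
response, so the series converges on the point of subjective equality (PSE).
Step-size adaptation:

* the step is halved (never below ``min_step``) when the response direction
  reverses relative to the previous counted response of the same staircase;
* the step is doubled (never above ``max_step``) whenever the last three
  counted responses of the staircase share one direction; a fourth identical
  response re-triggers the doubling.

Magnitudes are signed and may cross zero; they are clamped to the physical
platform limit.  All magnitudes in this module are expressed in the
displacement domain (cm or degrees); the block runner converts presented
stimuli to signed peak velocity for logging and for the observer.

Blocks interleave two independent staircases (one per visual-stimulus
direction) by random choice, subject to the constraint that no more than
``max_run`` successive presented stimuli share one physical direction; when
both staircases would extend such a run, the trial is presented anyway and
flagged ``run_violation``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from .motion import peak_velocity

__all__ = [
    "Response",
    "StaircaseError",
    "StaircaseConfig",
    "StaircaseState",
    "BlockDesign",
    "ScheduledTrial",
    "init_staircase",
    "update",
    "BlockScheduler",
    "run_block",
]


class Response(enum.Enum):
    """Forced-choice direction report; NONE marks a timed-out (unlogged) trial."""

    LEFT = "L"
    RIGHT = "R"
    NONE = "NONE"

    @classmethod
    def from_label(cls, label: str) -> "Response":
        label = str(label).strip().upper()
        for member in cls:
            if label in (member.value, member.name):
                return member
        raise ValueError(f"unknown response label {label!r}")


class StaircaseError(RuntimeError):
    """Raised when a staircase is driven outside its contract."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive staircase, in displacement units (cm or deg).

    Defaults follow the modelled experimental design: start at the 10 cm / 10 deg platform
    maximum, initial step 4, step bounds [0.25, 4], 25 counted trials.
    """

    initial_magnitude: float = 10.0
    initial_step: float = 4.0
    min_step: float = 0.25
    max_step: float = 4.0
    n_steps: int = 25
    magnitude_limit: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.min_step <= self.initial_step <= self.max_step):
            raise ValueError(
                "step sizes must satisfy 0 < min_step <= initial_step <= max_step, "
                f"got min={self.min_step}, initial={self.initial_step}, max={self.max_step}"
            )
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.magnitude_limit < abs(self.initial_magnitude):
            raise ValueError(
                f"magnitude_limit ({self.magnitude_limit}) must cover the initial "
                f"magnitude ({self.initial_magnitude})"
            )


@dataclass(frozen=True)
class StaircaseState:
    """Immutable snapshot of a staircase; :func:`update` returns a new state.

    ``history`` holds counted ``(magnitude, response)`` pairs; ``events``
    additionally records NONE (no-response) presentations, which never count
    toward ``n_steps`` and leave magnitude and step unchanged.
    """

    config: StaircaseConfig
    current_magnitude: float
    current_step: float
    history: tuple = ()
    events: tuple = ()

    @property
    def completed(self) -> bool:
        return len(self.history) == self.config.n_steps

    @property
    def consecutive_same_responses(self) -> int:
        """Length of the trailing run of identical counted responses."""
        run = 0
        last = None
        for _, resp in reversed(self.history):
            if last is None:
                last = resp
            if resp is not last:
                break
            run += 1
        return run


def init_staircase(config: StaircaseConfig) -> StaircaseState:
    """Fresh staircase at its configured starting magnitude and step."""
    return StaircaseState(
        config=config,
        current_magnitude=float(config.initial_magnitude),
        current_step=float(config.initial_step),
    )


def update(state: StaircaseState, response: Response) -> StaircaseState:
    """Apply one response: adapt the step size, then move the magnitude.

    The step is adapted *before* the move, so the first response after the
    10-unit start with a 4-unit step lands at 6 units.  NONE responses are
    logged as events only: the same magnitude will be re-presented.
    """
    if state.completed:
        raise StaircaseError("cannot update a completed staircase")
    if response is Response.NONE:
        return replace(state, events=state.events + ((state.current_magnitude, response),))

    cfg = state.config
    step = state.current_step
    prev = state.history[-1][1] if state.history else None
    if prev is not None:
        if response is not prev:
            step = max(cfg.min_step, step / 2.0)
        elif state.consecutive_same_responses + 1 >= 3:
            step = min(cfg.max_step, step * 2.0)

    move = -step if response is Response.RIGHT else step
    magnitude = state.current_magnitude + move
    magnitude = min(cfg.magnitude_limit, max(-cfg.magnitude_limit, magnitude))

    entry = (state.current_magnitude, response)
    return replace(
        state,
        current_magnitude=magnitude,
        current_step=step,
        history=state.history + (entry,),
        events=state.events + (entry,),
    )


@dataclass(frozen=True)
class BlockDesign:
    """One block: 2 interleaved staircases (experimental) or 1 (control).

    ``conditions`` maps staircase id -> visual-condition label; each
    staircase gets its own config (the two experimental staircases start at
    the platform maximum on the side implied by their visual condition).
    ``duration`` is the movement time used to convert displacement-domain
    magnitudes to signed peak velocity for presentation.
    """

    block_label: str
    block_type: str
    axis: str
    conditions: dict
    configs: dict
    max_run: int = 5
    duration: float = 1.0

    def __post_init__(self) -> None:
        if set(self.conditions) != set(self.configs):
            raise ValueError("conditions and configs must share staircase ids")
        if len(self.conditions) not in (1, 2):
            raise ValueError("a block contains one (control) or two (experimental) staircases")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")

    @property
    def n_trials(self) -> int:
        return sum(cfg.n_steps for cfg in self.configs.values())


@dataclass(frozen=True)
class ScheduledTrial:
    """One presented stimulus: identity, signed magnitudes, run-constraint flag."""

    staircase_id: str
    condition: str
    magnitude: float          # displacement domain, signed
    velocity: float           # signed peak velocity, presented to the observer
    counted: bool
    run_violation: bool


def _direction(magnitude: float) -> int:
    if magnitude > 0:
        return 1
    if magnitude < 0:
        return -1
    return 0


class BlockScheduler:
    """Interleaves a block's staircases trial by trial.

    Call :meth:`next_trial` to obtain the next stimulus, then
    :meth:`record` with the observer's response before asking for another.
    """

    def __init__(self, design: BlockDesign, rng: np.random.Generator):
        self.design = design
        self.rng = rng
        self.states = {sid: init_staircase(cfg) for sid, cfg in design.configs.items()}
        self._recent_directions: list[int] = []
        self._pending: Optional[str] = None

    @property
    def done(self) -> bool:
        return all(s.completed for s in self.states.values())

    def _incomplete(self) -> list[str]:
        return sorted(sid for sid, s in self.states.items() if not s.completed)

    def next_trial(self) -> ScheduledTrial:
        if self.done:
            raise StaircaseError("all staircases in this block are complete")
        if self._pending is not None:
            raise StaircaseError("previous trial has not been recorded")
        ids = self._incomplete()
        choice = ids[self.rng.integers(len(ids))] if len(ids) > 1 else ids[0]

        run_violation = False
        recent = self._recent_directions[-self.design.max_run:]
        if len(recent) == self.design.max_run and len(set(recent)) == 1 and recent[0] != 0:
            run_dir = recent[0]
            if _direction(self.states[choice].current_magnitude) == run_dir:
                breakers = [
                    sid for sid in ids
                    if _direction(self.states[sid].current_magnitude) != run_dir
                ]
                if breakers:
                    choice = breakers[self.rng.integers(len(breakers))] if len(breakers) > 1 else breakers[0]
                else:
                    run_violation = True

        state = self.states[choice]
        magnitude = state.current_magnitude
        self._pending = choice
        return ScheduledTrial(
            staircase_id=choice,
            condition=self.design.conditions[choice],
            magnitude=magnitude,
            velocity=_direction(magnitude) * peak_velocity(abs(magnitude), self.design.duration),
            counted=True,  # provisional; NONE responses are re-marked by record()
            run_violation=run_violation,
        )

    def record(self, staircase_id: str, response: Response) -> bool:
        """Log the response for the pending trial; returns True if it counted."""
        if self._pending != staircase_id:
            raise StaircaseError("record() must follow next_trial() for the same staircase")
        state = self.states[staircase_id]
        self._recent_directions.append(_direction(state.current_magnitude))
        self.states[staircase_id] = update(state, response)
        self._pending = None
        return response is not Response.NONE


def run_block(
    design: BlockDesign,
    respond: Callable[[str, float], Response],
    rng: np.random.Generator,
) -> Iterator[tuple[ScheduledTrial, Response]]:
    """Run a whole block against a responder ``respond(condition, velocity)``.

    Yields ``(trial, response)`` for every presentation, including
    non-counted NONE events; counted trials total ``design.n_trials``.
    """
    scheduler = BlockScheduler(design, rng)
    while not scheduler.done:
        trial = scheduler.next_trial()
        response = respond(trial.condition, trial.velocity)
        counted = scheduler.record(trial.staircase_id, response)
        if not counted:
            trial = replace(trial, counted=False)
        yield trial, response
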