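"""Synthetic forced-choice observers for direction-discrimination experiments.

An observer reports RIGHT with probability

    P(RIGHT | v) = lapse/2 + (1 - lapse) * Phi((v - mu_c) / sigma)

where ``v`` is the signed peak velocity of the inertial stimulus, ``mu_c``
the observer's point of subjective equality (PSE) under visual condition
``c``, and ``sigma`` the psychometric width (direction-discrimination
threshold) on that axis.  With probability ``p_none`` the observer times out
and no response is logged (rare in practice; default below 1% of presentations).

Condition labels pair a visual-stimulus type with its direction
(``star_left``, ``star_right``, ``illusion_left``, ``illusion_right``,
``arrow_left``, ``arrow_right``) plus ``control``; PSEs are keyed by
``(axis, condition)`` because sway (cm/s) and yaw (deg/s) live on different
scales.  Positive magnitudes and rightward visual motion are both "right";
a left-visual minus right-visual PSE difference is therefore negative when
the perceptual bias is opposite the direction of visual motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .staircase import Response

__all__ = ["ObserverModel", "EffectSpec", "SigmaSpec", "CohortSpec", "respond", "make_cohort"]


class ConfigurationError(ValueError):
    """Invalid observer or cohort configuration."""


@dataclass(frozen=True)
class ObserverModel:
    """A stochastic subject with per-condition PSEs.

    Parameters
    ----------
    pse : mapping
        ``(axis, condition) -> PSE`` in signed peak-velocity units.
    sigma : mapping
        ``axis -> psychometric width`` (> 0), same units as the PSEs.
    lapse : float
        Stimulus-independent error rate in [0, 0.5).
    p_none : float
        Probability of a timed-out (unlogged) trial, in [0, 0.1).
    """

    subject_id: str
    pse: Mapping
    sigma: Mapping
    lapse: float = 0.0
    p_none: float = 0.0

    def __post_init__(self) -> None:
        for axis, s in self.sigma.items():
            if not s > 0:
                raise ConfigurationError(f"sigma must be positive, got {s} for axis {axis!r}")
        if not 0 <= self.lapse < 0.5:
            raise ConfigurationError(f"lapse must lie in [0, 0.5), got {self.lapse}")
        if not 0 <= self.p_none < 0.1:
            raise ConfigurationError(f"p_none must lie in [0, 0.1), got {self.p_none}")

    def condition_pse(self, axis: str, condition: str) -> float:
        try:
            return self.pse[(axis, condition)]
        except KeyError:
            raise ConfigurationError(
                f"observer {self.subject_id!r} has no PSE for condition "
                f"{condition!r} on axis {axis!r}"
            ) from None

    def response_probability(self, axis: str, condition: str, stimulus) -> np.ndarray:
        """P(RIGHT) at signed stimulus magnitude(s), conditional on responding."""
        mu = self.condition_pse(axis, condition)
        sig = self.sigma[axis] if axis in self.sigma else None
        if sig is None:
            raise ConfigurationError(f"observer {self.subject_id!r} has no sigma for axis {axis!r}")
        z = (np.asarray(stimulus, dtype=float) - mu) / sig
        return self.lapse / 2.0 + (1.0 - self.lapse) * ndtr(z)

    def respond(self, axis: str, condition: str, stimulus: float, rng: np.random.Generator) -> Response:
        """One forced-choice report; NONE with probability ``p_none``."""
        if self.p_none > 0 and rng.random() < self.p_none:
            return Response.NONE
        p_right = float(self.response_probability(axis, condition, stimulus))
        return Response.RIGHT if rng.random() < p_right else Response.LEFT

    def responder(self, axis: str, rng: np.random.Generator):
        """Bind axis and rng into a ``respond(condition, stimulus)`` callable."""
        return lambda condition, stimulus: self.respond(axis, condition, stimulus, rng)


def respond(observer: ObserverModel, axis: str, condition: str, stimulus: float,
            rng: np.random.Generator) -> Response:
    """Functional alias for :meth:`ObserverModel.respond`."""
    return observer.respond(axis, condition, stimulus, rng)


@dataclass(frozen=True)
class EffectSpec:
    """Generative left-minus-right PSE difference for one block type.

    ``mean`` is the population-mean difference between the PSEs measured
    under the left- and right-directed visual stimulus (negative = bias
    opposite the visual motion), ``sd`` its between-subject standard
    deviation.  Each subject's two condition PSEs sit at ``baseline ±
    effect/2``.
    """

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"effect sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class SigmaSpec:
    """Between-subject distribution of the threshold sigma on one axis."""

    mean: float
    sd: float = 0.0
    floor: float = 0.2

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ConfigurationError(f"sigma floor must be positive, got {self.floor}")
        if self.sd < 0:
            raise ConfigurationError(f"sigma sd must be >= 0, got {self.sd}")

    def draw(self, rng: np.random.Generator) -> float:
        # truncation by resampling; degenerate sd=0 short-circuits
        if self.sd == 0:
            return max(self.mean, self.floor)
        for _ in range(1000):
            s = rng.normal(self.mean, self.sd)
            if s >= self.floor:
                return s
        return self.floor


# block type -> (axis, visual-stimulus prefix)
BLOCK_TYPES = {
    "star_sway": ("sway", "star"),
    "star_yaw": ("yaw", "star"),
    "illusion_sway": ("sway", "illusion"),
    "illusion_yaw": ("yaw", "illusion"),
    "arrow_sway": ("sway", "arrow"),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a simulated subject cohort.

    ``effects`` maps block types (e.g. ``star_sway``) to :class:`EffectSpec`;
    ``sigma`` and ``baseline_sd`` are keyed by axis.  ``baseline_sd`` is the
    between-subject SD of the idiosyncratic axis bias shared by all
    conditions of that axis (so it cancels in left-minus-right differences).
    """

    n_subjects: int = 13
    sigma: Mapping = field(default_factory=dict)
    effects: Mapping = field(default_factory=dict)
    baseline_sd: Mapping = field(default_factory=dict)
    lapse: float = 0.0
    p_none: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for bt in self.effects:
            if bt not in BLOCK_TYPES:
                raise ConfigurationError(f"unknown block type {bt!r}")
        for sd in self.baseline_sd.values():
            if sd < 0:
                raise ConfigurationError("baseline_sd values must be >= 0")

    @property
    def axes(self) -> list:
        return sorted({BLOCK_TYPES[bt][0] for bt in self.effects})


def make_cohort(spec: CohortSpec, rng: np.random.Generator) -> list:
    """Draw a deterministic cohort of observers from a cohort spec."""
    observers = []
    for i in range(spec.n_subjects):
        subject_id = f"s{i + 1:02d}"
        sigma = {}
        baseline = {}
        for axis in spec.axes:
            if axis not in spec.sigma:
                raise ConfigurationError(f"cohort spec lacks a sigma spec for axis {axis!r}")
            sigma[axis] = spec.sigma[axis].draw(rng)
            bsd = spec.baseline_sd.get(axis, 0.0)
            baseline[axis] = rng.normal(0.0, bsd) if bsd > 0 else 0.0
        pse = {(axis, "control"): baseline[axis] for axis in spec.axes}
        for block_type, effect in spec.effects.items():
            axis, visual = BLOCK_TYPES[block_type]
            subject_effect = rng.normal(effect.mean, effect.sd) if effect.sd > 0 else effect.mean
            pse[(axis, f"{visual}_left")] = baseline[axis] + subject_effect / 2.0
            pse[(axis, f"{visual}_right")] = baseline[axis] - subject_effect / 2.0
        observers.append(
            ObserverModel(
                subject_id=subject_id,
                pse=pse,
                sigma=sigma,
                lapse=spec.lapse,
                p_none=spec.p_none,
            )
        )
    return observers
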