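"""End-to-end simulated sessions and group-level analysis.

A session runs one subject through experimental blocks (two interleaved
25-trial staircases, one per visual-stimulus direction) and their matched
control blocks (a single 25-trial staircase), producing a tidy trial log.
Analysis fits a cumulative Gaussian per block x condition, bootstraps the
PSE, and compares the left- and right-visual conditions of each
experimental block.  Group summaries average the per-subject left-minus-
right differences per block type and attach a subject-level bootstrap
p-value, plus pooled threshold (sigma) summaries per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .observer import BLOCK_TYPES, ConfigurationError, ObserverModel
from .psychometric import (
    ConditionComparison,
    PsychometricFit,
    ResampleDistribution,
    compare,
    fit_cdf,
    resample,
)
from .staircase import BlockDesign, Response, StaircaseConfig, run_block

__all__ = [
    "make_block_designs",
    "simulate_session",
    "simulate_cohort",
    "analyze_session",
    "group_summary",
    "SessionResult",
    "GroupBlockStat",
    "GroupSummary",
]

AXIS_UNITS = {"sway": "cm/s", "yaw": "deg/s"}

TRIAL_COLUMNS = [
    "subject_id", "block_label", "block_type", "axis", "condition",
    "staircase_id", "trial_index", "event_index", "stimulus", "units",
    "response", "run_violation",
]


def make_block_designs(
    block_types: Sequence[str] = tuple(BLOCK_TYPES),
    *,
    n_steps: int = 25,
    initial_step: float = 4.0,
    min_step: float = 0.25,
    max_step: float = 4.0,
    magnitude_limit: float = 10.0,
    duration: float = 1.0,
    max_run: int = 5,
    include_controls: bool = True,
) -> list:
    """Experimental + control block designs for the requested block types.

    Each experimental staircase starts at the platform maximum on the side
    of its own visual condition (left-visual staircase at -limit); control
    staircases start at +limit.
    """
    def config(start: float) -> StaircaseConfig:
        return StaircaseConfig(
            initial_magnitude=start,
            initial_step=initial_step,
            min_step=min_step,
            max_step=max_step,
            n_steps=n_steps,
            magnitude_limit=magnitude_limit,
        )

    designs = []
    for block_type in block_types:
        if block_type not in BLOCK_TYPES:
            raise ConfigurationError(f"unknown block type {block_type!r}")
        axis, visual = BLOCK_TYPES[block_type]
        left, right = f"{visual}_left", f"{visual}_right"
        designs.append(
            BlockDesign(
                block_label=block_type,
                block_type=block_type,
                axis=axis,
                conditions={left: left, right: right},
                configs={left: config(-magnitude_limit), right: config(+magnitude_limit)},
                max_run=max_run,
                duration=duration,
            )
        )
        if include_controls:
            designs.append(
                BlockDesign(
                    block_label=f"{block_type}_control",
                    block_type=block_type,
                    axis=axis,
                    conditions={"control": "control"},
                    configs={"control": config(+magnitude_limit)},
                    max_run=max_run,
                    duration=duration,
                )
            )
    return designs


def simulate_session(
    designs: Sequence[BlockDesign],
    observer: ObserverModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run one observer through all blocks; returns the tidy trial log.

    Counted trials per block always total the design's ``n_trials``
    regardless of no-response events.
    """
    rows = []
    for design in designs:
        # fail fast if the observer lacks a required condition
        for condition in design.conditions.values():
            observer.condition_pse(design.axis, condition)
        respond = observer.responder(design.axis, rng)
        counts = {sid: 0 for sid in design.conditions}
        event_index = 0
        for trial, response in run_block(design, respond, rng):
            event_index += 1
            if trial.counted:
                counts[trial.staircase_id] += 1
            rows.append(
                {
                    "subject_id": observer.subject_id,
                    "block_label": design.block_label,
                    "block_type": design.block_type,
                    "axis": design.axis,
                    "condition": trial.condition,
                    "staircase_id": trial.staircase_id,
                    "trial_index": counts[trial.staircase_id] if trial.counted else -1,
                    "event_index": event_index,
                    "stimulus": trial.velocity,
                    "units": AXIS_UNITS[design.axis],
                    "response": response.value,
                    "run_violation": trial.run_violation,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_cohort(
    designs: Sequence[BlockDesign],
    observers: Iterable[ObserverModel],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Concatenate per-subject session logs (one shared rng, in order)."""
    logs = [simulate_session(designs, obs, rng) for obs in observers]
    if not logs:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(logs, ignore_index=True)


@dataclass
class SessionResult:
    """Per-subject analysis output: fits, bootstrap distributions, comparisons."""

    subject_id: str
    fits: dict          # (block_label, condition) -> PsychometricFit
    resamples: dict     # (block_label, condition) -> ResampleDistribution
    comparisons: dict   # block_label -> ConditionComparison
    block_axis: dict    # block_label -> axis
    block_type: dict    # block_label -> block type
    flags: dict = field(default_factory=dict)


def analyze_session(
    trial_log: pd.DataFrame,
    *,
    n_resamples: int = 2000,
    seed: int = 0,
    lapse: float = 0.0,
    sigma_floor: float = 0.01,
    confidence: float = 0.95,
    expected_steps: Optional[int] = 25,
) -> list:
    """Analyze a trial log; returns one :class:`SessionResult` per subject.

    Only counted trials (``trial_index >= 0``) with LEFT/RIGHT responses
    enter the fits.  Bootstrap seeds derive deterministically from ``seed``
    and the sorted (subject, block, condition) key, so re-analysis of the
    same log reproduces identical output.
    """
    log = trial_log[trial_log["trial_index"] >= 0]
    results = []
    for subject_id in sorted(log["subject_id"].unique()):
        sub = log[log["subject_id"] == subject_id]
        fits: dict = {}
        dists: dict = {}
        comparisons: dict = {}
        block_axis: dict = {}
        block_type: dict = {}
        flags: dict = {"degenerate": [], "incomplete": [], "run_violations": 0}
        flags["run_violations"] = int(
            trial_log[(trial_log["subject_id"] == subject_id)]["run_violation"].sum()
        )
        for block_label in sorted(sub["block_label"].unique()):
            blk = sub[sub["block_label"] == block_label]
            block_axis[block_label] = blk["axis"].iloc[0]
            block_type[block_label] = blk["block_type"].iloc[0]
            for condition in sorted(blk["condition"].unique()):
                trials = blk[blk["condition"] == condition]
                if expected_steps is not None and len(trials) < expected_steps:
                    flags["incomplete"].append((block_label, condition, len(trials)))
                key = (block_label, condition)
                child = np.random.default_rng(
                    np.random.SeedSequence(
                        [seed, _stable_key(subject_id, block_label, condition)]
                    )
                )
                x = trials["stimulus"].to_numpy()
                y = trials["response"].to_numpy()
                fit = fit_cdf(x, y, lapse=lapse, sigma_floor=sigma_floor)
                fits[key] = fit
                if fit.degenerate:
                    flags["degenerate"].append(key)
                dists[key] = resample(
                    x, y, n_resamples=n_resamples, rng=child,
                    lapse=lapse, sigma_floor=sigma_floor, confidence=confidence,
                )
            conditions = sorted(blk["condition"].unique())
            left = [c for c in conditions if c.endswith("_left")]
            right = [c for c in conditions if c.endswith("_right")]
            if left and right:
                comparisons[block_label] = compare(
                    dists[(block_label, left[0])],
                    dists[(block_label, right[0])],
                    confidence=confidence,
                )
        results.append(
            SessionResult(
                subject_id=subject_id,
                fits=fits,
                resamples=dists,
                comparisons=comparisons,
                block_axis=block_axis,
                block_type=block_type,
                flags=flags,
            )
        )
    return results


def _stable_key(*parts: str) -> int:
    """Deterministic non-cryptographic hash of string parts into [0, 2^31)."""
    h = 2166136261
    for part in parts:
        for byte in str(part).encode():
            h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h % (2**31)


@dataclass(frozen=True)
class GroupBlockStat:
    """Group statistic for one block type (Table-1-style row)."""

    block_type: str
    axis: str
    n_subjects: int
    mean_difference: float
    p_value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    per_subject: tuple  # (subject_id, difference, p_two_sided, significant)


@dataclass(frozen=True)
class GroupSummary:
    blocks: dict        # block_type -> GroupBlockStat
    thresholds: dict    # axis -> dict(mean=, sd=, n=)


def group_summary(
    session_results: Sequence[SessionResult],
    *,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> GroupSummary:
    """Across-subject means of the left-minus-right PSE differences.

    The group p-value per block type is a subject-level bootstrap: subjects
    are resampled with replacement ``n_boot`` times, the mean difference is
    recomputed, and ``p = 2 * min(f, 1-f)`` with ``f`` the fraction of
    bootstrap means <= 0 (continuity floor ``1/(n_boot+1)``).  With a single
    subject the group p is undefined (None).  Threshold summaries pool
    fitted sigmas per axis over all non-degenerate fits.
    """
    if not session_results:
        raise ValueError("no session results")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))

    by_type: dict = {}
    for res in session_results:
        for block_label, comparison in res.comparisons.items():
            bt = res.block_type[block_label]
            by_type.setdefault(bt, []).append(
                (res.subject_id, res.block_axis[block_label], comparison)
            )

    blocks = {}
    for bt in sorted(by_type):
        entries = by_type[bt]
        diffs = np.array([c.difference for _, _, c in entries])
        per_subject = tuple(
            (sid, c.difference, c.p_two_sided, c.p_two_sided < alpha)
            for sid, _, c in entries
        )
        if len(diffs) >= 2:
            idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
            boot_means = diffs[idx].mean(axis=1)
            f = float((boot_means < 0).mean() + 0.5 * (boot_means == 0).mean())
            p = 2.0 * min(f, 1.0 - f)
            p = min(1.0, max(p, 1.0 / (n_boot + 1)))
            lo, hi = np.quantile(boot_means, [0.025, 0.975])
            lo, hi = float(lo), float(hi)
        else:
            p, lo, hi = None, None, None
        blocks[bt] = GroupBlockStat(
            block_type=bt,
            axis=entries[0][1],
            n_subjects=len(diffs),
            mean_difference=float(diffs.mean()),
            p_value=p,
            ci_low=lo,
            ci_high=hi,
            per_subject=per_subject,
        )

    sigmas: dict = {}
    for res in session_results:
        for (block_label, _condition), fit in res.fits.items():
            if fit.degenerate:
                continue
            sigmas.setdefault(res.block_axis[block_label], []).append(fit.sigma)
    thresholds = {
        axis: {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n": len(vals),
        }
        for axis, vals in sorted(sigmas.items())
    }
    return GroupSummary(blocks=blocks, thresholds=thresholds)
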