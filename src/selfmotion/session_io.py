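"""Trial-log CSV schema, YAML configuration, and result serialization.

Trial logs are RFC-4180 CSV with a leading schema comment line
(``# schema: selfmotion.trials.v1``) and one row per stimulus presentation.
Counted trials carry a per-staircase ``trial_index`` starting at 1;
no-response (NONE) events carry ``trial_index = -1`` and never count toward
a staircase's step budget.  Stimulus magnitudes are signed peak velocities;
the ``units`` tag (cm/s for sway, deg/s for yaw) must be constant within a
block.
"""

from __future__ import annotations

import io as _io
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .observer import BLOCK_TYPES, CohortSpec, ConfigurationError, EffectSpec, SigmaSpec
from .pipeline import TRIAL_COLUMNS, GroupSummary, SessionResult

__all__ = [
    "SchemaError",
    "write_trial_log",
    "read_trial_log",
    "default_config",
    "load_config",
    "save_config",
    "cohort_spec_from_config",
    "fits_to_frame",
    "comparisons_to_frame",
    "group_to_frame",
]

TRIAL_SCHEMA = "selfmotion.trials.v1"
CONFIG_SCHEMA = "selfmotion.config.v1"


class SchemaError(ValueError):
    """A file does not conform to the declared schema."""


def _validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log is missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if unknown:
        raise SchemaError(f"trial log contains unknown columns: {unknown}")
    for (subject, block), grp in df.groupby(["subject_id", "block_label"], sort=False):
        units = grp["units"].unique()
        if len(units) > 1:
            raise SchemaError(
                f"mixed units {sorted(units)} within block {block!r} of subject {subject!r}"
            )
    counted = df[df["trial_index"] >= 0]
    for key, grp in counted.groupby(["subject_id", "block_label", "staircase_id"], sort=False):
        idx = grp["trial_index"].to_numpy()
        if not (np.diff(idx) > 0).all():
            raise SchemaError(f"trial_index not strictly increasing for staircase {key}")
    return df


def write_trial_log(records: pd.DataFrame, path) -> None:
    """Write a validated trial log as CSV with a schema header line."""
    df = _validate_trials(pd.DataFrame(records, columns=TRIAL_COLUMNS))
    buf = _io.StringIO()
    buf.write(f"# schema: {TRIAL_SCHEMA}\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV written by :func:`write_trial_log`."""
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("#") else 0
    if skip and TRIAL_SCHEMA not in first:
        raise SchemaError(f"unrecognised trial-log schema line: {first.strip()!r}")
    df = pd.read_csv(
        path,
        skiprows=skip,
        dtype={"response": str, "units": str, "condition": str},
    )
    df["run_violation"] = df["run_violation"].astype(bool) if "run_violation" in df else False
    return _validate_trials(df)


# ---------------------------------------------------------------------------
# configuration

def default_config() -> dict:
    """The shipped default experiment configuration.

    Effect presets carry the study-scale generative left-minus-right PSE
    differences per block type (cm/s or deg/s of peak velocity); threshold
    presets give the between-subject distribution of sigma per axis.
    """
    return {
        "schema": CONFIG_SCHEMA,
        "cohort": {
            "n_subjects": 13,
            "lapse": 0.0,
            "p_none": 0.005,
            "sigma": {
                "sway": {"mean": 1.1, "sd": 0.6, "floor": 0.2},
                "yaw": {"mean": 1.1, "sd": 0.7, "floor": 0.2},
            },
            "baseline_sd": {"sway": 0.5, "yaw": 1.0},
            "effects": {
                "star_sway": {"mean": -0.832, "sd": 0.5},
                "star_yaw": {"mean": -3.394, "sd": 1.5},
                "illusion_sway": {"mean": 0.0, "sd": 0.5},
                "illusion_yaw": {"mean": 0.0, "sd": 1.5},
                "arrow_sway": {"mean": 0.508, "sd": 0.5},
            },
        },
        "blocks": list(BLOCK_TYPES),
        "staircase": {
            "n_steps": 25,
            "initial_step": 4.0,
            "min_step": 0.25,
            "max_step": 4.0,
            "magnitude_limit": 10.0,
            "duration": 1.0,
            "max_run": 5,
        },
        "analysis": {
            "n_resamples": 2000,
            "confidence": 0.95,
            "group_bootstrap": 10000,
            "sigma_floor": 0.01,
            "lapse": 0.0,
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or cfg.get("schema") != CONFIG_SCHEMA:
        raise SchemaError(f"config must declare schema: {CONFIG_SCHEMA}")
    base = default_config()
    for section in ("cohort", "staircase", "analysis"):
        if section in cfg and not isinstance(cfg[section], dict):
            raise SchemaError(f"config section {section!r} must be a mapping")
    merged = _deep_merge(base, cfg)
    unknown = set(merged["blocks"]) - set(BLOCK_TYPES)
    if unknown:
        raise SchemaError(f"unknown block types in config: {sorted(unknown)}")
    return merged


def save_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def cohort_spec_from_config(cfg: Mapping) -> CohortSpec:
    cohort = cfg["cohort"]
    try:
        sigma = {axis: SigmaSpec(**spec) for axis, spec in cohort["sigma"].items()}
        effects = {
            bt: EffectSpec(**spec)
            for bt, spec in cohort["effects"].items()
            if bt in cfg["blocks"]
        }
    except TypeError as exc:
        raise SchemaError(f"malformed cohort spec: {exc}") from exc
    return CohortSpec(
        n_subjects=int(cohort["n_subjects"]),
        sigma=sigma,
        effects=effects,
        baseline_sd=dict(cohort.get("baseline_sd", {})),
        lapse=float(cohort.get("lapse", 0.0)),
        p_none=float(cohort.get("p_none", 0.0)),
    )


# ---------------------------------------------------------------------------
# result tables

def fits_to_frame(results: Sequence[SessionResult]) -> pd.DataFrame:
    """One row per subject x block x condition with fit and bootstrap CI."""
    rows = []
    for res in results:
        for (block_label, condition), fit in res.fits.items():
            dist = res.resamples[(block_label, condition)]
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "block_label": block_label,
                    "block_type": res.block_type[block_label],
                    "axis": res.block_axis[block_label],
                    "condition": condition,
                    "mu": fit.mu,
                    "sigma": fit.sigma,
                    "n_trials": fit.n_trials,
                    "log_likelihood": fit.log_likelihood,
                    "converged": fit.converged,
                    "degenerate": fit.degenerate,
                    "mu_boot_mean": dist.mean,
                    "mu_boot_sd": dist.sd,
                    "ci_low": dist.ci_low,
                    "ci_high": dist.ci_high,
                }
            )
    return pd.DataFrame(rows)


def comparisons_to_frame(results: Sequence[SessionResult]) -> pd.DataFrame:
    """One row per subject x experimental block: the left-right statistic."""
    rows = []
    for res in results:
        for block_label, cmp_ in res.comparisons.items():
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "block_label": block_label,
                    "block_type": res.block_type[block_label],
                    "axis": res.block_axis[block_label],
                    "mu_left": cmp_.mu_left,
                    "mu_right": cmp_.mu_right,
                    "difference": cmp_.difference,
                    "p_two_sided": cmp_.p_two_sided,
                    "ci_low": cmp_.ci_low,
                    "ci_high": cmp_.ci_high,
                }
            )
    return pd.DataFrame(rows)


def group_to_frame(summary: GroupSummary) -> pd.DataFrame:
    """Table-1-style group rows: block type, mean difference, group p-value."""
    rows = []
    for bt, stat in summary.blocks.items():
        units = "cm/s" if stat.axis == "sway" else "deg/s"
        rows.append(
            {
                "block_type": bt,
                "axis": stat.axis,
                "units": units,
                "n_subjects": stat.n_subjects,
                "mean_difference": stat.mean_difference,
                "p_value": stat.p_value,
                "ci_low": stat.ci_low,
                "ci_high": stat.ci_high,
                "n_significant_subjects": sum(1 for s in stat.per_subject if s[3]),
            }
        )
    rows.extend(
        {
            "block_type": f"threshold_{axis}",
            "axis": axis,
            "units": "cm/s" if axis == "sway" else "deg/s",
            "n_subjects": stats["n"],
            "mean_difference": stats["mean"],
            "p_value": None,
            "ci_low": None,
            "ci_high": None,
            "n_significant_subjects": None,
        }
        for axis, stats in summary.thresholds.items()
    )
    return pd.DataFrame(rows)
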