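"""Session/config serialization: the session CSV dialect, run-config JSON,
and fit-result JSON.

Session CSV columns (one row per trial; header mandatory; all angle columns
carry a ``_deg`` suffix to prevent unit drift)::

    participant_id, group_bias_deg, phi_deg, trial_index, phase,
    opt1_dir, opt2_dir, opt3_dir, chosen_dir, reach_angle_deg,
    perturbation_deg, feedback_error_deg, feedback_given

Directions lie in [0, 360); signed quantities in (-180, 180]. Probe rows have
empty perturbation/feedback fields; single-target (training/probe) rows leave
opt2/opt3 empty. Floats are written at full (round-trip) precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .fitting import FitResult
from .reach import ReachParams
from .selection import SelectionParams
from .task import PHASE_CHOICE, PHASE_PROBE, PHASE_TRAINING, Session, TaskConfig, Trial

SESSION_COLUMNS = [
    "participant_id",
    "group_bias_deg",
    "phi_deg",
    "trial_index",
    "phase",
    "opt1_dir",
    "opt2_dir",
    "opt3_dir",
    "chosen_dir",
    "reach_angle_deg",
    "perturbation_deg",
    "feedback_error_deg",
    "feedback_given",
]

_PHASES = (PHASE_TRAINING, PHASE_CHOICE, PHASE_PROBE)


def write_sessions(sessions: Sequence[Session], path) -> None:
    """Write sessions to one CSV file (lossless round trip of trial fields)."""
    rows = []
    for sess in sessions:
        for t in sess.trials:
            # single-target trials store the target in opt1, leave opt2/3 empty
            opts = t.option_directions or (t.chosen_direction, np.nan, np.nan)
            rows.append(
                {
                    "participant_id": sess.participant_id,
                    "group_bias_deg": sess.alpha,
                    "phi_deg": sess.phi,
                    "trial_index": t.index,
                    "phase": t.phase,
                    "opt1_dir": opts[0],
                    "opt2_dir": opts[1],
                    "opt3_dir": opts[2],
                    "chosen_dir": t.chosen_direction,
                    "reach_angle_deg": t.reach_angle_deg,
                    "perturbation_deg": t.perturbation_deg,
                    "feedback_error_deg": t.feedback_error_deg,
                    "feedback_given": t.feedback_given,
                }
            )
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def _check(cond: bool, row: int, column: str, message: str) -> None:
    if not cond:
        raise ValueError(f"row {row}, column {column!r}: {message}")


def _valid_direction(x) -> bool:
    return np.isfinite(x) and 0.0 <= x < 360.0


def _valid_signed(x) -> bool:
    return np.isfinite(x) and -180.0 < x <= 180.0


def read_sessions(path) -> List[Session]:
    """Read and validate a session CSV; returns one Session per participant.

    The experiment protocol (1 or 2) is inferred from the presence of a
    training phase; provenance is marked empirical (true parameters are not
    part of the on-disk dialect).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header: missing columns {missing}")

    sessions = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial_index")
        bias = float(grp["group_bias_deg"].iloc[0])
        phi = float(grp["phi_deg"].iloc[0])
        trials = []
        for ridx, row in grp.iterrows():
            phase = row["phase"]
            _check(phase in _PHASES, ridx, "phase", f"unknown phase {phase!r}")
            chosen = float(row["chosen_dir"])
            _check(_valid_direction(chosen), ridx, "chosen_dir", f"direction out of [0, 360): {chosen}")
            fb = bool(row["feedback_given"])
            if phase == PHASE_CHOICE:
                opts = tuple(float(row[c]) for c in ("opt1_dir", "opt2_dir", "opt3_dir"))
                for c, o in zip(("opt1_dir", "opt2_dir", "opt3_dir"), opts):
                    _check(_valid_direction(o), ridx, c, f"direction out of [0, 360): {o}")
            else:
                opts = None
            pert = float(row["perturbation_deg"])
            err = float(row["feedback_error_deg"])
            if phase == PHASE_PROBE:
                _check(np.isnan(pert), ridx, "perturbation_deg", "probe rows must be empty")
                _check(np.isnan(err), ridx, "feedback_error_deg", "probe rows must be empty")
                _check(not fb, ridx, "feedback_given", "probe rows must have feedback_given = False")
            else:
                _check(_valid_signed(pert), ridx, "perturbation_deg", f"signed angle out of (-180, 180]: {pert}")
                _check(_valid_signed(err), ridx, "feedback_error_deg", f"signed angle out of (-180, 180]: {err}")
                _check(fb, ridx, "feedback_given", "feedback trials must have feedback_given = True")
            y = float(row["reach_angle_deg"])
            _check(np.isfinite(y), ridx, "reach_angle_deg", "must be finite")
            trials.append(Trial(int(row["trial_index"]), phase, opts, chosen, y, pert, err, fb))

        phases = {t.phase for t in trials}
        experiment = 2 if PHASE_TRAINING in phases else 1
        config = TaskConfig(
            experiment=experiment,
            bias_angle_deg=bias,
            least_noisy_direction_deg=phi,
            n_choice_trials=sum(t.phase == PHASE_CHOICE for t in trials),
            n_training_trials=sum(t.phase == PHASE_TRAINING for t in trials),
        )
        sessions.append(Session(str(pid), config, trials, provenance="empirical"))
    return sessions


# ---------------------------------------------------------------------------
# Run configuration (JSON, schema-validated, unknown keys rejected)
# ---------------------------------------------------------------------------


class TaskSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    experiment: int = 1
    bias_angle_deg: float = 0.0
    least_noisy_direction_deg: Optional[float] = None
    noise_halfwidth_slope: float = 1.0 / 6.0
    n_choice_trials: Optional[int] = None
    n_training_trials: Optional[int] = None

    def to_task_config(self) -> TaskConfig:
        extra = {}
        if self.n_choice_trials is not None:
            extra["n_choice_trials"] = self.n_choice_trials
        if self.experiment == 2 and self.n_training_trials is not None:
            extra["n_training_trials"] = self.n_training_trials
        cls = TaskConfig.experiment1 if self.experiment == 1 else TaskConfig.experiment2
        return cls(
            self.bias_angle_deg,
            least_noisy_direction_deg=self.least_noisy_direction_deg,
            noise_halfwidth_slope=self.noise_halfwidth_slope,
            **extra,
        )


class ReachSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a: float = 0.986
    b: float = 0.048
    l: float = 0.46

    def to_params(self) -> ReachParams:
        return ReachParams(self.a, self.b, self.l)


class SelectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    eta: float = 0.039
    lam: float = 0.80
    beta: float = 0.15
    variant: str = "loss"

    def to_params(self) -> SelectionParams:
        return SelectionParams(self.eta, self.lam, self.beta, self.variant)


class FittingSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_restarts: int = 50
    reach_bounds: Optional[List[Tuple[float, float]]] = None
    selection_bounds: Optional[List[Tuple[float, float]]] = None


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    groups: List[Tuple[float, int]] = Field(default_factory=lambda: [(0.0, 1)])
    n_runs_per_participant: int = 1


class RunConfig(BaseModel):
    """Top-level JSON run configuration."""

    model_config = ConfigDict(extra="forbid")
    task: TaskSettings = Field(default_factory=TaskSettings)
    reach: ReachSettings = Field(default_factory=ReachSettings)
    selection: SelectionSettings = Field(default_factory=SelectionSettings)
    fitting: FittingSettings = Field(default_factory=FittingSettings)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    seed: int = 0


def load_run_config(path) -> RunConfig:
    return RunConfig.model_validate_json(Path(path).read_text())


def save_run_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# Fit results (JSON)
# ---------------------------------------------------------------------------


def fit_result_to_dict(result: FitResult) -> dict:
    d = dataclasses.asdict(result)
    d["params"] = dataclasses.asdict(result.params)
    d["param_type"] = type(result.params).__name__
    return d


def write_fit_result(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(result), indent=2))


def read_fit_result(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    ptype = d.pop("param_type")
    params = ReachParams(**d["params"]) if ptype == "ReachParams" else SelectionParams(**d["params"])
    d["params"] = params
    return FitResult(**d)
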