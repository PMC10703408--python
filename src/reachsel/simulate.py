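"""Closed-loop agent-environment simulation: the synthetic-data generator.

A simulated session couples the reach-adaptation model and a target-selection
model inside the task environment, recursively feeding model-generated
choices and reach angles back into both learners. Sessions carry their
ground-truth parameters and seed, so they serve as the substrate for
parameter-recovery and model-comparison experiments.

``POOLED_REACH_PARAMS`` / ``POOLED_SELECTION_PARAMS`` are the group-pooled
behavioral estimates (a = 0.986, b = 0.048, l = 0.46; eta = 0.039,
lambda = 0.80, beta = 0.15) used as the default study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .circular import wrap_signed
from .reach import ReachParams, decay_only, init_reach_state, plan_reach, reach_update
from .selection import (
    SelectionParams,
    choice_probabilities,
    init_selection_state,
    sample_choice,
    selection_update,
)
from .task import (
    PHASE_CHOICE,
    PHASE_PROBE,
    PHASE_TRAINING,
    Session,
    TaskConfig,
    Trial,
    build_protocol,
    sample_perturbation,
)

POOLED_REACH_PARAMS = ReachParams(a=0.986, b=0.048, l=0.46)
POOLED_SELECTION_PARAMS = SelectionParams(eta=0.039, lam=0.80, beta=0.15, variant="loss")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort.

    ``groups`` lists (bias_angle_deg, n_participants) pairs; every participant
    is simulated ``n_runs_per_participant`` times with an independent seed and
    a freshly drawn least-noisy direction phi (unless ``phi`` pins it).
    """

    groups: Tuple[Tuple[float, int], ...]
    reach_params: ReachParams
    selection_params: SelectionParams
    n_runs_per_participant: int = 1
    experiment: int = 1
    master_seed: int = 0
    phi: Optional[float] = None
    grid_resolution: float = 1.0
    n_choice_trials: Optional[int] = None  # override protocol defaults
    n_training_trials: Optional[int] = None

    def __post_init__(self):
        if not self.groups:
            raise ValueError("groups must be non-empty")
        if any(n <= 0 for _, n in self.groups):
            raise ValueError("participant counts must be positive")
        if self.n_runs_per_participant <= 0:
            raise ValueError("n_runs_per_participant must be positive")


def run_session(
    reach_params: ReachParams,
    selection_params: SelectionParams,
    config: TaskConfig,
    seed: int,
    participant_id: str = "sim",
    grid_resolution: float = 1.0,
) -> Session:
    """Simulate one full session of the configured experiment.

    Per choice trial: sample the option triplet orientation, compute softmax
    choice probabilities from the selection state, sample the choice, plan the
    reach from the adaptation state, draw the perturbation, observe the signed
    feedback error and loss, then update both learners. Training trials (Exp 2)
    engage only the reach learner with the noise-free bias. Probe trials record
    the planned reach and let the adaptation state decay without updating.
    """
    rng = np.random.default_rng(seed)
    if config.least_noisy_direction_deg is None:
        config = config.with_phi(rng.uniform(0.0, 360.0))
    stubs = build_protocol(config, rng)

    reach_state = init_reach_state(reach_params, grid_resolution)
    sel_state = init_selection_state(selection_params, grid_resolution)

    trials = []
    for i, stub in enumerate(stubs, start=1):
        if stub.phase == PHASE_CHOICE:
            opts = np.asarray(stub.option_directions)
            probs = choice_probabilities(sel_state, opts)
            idx = sample_choice(probs, rng)
            theta = float(opts[idx])
            y = plan_reach(reach_state, theta)
            p = sample_perturbation(config, theta, rng)
            err = float(wrap_signed(y + p))
            reach_state = reach_update(reach_state, theta, p)
            sel_state = selection_update(
                sel_state,
                theta,
                observed_loss=abs(err),
                observed_signed_error=err,
                observed_perturbation=p,
            )
            trials.append(
                Trial(i, PHASE_CHOICE, tuple(opts), theta, y, p, err, True)
            )
        elif stub.phase == PHASE_TRAINING:
            theta = stub.target_direction
            y = plan_reach(reach_state, theta)
            p = float(config.bias_angle_deg)  # bias only, no noise during training
            err = float(wrap_signed(y + p))
            reach_state = reach_update(reach_state, theta, p)
            trials.append(Trial(i, PHASE_TRAINING, None, theta, y, p, err, True))
        else:  # probe: no feedback, decay only
            theta = stub.target_direction
            y = plan_reach(reach_state, theta)
            reach_state = decay_only(reach_state)
            trials.append(
                Trial(i, PHASE_PROBE, None, theta, y, float("nan"), float("nan"), False)
            )

    return Session(
        participant_id=participant_id,
        config=config,
        trials=trials,
        provenance="simulated",
        true_params={
            "reach": {"a": reach_params.a, "b": reach_params.b, "l": reach_params.l},
            "selection": {
                "eta": selection_params.eta,
                "lam": selection_params.lam,
                "beta": selection_params.beta,
                "variant": selection_params.variant,
            },
        },
        seed=int(seed),
    )


def derive_run_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-run seeds from a master seed (each < 2**31)."""
    return np.random.SeedSequence(master_seed).generate_state(n) & 0x7FFFFFFF


def simulate_cohort(spec: CohortSpec) -> list:
    """Simulate all runs of a cohort; one Session per (group, participant, run)."""
    total = sum(n for _, n in spec.groups) * spec.n_runs_per_participant
    seeds = derive_run_seeds(spec.master_seed, total)
    sessions = []
    k = 0
    overrides = {}
    if spec.n_choice_trials is not None:
        overrides["n_choice_trials"] = spec.n_choice_trials
    if spec.n_training_trials is not None and spec.experiment == 2:
        overrides["n_training_trials"] = spec.n_training_trials
    for bias, n_participants in spec.groups:
        if spec.experiment == 1:
            config = TaskConfig.experiment1(bias, least_noisy_direction_deg=spec.phi, **overrides)
        else:
            config = TaskConfig.experiment2(bias, least_noisy_direction_deg=spec.phi, **overrides)
        for p_idx in range(n_participants):
            for r_idx in range(spec.n_runs_per_participant):
                pid = f"g{bias:g}_p{p_idx}_r{r_idx}"
                sessions.append(
                    run_session(
                        spec.reach_params,
                        spec.selection_params,
                        config,
                        seed=int(seeds[k]),
                        participant_id=pid,
                        grid_resolution=spec.grid_resolution,
                    )
                )
                k += 1
    return sessions
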