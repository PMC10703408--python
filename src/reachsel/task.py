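"""Task environment: trial schedules and the bias + direction-dependent-noise
perturbation process.

The paradigm is a center-out reaching task with a visuomotor rotation applied
between hand and cursor. The rotation on trial t is

    p_t = alpha + eps_t,    eps_t ~ U[-delta_t * s, +delta_t * s],

where ``alpha`` is a constant bias angle, ``delta_t`` is the absolute angular
distance of the selected target from a per-participant least-noisy direction
``phi``, and ``s`` is the noise half-width slope (1/6 degrees of half-width
per degree of distance, so the noise half-width reaches its 30-degree maximum
at delta = 180).

Two protocols are supported:

* Experiment 1 - 400 choice trials (three targets spaced 120 degrees at a
  uniformly random orientation) followed by 24 no-feedback probe trials
  (8 equally spaced directions x 3 repetitions, shuffled).
* Experiment 2 - 200 single-target training trials (uniformly random
  direction, bias only, no noise), then 200 choice trials, then 24 probes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .circular import abs_angular_distance, wrap_direction, wrap_signed

PHASE_TRAINING = "training"
PHASE_CHOICE = "choice"
PHASE_PROBE = "probe"


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the task environment.

    ``least_noisy_direction_deg`` may be None, in which case the simulator
    draws phi uniformly per session (the study's per-participant convention).
    """

    experiment: int
    bias_angle_deg: float
    least_noisy_direction_deg: Optional[float] = None
    noise_halfwidth_slope: float = 1.0 / 6.0
    n_choice_trials: int = 400
    n_training_trials: int = 0
    probe_directions: int = 8
    probe_reps: int = 3
    n_options: int = 3
    option_spacing_deg: float = 120.0

    def __post_init__(self):
        if self.experiment not in (1, 2):
            raise ValueError(f"experiment must be 1 or 2, got {self.experiment}")
        if abs(self.n_options * self.option_spacing_deg - 360.0) > 1e-9:
            raise ValueError("option spacing times option count must equal 360")
        if self.noise_halfwidth_slope < 0:
            raise ValueError("noise_halfwidth_slope must be non-negative")
        if self.n_choice_trials < 0 or self.n_training_trials < 0:
            raise ValueError("trial counts must be non-negative")
        if self.least_noisy_direction_deg is not None and not (
            0.0 <= self.least_noisy_direction_deg < 360.0
        ):
            raise ValueError("least_noisy_direction_deg must lie in [0, 360)")

    @classmethod
    def experiment1(cls, bias_angle_deg: float, **kwargs) -> "TaskConfig":
        """Standard Experiment 1: 400 choice + 24 probe trials."""
        kwargs.setdefault("n_choice_trials", 400)
        return cls(experiment=1, bias_angle_deg=bias_angle_deg, **kwargs)

    @classmethod
    def experiment2(cls, bias_angle_deg: float = 40.0, **kwargs) -> "TaskConfig":
        """Standard Experiment 2: 200 training + 200 choice + 24 probe trials."""
        kwargs.setdefault("n_choice_trials", 200)
        kwargs.setdefault("n_training_trials", 200)
        return cls(experiment=2, bias_angle_deg=bias_angle_deg, **kwargs)

    @property
    def n_probe_trials(self) -> int:
        return self.probe_directions * self.probe_reps

    @property
    def n_trials(self) -> int:
        return self.n_training_trials + self.n_choice_trials + self.n_probe_trials

    def with_phi(self, phi: float) -> "TaskConfig":
        return replace(self, least_noisy_direction_deg=float(wrap_direction(phi)))


@dataclass
class Trial:
    """One trial record.

    ``reach_angle_deg`` is the signed deviation of the hand endpoint from the
    selected target direction. ``feedback_error_deg`` is the signed cursor
    error R_t = wrap(y_t + p_t); its absolute value is the loss L_t. Probe
    trials carry no perturbation or feedback (NaN fields, feedback_given
    False).
    """

    index: int
    phase: str
    option_directions: Optional[tuple]  # 3 directions on choice trials, else None
    chosen_direction: float
    reach_angle_deg: float
    perturbation_deg: float  # NaN on probe trials
    feedback_error_deg: float  # NaN on probe trials
    feedback_given: bool

    @property
    def loss_deg(self) -> float:
        return abs(self.feedback_error_deg)


@dataclass
class Session:
    """Ordered trials of one participant (empirical or simulated)."""

    participant_id: str
    config: TaskConfig
    trials: list
    provenance: str = "simulated"  # or "empirical"
    true_params: Optional[dict] = None
    seed: Optional[int] = None

    @property
    def phi(self) -> float:
        return self.config.least_noisy_direction_deg

    @property
    def alpha(self) -> float:
        return self.config.bias_angle_deg

    def by_phase(self, phase: str) -> list:
        return [t for t in self.trials if t.phase == phase]

    @property
    def choice_trials(self) -> list:
        return self.by_phase(PHASE_CHOICE)

    @property
    def training_trials(self) -> list:
        return self.by_phase(PHASE_TRAINING)

    @property
    def probe_trials(self) -> list:
        return self.by_phase(PHASE_PROBE)


@dataclass(frozen=True)
class TrialStub:
    """Schedule entry: the phase and target geometry, before the agent acts."""

    phase: str
    option_directions: Optional[tuple] = None  # choice trials
    target_direction: Optional[float] = None  # training/probe trials


def sample_option_directions(rng: np.random.Generator) -> np.ndarray:
    """Three target directions spaced 120 degrees at a uniform orientation."""
    u = rng.uniform(0.0, 360.0)
    return wrap_direction(u + np.array([0.0, 120.0, 240.0]))


def sample_perturbation(
    config: TaskConfig, chosen_direction: float, rng: np.random.Generator
) -> float:
    """Draw p = alpha + eps with eps ~ U[-delta*s, +delta*s].

    delta is the absolute angular distance of the chosen target from the
    least-noisy direction phi; with the default slope 1/6 the noise half-width
    is at most 30 degrees (delta = 180).
    """
    if config.least_noisy_direction_deg is None:
        raise ValueError("config must carry a resolved least-noisy direction phi")
    delta = float(abs_angular_distance(chosen_direction, config.least_noisy_direction_deg))
    half_width = config.noise_halfwidth_slope * delta
    eps = rng.uniform(-half_width, half_width) if half_width > 0 else 0.0
    return float(wrap_signed(config.bias_angle_deg + eps))


def probe_direction_set(config: TaskConfig) -> np.ndarray:
    """The equally spaced probe directions (degrees)."""
    return np.arange(config.probe_directions) * (360.0 / config.probe_directions)


def build_protocol(config: TaskConfig, rng: np.random.Generator) -> list:
    """Generate the ordered trial schedule for the configured experiment.

    Experiment 1: choice trials then probes. Experiment 2: single-target
    training trials (uniform random directions) then choice trials then
    probes. Probe directions repeat ``probe_reps`` times in shuffled order.
    A pure function of (config, rng state).
    """
    stubs: list = []
    if config.experiment == 2:
        for _ in range(config.n_training_trials):
            stubs.append(
                TrialStub(PHASE_TRAINING, target_direction=float(rng.uniform(0.0, 360.0)))
            )
    elif config.n_training_trials:
        raise ValueError("training trials are only part of the Experiment 2 protocol")
    for _ in range(config.n_choice_trials):
        stubs.append(TrialStub(PHASE_CHOICE, option_directions=tuple(sample_option_directions(rng))))
    probes = np.repeat(probe_direction_set(config), config.probe_reps)
    for d in rng.permutation(probes):
        stubs.append(TrialStub(PHASE_PROBE, target_direction=float(d)))
    return stubs
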