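"""Trial-by-trial state-space model of reach adaptation with local
periodic-kernel generalization.

The learner maintains an estimate ``p_hat(theta)`` of the visuomotor
perturbation as a function of target direction and aims to counteract it:

    y_t = -p_hat_t(theta_t)                                  (planning)
    d_t = p_t - p_hat_t(theta_t)                             (prediction error)
    p_hat_{t+1}(theta) = a p_hat_t(theta) + b G(theta, theta_t) d_t   (update)

where ``a`` is a retention (decay) factor applied globally on every trial,
``b`` the learning rate, and ``G`` the periodic kernel with length-scale
``l`` that localizes learning around the practiced direction. On no-feedback
(probe) trials the estimate only decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import KernelSpec, periodic_kernel
from .grids import DirectionalFunction


@dataclass(frozen=True)
class ReachParams:
    """Reach-model parameters: retention ``a``, learning rate ``b``,
    generalization length-scale ``l`` (all dimensionless)."""

    a: float
    b: float
    l: float

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0):
            raise ValueError(f"decay factor a must lie in [0, 1], got {self.a}")
        if not (0.0 <= self.b <= 1.0):
            raise ValueError(f"learning rate b must lie in [0, 1], got {self.b}")
        if not (np.isfinite(self.l) and self.l > 0):
            raise ValueError(f"length-scale l must be positive, got {self.l}")

    @property
    def kernel(self) -> KernelSpec:
        return KernelSpec(self.l)


@dataclass
class ReachState:
    """Learner state: parameters plus the current perturbation estimate."""

    params: ReachParams
    estimate: DirectionalFunction

    def copy(self) -> "ReachState":
        return ReachState(self.params, self.estimate.copy())


def init_reach_state(params: ReachParams, grid_resolution: float = 1.0) -> ReachState:
    """Fresh state with p_hat identically zero (a calibrated learner)."""
    return ReachState(params, DirectionalFunction.zeros(grid_resolution))


def plan_reach(state: ReachState, target_direction: float) -> float:
    """Reach angle chosen to counteract the expected perturbation: -p_hat(theta)."""
    return -float(state.estimate.value_at(target_direction))


def reach_update(
    state: ReachState, target_direction: float, observed_perturbation: float
) -> ReachState:
    """Apply one feedback-trial update and return the new state.

    Decay and the kernel-weighted correction are applied in a single
    assignment; the prediction error is computed from the pre-update state.
    """
    if not np.isfinite(observed_perturbation):
        raise ValueError("observed_perturbation must be finite on a feedback trial")
    p = state.params
    d = observed_perturbation - state.estimate.value_at(target_direction)
    g = periodic_kernel(state.estimate.grid, target_direction, p.kernel)
    new_values = p.a * state.estimate.values + p.b * g * d
    return ReachState(p, DirectionalFunction(state.estimate.resolution, new_values))


def decay_only(state: ReachState) -> ReachState:
    """No-feedback trial: the estimate decays everywhere, no error update."""
    return ReachState(
        state.params,
        DirectionalFunction(state.estimate.resolution, state.params.a * state.estimate.values),
    )


def steady_state_residual(params: ReachParams, alpha: float) -> float:
    """Asymptotic uncompensated bias at a single practiced direction.

    With a constant perturbation ``alpha`` at one direction (kernel weight 1
    there), the fixed point of the update gives a residual error of

        alpha * (1 - a) / (1 - a + b).

    Undefined (raises) when a = 1 and b = 0 (no decay, no learning).
    """
    if params.a == 1.0 and params.b == 0.0:
        raise ValueError("steady state undefined for a = 1, b = 0")
    return alpha * (1.0 - params.a) / (1.0 - params.a + params.b)
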