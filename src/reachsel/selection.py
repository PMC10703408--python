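"""Reinforcement-based target-selection models with softmax choice.

Three variants share the same softmax policy over a learned per-direction
value function v(theta), with decision-noise parameter beta (units 1/degree,
value functions in degrees):

    P(choice = i) = exp(-beta v(theta_i)) / sum_j exp(-beta v(theta_j))

* ``loss``  - v = L_hat, the expected loss (absolute feedback error),
  delta-rule updated with learning rate eta and periodic kernel K
  (length-scale lambda): L_hat(theta) += eta K(theta, theta_t) (L_t - L_hat(theta_t)).
  L_hat is initialized to the first observed loss, equally for all directions.
* ``bias``  - v = |R_hat|, the expected *signed* feedback error, same delta
  rule on the signed error R_t; mirrors the loss variant's deferred
  initialization (a zero-init switch is provided).
* ``noise`` - v = S, a one-pass kernel-weighted estimate of the perturbation
  standard deviation per direction, tracking fractional sample counts N,
  running means M and SDs S (all initialized to zero):

      N+(theta) = N(theta) + K(theta, theta_t)
      M+(theta) = (N(theta) M(theta) + K(theta, theta_t) p_t) / N+(theta)
      S+^2(theta) = (N(theta) S^2(theta)
                     + K(theta, theta_t) (p_t - M+(theta_t)) (p_t - M(theta_t))) / N+(theta)

  With all trials at a single direction (K = 1 there) this reduces to
  Welford's algorithm and S equals the population SD of the observed
  perturbations.

Before a deferred-initialization variant has seen its first observation, the
value function is constant, so choice probabilities are uniform (1/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import softmax as _softmax

from .circular import KernelSpec, periodic_kernel
from .grids import DirectionalFunction

VARIANTS = ("loss", "bias", "noise")

#: Floor on the fractional sample count N to guard division underflow.
N_FLOOR = 1e-12


@dataclass(frozen=True)
class SelectionParams:
    """Selection-model parameters: learning rate ``eta``, kernel length-scale
    ``lam``, decision noise ``beta`` (1/degree), and the model ``variant``."""

    eta: float
    lam: float
    beta: float
    variant: str = "loss"

    def __post_init__(self):
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"learning rate eta must lie in [0, 1], got {self.eta}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"length-scale lam must be positive, got {self.lam}")
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"decision noise beta must be >= 0, got {self.beta}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @property
    def kernel(self) -> KernelSpec:
        return KernelSpec(self.lam)


@dataclass
class SelectionState:
    """Variant-dependent learner state.

    loss/bias: ``value`` holds L_hat or R_hat once initialized; ``initialized``
    is False during the deferred-initialization window.
    noise: ``n_fn``, ``m_fn``, ``s_fn`` hold N, M, S (always initialized).
    """

    params: SelectionParams
    value: Optional[DirectionalFunction] = None
    n_fn: Optional[DirectionalFunction] = None
    m_fn: Optional[DirectionalFunction] = None
    s_fn: Optional[DirectionalFunction] = None
    initialized: bool = False


def init_selection_state(
    params: SelectionParams, grid_resolution: float = 1.0, bias_zero_init: bool = False
) -> SelectionState:
    """Fresh state for the given variant.

    loss: deferred init (value set to the first observed loss, equally for all
    directions). bias: same deferred rule, or R_hat = 0 everywhere when
    ``bias_zero_init``. noise: N = M = S = 0 everywhere.
    """
    if params.variant == "noise":
        return SelectionState(
            params,
            n_fn=DirectionalFunction.zeros(grid_resolution),
            m_fn=DirectionalFunction.zeros(grid_resolution),
            s_fn=DirectionalFunction.zeros(grid_resolution),
            initialized=True,
        )
    if params.variant == "bias" and bias_zero_init:
        return SelectionState(
            params, value=DirectionalFunction.zeros(grid_resolution), initialized=True
        )
    # deferred: remember the grid resolution via an empty placeholder
    return SelectionState(
        params, value=DirectionalFunction.zeros(grid_resolution), initialized=False
    )


def option_values(state: SelectionState, option_directions) -> np.ndarray:
    """The value v(theta) entering the softmax, per option.

    Constant (zero) before deferred initialization, so probabilities are
    uniform on the first choice trial.
    """
    opts = np.asarray(option_directions, dtype=float)
    if state.params.variant == "noise":
        return np.asarray(state.s_fn.value_at(opts), dtype=float)
    if not state.initialized:
        return np.zeros(opts.shape)
    vals = np.asarray(state.value.value_at(opts), dtype=float)
    return np.abs(vals) if state.params.variant == "bias" else vals


def choice_probabilities(state: SelectionState, option_directions) -> np.ndarray:
    """Softmax choice probabilities over the (three) option directions."""
    opts = np.asarray(option_directions, dtype=float)
    if opts.size != 3:
        raise ValueError(f"expected exactly 3 options, got {opts.size}")
    v = option_values(state, opts)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite option values")
    return _softmax(-state.params.beta * v)


def sample_choice(probabilities, rng: np.random.Generator) -> int:
    """Sample an option index from a categorical distribution."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    return int(rng.choice(p.size, p=p / p.sum()))


def selection_update(
    state: SelectionState,
    chosen_direction: float,
    observed_loss: Optional[float] = None,
    observed_signed_error: Optional[float] = None,
    observed_perturbation: Optional[float] = None,
) -> SelectionState:
    """Apply one feedback choice-trial update; returns the new state.

    Only the observation relevant to the variant is required: the loss for
    ``loss``, the signed feedback error for ``bias``, the perturbation for
    ``noise``.
    """
    params = state.params
    if params.variant in ("loss", "bias"):
        obs = observed_loss if params.variant == "loss" else observed_signed_error
        name = "observed_loss" if params.variant == "loss" else "observed_signed_error"
        if obs is None or not np.isfinite(obs):
            raise ValueError(f"{name} must be finite for the {params.variant} variant")
        if not state.initialized:
            fn = DirectionalFunction.constant(float(obs), state.value.resolution)
            return SelectionState(params, value=fn, initialized=True)
        e = float(obs) - state.value.value_at(chosen_direction)
        k = periodic_kernel(state.value.grid, chosen_direction, params.kernel)
        new_values = state.value.values + params.eta * k * e
        fn = DirectionalFunction(state.value.resolution, new_values)
        return SelectionState(params, value=fn, initialized=True)

    # noise variant: one-pass kernel-weighted mean/SD of the perturbation
    if observed_perturbation is None or not np.isfinite(observed_perturbation):
        raise ValueError("observed_perturbation must be finite for the noise variant")
    p_t = float(observed_perturbation)
    n, m, s = state.n_fn, state.m_fn, state.s_fn
    k = periodic_kernel(n.grid, chosen_direction, params.kernel)
    n_new = n.values + k
    denom = np.maximum(n_new, N_FLOOR)
    m_old_at = m.value_at(chosen_direction)
    m_new_vals = (n.values * m.values + k * p_t) / denom
    m_new = DirectionalFunction(m.resolution, m_new_vals)
    m_new_at = m_new.value_at(chosen_direction)
    s2_new = (n.values * s.values**2 + k * (p_t - m_new_at) * (p_t - m_old_at)) / denom
    s_new = np.sqrt(np.clip(s2_new, 0.0, None))
    return SelectionState(
        params,
        n_fn=DirectionalFunction(n.resolution, n_new),
        m_fn=m_new,
        s_fn=DirectionalFunction(s.resolution, s_new),
        initialized=True,
    )
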