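"""Behavioral metrics, data-cleaning rules, and model-evaluation statistics.

Conventions
-----------
* *Reach angle error* is the signed deviation of the reach from the ideal
  fully-compensating angle, wrap(y_t + alpha). Summaries use the signed mean
  by default; the absolute variant backs threshold rules (good-learner
  classification).
* *Target selection error* (TSE) is the absolute angular distance of the
  chosen target from the least-noisy direction phi minus that of the closest
  available target; it ranges over [0, 120] for three options spaced 120
  degrees and is 0 iff the closest option was chosen.
* Change-in-TSE series are 10-trial-bin means with the first bin subtracted,
  so negative values indicate learning of phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import logsumexp

from .circular import (
    abs_angular_distance,
    circular_mean,
    circular_sd,
    fit_von_mises,
    wrap_direction,
    wrap_signed,
    VonMisesFit,
)
from .task import Session


@dataclass
class MetricSeries:
    """Per-bin metric values (degrees) in consecutive ``bin_size``-trial bins."""

    bin_size: int
    values: np.ndarray
    baseline_subtracted: bool = False


@dataclass(frozen=True)
class PFCResult:
    """Probabilistic fraction correct with its von Mises upper bound."""

    pfc: float
    window: int
    von_mises: VonMisesFit
    upper_bound: float


def reach_angle_error(reach_angle, alpha, signed: bool = True):
    """Signed (default) or absolute deviation from full compensation,
    wrap(y + alpha)."""
    err = wrap_signed(np.asarray(reach_angle, dtype=float) + alpha)
    return err if signed else np.abs(err)


def session_reach_angle_errors(session: Session, phase: Optional[str] = None,
                               signed: bool = True) -> np.ndarray:
    trials = session.trials if phase is None else session.by_phase(phase)
    y = np.array([t.reach_angle_deg for t in trials], dtype=float)
    return reach_angle_error(y, session.alpha, signed=signed)


def target_selection_error(option_directions, chosen_direction, phi) -> float:
    """|d(chosen, phi)| - min_i |d(option_i, phi)|, in [0, 120]."""
    opts = np.asarray(option_directions, dtype=float)
    if opts.size != 3:
        raise ValueError("expected exactly 3 option directions")
    dists = abs_angular_distance(opts, phi)
    d_chosen = abs_angular_distance(chosen_direction, phi)
    which = np.argmin(np.abs(wrap_signed(opts - chosen_direction)))
    if abs(wrap_signed(opts[which] - chosen_direction)) > 1e-6:
        raise ValueError("chosen direction is not among the options")
    return float(d_chosen - dists.min())


def session_tse(session: Session) -> np.ndarray:
    """Per-choice-trial target selection error."""
    return np.array(
        [
            target_selection_error(t.option_directions, t.chosen_direction, session.phi)
            for t in session.choice_trials
        ]
    )


def _bin_means(values: np.ndarray, bin_size: int) -> np.ndarray:
    n_bins = len(values) // bin_size  # partial final bins are dropped
    if n_bins < 1:
        raise ValueError(f"need at least {bin_size} trials, got {len(values)}")
    return values[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)


def change_in_tse(session: Session, bin_size: int = 10) -> MetricSeries:
    """Binned TSE with each participant's first-bin mean subtracted."""
    tse = session_tse(session)
    if len(tse) < 2 * bin_size:
        raise ValueError("need at least two full bins of choice trials")
    binned = _bin_means(tse, bin_size)
    return MetricSeries(bin_size, binned - binned[0], baseline_subtracted=True)


def preferred_direction(session: Session, window: int = 50) -> float:
    """Circular mean of the last ``window`` chosen target directions."""
    chosen = [t.chosen_direction for t in session.choice_trials]
    if len(chosen) < window:
        raise ValueError(f"need at least {window} choice trials, got {len(chosen)}")
    return circular_mean(chosen[-window:])


def probability_weighted_tse(
    session: Session,
    probabilities,
    bin_size: int = 10,
    align_first_bin_to: Optional[float] = None,
) -> MetricSeries:
    """Model-expected TSE: per-trial option TSEs weighted by the model's
    choice probabilities, binned; optionally shifted so the first bin matches
    an empirical baseline (for direct overlay on aligned empirical series)."""
    probs = np.asarray(probabilities, dtype=float)
    trials = session.choice_trials
    if probs.shape != (len(trials), 3):
        raise ValueError(f"probabilities must have shape ({len(trials)}, 3)")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    per_trial = np.empty(len(trials))
    for i, t in enumerate(trials):
        tses = [
            target_selection_error(t.option_directions, opt, session.phi)
            for opt in t.option_directions
        ]
        per_trial[i] = float(np.dot(probs[i], tses))
    binned = _bin_means(per_trial, bin_size)
    if align_first_bin_to is not None:
        binned = binned + (align_first_bin_to - binned[0])
    return MetricSeries(bin_size, binned, baseline_subtracted=False)


def probabilistic_fraction_correct(probabilities, chosen_indices, window: int = 50) -> float:
    """Geometric mean of model probabilities assigned to the actual choices
    over the last ``window`` choice trials."""
    probs = np.asarray(probabilities, dtype=float)
    idx = np.asarray(chosen_indices, dtype=int)
    if len(idx) < window:
        raise ValueError(f"need at least {window} choice trials, got {len(idx)}")
    p_chosen = probs[np.arange(len(idx)), idx][-window:]
    return float(np.exp(np.mean(np.log(np.maximum(p_chosen, 1e-300)))))


def von_mises_upper_bound(choices, option_triplets, window: int = 50) -> PFCResult:
    """Best achievable predictive performance from the chooser's own choice
    distribution.

    Fits a von Mises distribution to the last ``window`` chosen directions,
    converts its density at the three options of each trial into choice
    probabilities, and returns their geometric mean (computed in log space,
    so the capped-concentration path is overflow-safe). ``pfc`` in the result
    equals the upper bound here; pair with a model PFC for comparison.
    """
    chosen = np.asarray(choices, dtype=float)[-window:]
    opts = np.asarray(option_triplets, dtype=float)[-window:]
    if chosen.size < window:
        raise ValueError(f"need at least {window} choices, got {chosen.size}")
    vm = fit_von_mises(chosen)
    mu = 0.0 if np.isnan(vm.mu) else vm.mu
    log_f = vm.kappa * np.cos(np.radians(opts - mu))
    chosen_col = np.argmin(np.abs(wrap_signed(opts - chosen[:, None])), axis=1)
    log_p = log_f[np.arange(chosen.size), chosen_col] - logsumexp(log_f, axis=1)
    bound = float(np.exp(np.mean(log_p)))
    return PFCResult(pfc=bound, window=window, von_mises=vm, upper_bound=bound)


@dataclass
class WLSResult:
    slope: float
    p_value: float
    intercept: float
    weights: np.ndarray


def wls_goodness_of_fit(empirical, sim_runs: Sequence, bias_angles) -> WLSResult:
    """Weighted least-squares test of simulation-versus-data agreement.

    Regresses per-participant differences (empirical minus mean simulated
    value) on bias angle, weighting each participant by the inverse variance
    of their simulated runs. A slope indistinguishable from zero (large
    p-value) means the simulations track the empirical trend across bias
    angles; p < 0.05 rejects the model.
    """
    emp = np.asarray(empirical, dtype=float)
    bias = np.asarray(bias_angles, dtype=float)
    if len(np.unique(bias)) < 2:
        raise ValueError("need at least 2 distinct bias angles")
    sim_means = np.array([np.mean(r) for r in sim_runs])
    sim_vars = np.array([np.var(r, ddof=1) for r in sim_runs])
    if np.any(~(sim_vars > 0)):
        raise ValueError("zero variance across simulated runs; weights undefined")
    if len({len(emp), len(sim_means), len(bias)}) != 1:
        raise ValueError("empirical, sim_runs and bias_angles must align")
    diffs = emp - sim_means
    weights = 1.0 / sim_vars
    res = sm.WLS(diffs, sm.add_constant(bias), weights=weights).fit()
    return WLSResult(
        slope=float(res.params[1]),
        p_value=float(res.pvalues[1]),
        intercept=float(res.params[0]),
        weights=weights,
    )


def classify_good_learner(session: Session, threshold: float = 20.0, window: int = 50) -> bool:
    """True iff the mean absolute reach angle error over the last ``window``
    training trials is strictly below ``threshold`` (Experiment 2 only)."""
    if session.config.experiment != 2:
        raise ValueError("good-learner classification applies to Experiment 2 sessions")
    training = session.training_trials
    if len(training) < session.config.n_training_trials or len(training) < window:
        raise ValueError("session lacks the full training phase")
    y = np.array([t.reach_angle_deg for t in training[-window:]])
    return bool(np.mean(reach_angle_error(y, session.alpha, signed=False)) < threshold)


@dataclass
class ExclusionReport:
    excluded_participants: list = field(default_factory=list)
    dropped_trials: dict = field(default_factory=dict)


def apply_exclusions(
    sessions: Sequence[Session],
    sd_threshold: float = 12.0,
    sd_window: int = 20,
    trial_threshold: float = 60.0,
) -> tuple:
    """Participant- and trial-level data cleaning.

    A participant is excluded when the circular SD of their reach directions
    (hand endpoint direction = target + reach angle) is below ``sd_threshold``
    degrees in any ``sd_window`` consecutive trials, indicating reaching in a
    single direction regardless of target. Otherwise, trials whose hand
    endpoint deviates more than ``trial_threshold`` degrees from the selected
    target are dropped. Returns (kept sessions, report).
    """
    kept = []
    report = ExclusionReport()
    for sess in sessions:
        dirs = np.array(
            [wrap_direction(t.chosen_direction + t.reach_angle_deg) for t in sess.trials]
        )
        excluded = False
        for start in range(0, len(dirs) - sd_window + 1):
            if circular_sd(dirs[start : start + sd_window]) < sd_threshold:
                excluded = True
                break
        if excluded:
            report.excluded_participants.append(sess.participant_id)
            continue
        kept_trials = [
            t for t in sess.trials if abs(wrap_signed(t.reach_angle_deg)) <= trial_threshold
        ]
        n_dropped = len(sess.trials) - len(kept_trials)
        report.dropped_trials[sess.participant_id] = n_dropped
        if n_dropped:
            sess = Session(
                participant_id=sess.participant_id,
                config=sess.config,
                trials=kept_trials,
                provenance=sess.provenance,
                true_params=sess.true_params,
                seed=sess.seed,
            )
        kept.append(sess)
    return kept, report
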