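import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import reachsel as rs
from reachsel.metrics import (
    apply_exclusions,
    change_in_tse,
    classify_good_learner,
    preferred_direction,
    probabilistic_fraction_correct,
    probability_weighted_tse,
    reach_angle_error,
    session_tse,
    target_selection_error,
    von_mises_upper_bound,
    wls_goodness_of_fit,
)
from reachsel.task import PHASE_CHOICE, Session, TaskConfig, Trial


def _choice_trial(i, opts, chosen, y=0.0, pert=0.0):
    err = float(rs.wrap_signed(y + pert))
    return Trial(i, PHASE_CHOICE, tuple(opts), chosen, y, pert, err, True)


def make_choice_session(chosen_seq, opts_seq, phi=0.0, alpha=0.0, y_seq=None):
    y_seq = y_seq if y_seq is not None else [0.0] * len(chosen_seq)
    trials = [
        _choice_trial(i + 1, o, c, y) for i, (o, c, y) in enumerate(zip(opts_seq, chosen_seq, y_seq))
    ]
    config = TaskConfig.experiment1(
        alpha, least_noisy_direction_deg=phi, n_choice_trials=len(trials)
    )
    return Session("synthetic", config, trials)


def test_reach_angle_error_examples():
    assert reach_angle_error(-40.0, 40.0) == pytest.approx(0.0)
    assert reach_angle_error(0.0, 40.0) == pytest.approx(40.0)
    assert reach_angle_error(170.0, 40.0) == pytest.approx(-150.0)  # wraps
    assert reach_angle_error(-60.0, 40.0, signed=False) == pytest.approx(20.0)


def test_group_mean_reach_error_starts_at_bias_and_decreases(pooled_reach, pooled_selection):
    """For a 40-degree bias cohort at pooled parameters, the group-mean signed
    reach angle error starts near 40 and decreases across the session."""
    from reachsel.metrics import session_reach_angle_errors

    config = TaskConfig.experiment1(40.0)
    errs = []
    seeds = np.random.SeedSequence(31).generate_state(30) & 0x7FFFFFFF
    for s in seeds:
        sess = rs.run_session(pooled_reach, pooled_selection, config, seed=int(s))
        errs.append(session_reach_angle_errors(sess, phase=PHASE_CHOICE))
    mean_err = np.mean(errs, axis=0)
    assert mean_err[0] == pytest.approx(40.0, abs=1.0)
    assert mean_err[-50:].mean() < mean_err[:50].mean()
    assert mean_err[-50:].mean() > 0  # adaptation remains incomplete


def test_target_selection_error_examples():
    opts = [30.0, 150.0, 270.0]
    assert target_selection_error(opts, 30.0, phi=0.0) == pytest.approx(0.0)
    assert target_selection_error(opts, 270.0, phi=0.0) == pytest.approx(60.0)  # 90 - 30
    with pytest.raises(ValueError):
        target_selection_error(opts, 31.0, phi=0.0)


def test_target_selection_error_max_is_120_exhaustive():
    """Exhaustive 1-degree enumeration of orientations x choices: TSE spans
    exactly [0, 120]."""
    phi = 0.0
    worst = 0.0
    for u in range(120):
        opts = np.array([u, u + 120.0, u + 240.0]) % 360.0
        for chosen in opts:
            tse = target_selection_error(opts, chosen, phi)
            assert 0.0 <= tse <= 120.0 + 1e-9
            worst = max(worst, tse)
    assert worst == pytest.approx(120.0, abs=1e-9)


@given(st.floats(0, 360), st.floats(0, 360), st.integers(0, 2))
def test_target_selection_error_range_property(u, phi, pick):
    opts = (np.array([0.0, 120.0, 240.0]) + u) % 360.0
    tse = target_selection_error(opts, opts[pick], phi)
    assert -1e-9 <= tse <= 120.0 + 1e-9
    best = opts[np.argmin(np.abs(rs.wrap_signed(opts - phi)))]
    assert target_selection_error(opts, best, phi) == pytest.approx(0.0, abs=1e-9)


def test_change_in_tse_constant_is_zero():
    opts = [10.0, 130.0, 250.0]
    sess = make_choice_session([130.0] * 40, [opts] * 40, phi=10.0)
    series = change_in_tse(sess)
    assert series.baseline_subtracted
    assert np.allclose(series.values, 0.0)
    assert series.values[0] == 0.0


def test_change_in_tse_constructed_slope():
    """Choices drift one target closer to phi every bin: the aligned series
    decreases by the per-bin TSE step."""
    opts = [0.0, 120.0, 240.0]
    phi = 0.0
    chosen = [240.0] * 10 + [240.0] * 10 + [0.0] * 20  # TSE 120 then 0
    sess = make_choice_session(chosen, [opts] * 40, phi=phi)
    series = change_in_tse(sess)
    assert np.allclose(series.values, [0.0, 0.0, -120.0, -120.0])


def test_change_in_tse_needs_two_bins():
    opts = [0.0, 120.0, 240.0]
    sess = make_choice_session([0.0] * 15, [opts] * 15)
    with pytest.raises(ValueError):
        change_in_tse(sess)


def test_change_in_tse_invariant_to_constant_shift(exp1_session):
    """The baseline-subtracted series only reflects per-trial TSE *changes*:
    adding a constant to every per-trial TSE leaves it unchanged."""
    tse = session_tse(exp1_session)
    series = change_in_tse(exp1_session)
    binned = tse[:400].reshape(40, 10).mean(axis=1)
    assert np.allclose(series.values, binned - binned[0])
    shifted = (tse + 17.5)[:400].reshape(40, 10).mean(axis=1)
    assert np.allclose(series.values, shifted - shifted[0])


def test_preferred_direction(rng):
    opts = [90.0, 210.0, 330.0]
    sess = make_choice_session([90.0] * 60, [opts] * 60)
    assert preferred_direction(sess) == pytest.approx(90.0)
    # symmetric choices about 0
    chosen = [10.0, 350.0] * 30
    sess = make_choice_session(chosen, [[10.0, 130.0, 250.0], [350.0, 110.0, 230.0]] * 30)
    assert preferred_direction(sess) in (pytest.approx(0.0), pytest.approx(360.0))
    draws = np.degrees(rng.vonmises(np.radians(120.0), 8.0, size=60)) % 360.0
    sess = make_choice_session(list(draws), [[d, (d + 120) % 360, (d + 240) % 360] for d in draws])
    assert rs.abs_angular_distance(preferred_direction(sess), 120.0) < 5.0
    short = make_choice_session([0.0] * 30, [[0.0, 120.0, 240.0]] * 30)
    with pytest.raises(ValueError):
        preferred_direction(short)


def test_probability_weighted_tse_reductions():
    opts = [30.0, 150.0, 270.0]
    sess = make_choice_session([30.0] * 20, [opts] * 20, phi=0.0)
    tses = [target_selection_error(opts, o, 0.0) for o in opts]
    # degenerate probabilities pick out one option's TSE
    probs = np.tile([1.0, 0.0, 0.0], (20, 1))
    series = probability_weighted_tse(sess, probs)
    assert np.allclose(series.values, tses[0])
    # uniform probabilities give the arithmetic mean of the three TSEs
    probs = np.full((20, 3), 1.0 / 3.0)
    series = probability_weighted_tse(sess, probs)
    assert np.allclose(series.values, np.mean(tses))
    # alignment pins the first bin to the requested baseline
    series = probability_weighted_tse(sess, probs, align_first_bin_to=12.5)
    assert series.values[0] == pytest.approx(12.5)
    with pytest.raises(ValueError):
        probability_weighted_tse(sess, probs * 0.9)


def test_pfc_uniform_model_is_exactly_one_third():
    probs = np.full((60, 3), 1.0 / 3.0)
    idx = np.arange(60) % 3
    assert probabilistic_fraction_correct(probs, idx) == pytest.approx(1.0 / 3.0, rel=1e-15)


def test_pfc_perfect_and_constant_models():
    probs = np.zeros((50, 3))
    probs[:, 1] = 1.0
    assert probabilistic_fraction_correct(probs, np.ones(50, dtype=int)) == pytest.approx(1.0)
    probs = np.tile([0.5, 0.25, 0.25], (50, 1))
    assert probabilistic_fraction_correct(probs, np.zeros(50, dtype=int)) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        probabilistic_fraction_correct(probs[:10], np.zeros(10, dtype=int))


def test_von_mises_upper_bound_limits(rng):
    opts = [[40.0, 160.0, 280.0]] * 50
    # perfectly consistent chooser: bound approaches 1 under the capped kappa
    res = von_mises_upper_bound([40.0] * 50, opts)
    assert res.upper_bound > 0.999
    # uniform chooser: bound near chance
    chosen = [opts[0][rng.integers(3)] for _ in range(200)]
    res = von_mises_upper_bound(chosen, [opts[0]] * 200, window=200)
    assert res.upper_bound == pytest.approx(1.0 / 3.0, abs=0.05)


def test_von_mises_upper_bound_vs_model_pfc(pooled_reach, pooled_selection):
    """For weakly concentrated choosers the choice-distribution bound exceeds
    the generating model's own PFC in the large majority of sessions, and it
    stays above chance whenever choices carry any consistency.

    The bound is fit to the marginal distribution of chosen directions, which
    is flatter than the conditional preference when choices are strongly
    concentrated, so strict dominance over the true generating model is not
    guaranteed in general; this test pins the regime where it holds.
    """
    config = TaskConfig.experiment1(0.0)
    seeds = np.random.SeedSequence(55).generate_state(30) & 0x7FFFFFFF
    wins = 0
    for s in seeds:
        sess = rs.run_session(pooled_reach, pooled_selection, config, seed=int(s))
        probs, idx = rs.selection_trial_probabilities(pooled_selection, sess)
        pfc = probabilistic_fraction_correct(probs, idx)
        choices = [t.chosen_direction for t in sess.choice_trials]
        opts = [t.option_directions for t in sess.choice_trials]
        res = von_mises_upper_bound(choices, opts)
        if res.von_mises.kappa > 0:
            assert res.upper_bound > 1.0 / 3.0 - 0.02
        if res.upper_bound >= pfc:
            wins += 1
    assert wins >= 24  # 80% of replicates (26/30 on the pinned seeds)


def test_wls_goodness_of_fit(rng):
    bias = np.repeat([0.0, 10.0, 20.0, 30.0, 40.0], 10)
    sim_runs = [rng.normal(-5.0, 2.0, size=20) for _ in bias]
    # empirical identical to simulation means: slope exactly 0
    emp = np.array([np.mean(r) for r in sim_runs])
    res = wls_goodness_of_fit(emp, sim_runs, bias)
    assert res.slope == pytest.approx(0.0, abs=1e-12)
    # small trendless residuals: slope indistinguishable from 0
    res0 = wls_goodness_of_fit(emp + rng.normal(0, 0.5, size=len(bias)), sim_runs, bias)
    assert res0.p_value > 0.05
    # constructed trend 0.1 deg per deg of bias is recovered
    emp2 = emp + 0.1 * bias + rng.normal(0, 0.2, size=len(bias))
    res2 = wls_goodness_of_fit(emp2, sim_runs, bias)
    assert res2.slope == pytest.approx(0.1, abs=0.03)
    assert res2.p_value < 0.05


def test_wls_weights_are_inverse_variance(rng):
    bias = np.array([0.0, 20.0, 40.0])
    runs = [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(0, 1, 50)]
    res = wls_goodness_of_fit(np.zeros(3), runs, bias)
    doubled = [runs[0] * np.sqrt(2.0), runs[1], runs[2]]
    res2 = wls_goodness_of_fit(np.zeros(3), doubled, bias)
    assert res2.weights[0] == pytest.approx(res.weights[0] / 2.0)
    with pytest.raises(ValueError):
        wls_goodness_of_fit(np.zeros(3), [np.ones(5), runs[1], runs[2]], bias)
    with pytest.raises(ValueError):
        wls_goodness_of_fit(np.zeros(2), runs[:2], np.array([10.0, 10.0]))


def _training_session(mean_abs_error, alpha=40.0):
    trials = []
    for i in range(200):
        # reach angle such that |wrap(y + alpha)| == mean_abs_error
        y = float(rs.wrap_signed(mean_abs_error - alpha))
        trials.append(Trial(i + 1, "training", None, float(i % 360), y, alpha,
                            float(rs.wrap_signed(y + alpha)), True))
    config = TaskConfig.experiment2(alpha, least_noisy_direction_deg=0.0)
    return Session("t", config, trials)


@pytest.mark.parametrize("err,expected", [(10.0, True), (40.0, False), (20.0, False)])
def test_good_learner_classification(err, expected):
    assert classify_good_learner(_training_session(err)) is expected


def test_good_learner_requires_experiment2(exp1_session):
    with pytest.raises(ValueError):
        classify_good_learner(exp1_session)


def test_exclusions(exp1_session):
    # a participant who reaches in one constant direction is excluded
    trials = [
        Trial(i + 1, PHASE_CHOICE, (0.0, 120.0, 240.0), float(i * 7 % 360),
              float(rs.wrap_signed(90.0 - i * 7 % 360)), 0.0, 0.0, True)
        for i in range(40)
    ]
    config = TaskConfig.experiment1(0.0, least_noisy_direction_deg=0.0, n_choice_trials=40)
    stuck = Session("stuck", config, trials)
    kept, report = apply_exclusions([stuck])
    assert kept == [] and report.excluded_participants == ["stuck"]

    # one wild trial (70 degrees off target) is dropped, session kept
    good_trials = [
        _choice_trial(i + 1, ((i * 37) % 360, ((i * 37) + 120) % 360, ((i * 37) + 240) % 360),
                      float((i * 37) % 360), y=0.0)
        for i in range(40)
    ]
    good_trials[5].reach_angle_deg = 70.0
    messy = Session("messy", config, good_trials)
    kept, report = apply_exclusions([messy])
    assert len(kept) == 1 and len(kept[0].trials) == 39
    assert report.dropped_trials["messy"] == 1

    # a clean simulated session passes through unchanged
    kept, report = apply_exclusions([exp1_session])
    assert len(kept[0].trials) == 424
    assert report.dropped_trials[exp1_session.participant_id] == 0
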