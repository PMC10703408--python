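"""Compare the three target-selection models on one simulated session.

The session is generated by the expected-loss learner (Model ``loss``). Each
variant is refit by maximum likelihood and scored by the probabilistic
fraction correct (geometric mean of the probability assigned to the actual
choices) over the last 50 trials, alongside the von Mises upper bound
computed from the chooser's own choice distribution.
"""

import reachsel as rs
from reachsel.metrics import probabilistic_fraction_correct, von_mises_upper_bound

config = rs.TaskConfig.experiment1(bias_angle_deg=20.0)
session = rs.run_session(rs.POOLED_REACH_PARAMS, rs.POOLED_SELECTION_PARAMS, config, seed=17)

print("variant   NLL (fit)   PFC (last 50 choices)")
for variant in ("loss", "bias", "noise"):
    fit = rs.fit_selection(session, variant=variant, n_restarts=8, seed=5)
    probs, idx = rs.selection_trial_probabilities(fit.params, session)
    pfc = probabilistic_fraction_correct(probs, idx)
    print(f"{variant:7s}   {fit.objective:8.2f}    {pfc:.3f}")

choices = [t.chosen_direction for t in session.choice_trials]
opts = [t.option_directions for t in session.choice_trials]
bound = von_mises_upper_bound(choices, opts)
print(f"chance = 0.333; von Mises upper bound = {bound.upper_bound:.3f} "
      f"(choice concentration kappa = {bound.von_mises.kappa:.2f})")
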