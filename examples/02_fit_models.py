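"""Fit both models to a simulated session and compare with the truth.

The reach model is fit by minimizing the mean squared error of the predicted
reach-angle sequence; the target-selection model by maximizing the likelihood
of the observed choices. Because the generator is noise-free, the reach fit
recovers its parameters almost exactly, while selection parameters carry the
sampling noise of 400 categorical choices.
"""

import reachsel as rs

config = rs.TaskConfig.experiment1(bias_angle_deg=40.0)
session = rs.run_session(rs.POOLED_REACH_PARAMS, rs.POOLED_SELECTION_PARAMS, config, seed=7)

reach_fit = rs.fit_reach(session, n_restarts=10, seed=1)
sel_fit = rs.fit_selection(session, variant="loss", n_restarts=10, seed=2)

true_r, true_s = rs.POOLED_REACH_PARAMS, rs.POOLED_SELECTION_PARAMS
print("reach model (MSE fit, deg^2):")
print(f"  true:   a={true_r.a:.3f}  b={true_r.b:.3f}  l={true_r.l:.3f}")
print(f"  fitted: a={reach_fit.params.a:.3f}  b={reach_fit.params.b:.3f}  "
      f"l={reach_fit.params.l:.3f}   objective={reach_fit.objective:.2e}")
print("selection model (max-likelihood fit, nats):")
print(f"  true:   eta={true_s.eta:.3f}  lam={true_s.lam:.3f}  beta={true_s.beta:.3f}"
      f"   NLL at truth={rs.selection_nll(true_s, session):.2f}")
print(f"  fitted: eta={sel_fit.params.eta:.3f}  lam={sel_fit.params.lam:.3f}  "
      f"beta={sel_fit.params.beta:.3f}   NLL={sel_fit.objective:.2f}")
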