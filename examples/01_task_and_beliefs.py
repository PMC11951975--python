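"""Simulate the reward-learning task and filter its outcomes into beliefs.

Builds the default 160-trial phase-structured design, samples which option is
rewarded on each trial, and runs the 3-level binary-input filter over the
outcome sequence.
"""

import numpy as np

import spirlhgf as sp

design = sp.default_design()
u = sp.sample_outcomes(design, seed=1)
traj = sp.filter_inputs(u, sp.PerceptualParams(omega2=-3.0, omega3=-6.0))

print(f"trials: {design.n_trials}, phases: {sorted(set(design.phase_label))}")
print(f"achievable maximum correct predictions: {sp.max_expected_correct(u, design)}")
for k in (1, 40, 80, 120, 160):
    i = k - 1
    print(
        f"trial {k:3d}  phase={design.phase_label[i]:13s} p={design.p_reward_a[i]:.1f} "
        f"u={u[i]}  muhat1={traj.muhat1[i]:.3f}  sigma2={traj.sigma2[i]:.3f} "
        f"mu3={traj.mu3[i]:+.3f}"
    )
# muhat1 is the agent's predicted probability that option A is rewarded; it
# tracks the schedule, sigma2 is the (uncertainty-driven) learning rate and
# mu3 the inferred log-volatility of the environment.
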