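"""Posterior predictive check for one subject.

After fitting, draws parameters from the Laplace posterior, simulates new
behaviour, and compares the subject's adjusted correctness with the predictive
distribution.
"""

import numpy as np

import spirlhgf as sp

design = sp.default_design()
priors = sp.initial_priors("M1")
_, datasets = sp.simulate_from_priors("M1", priors, design, n_sim=1, seed=9)
ds = datasets[0]

fit = sp.fit_dataset(ds, "M1", priors, n_starts=20, seed=2)
bundle = sp.posterior_predictive(fit, priors, design, ds.u, n_ppc=100, seed=3)

observed = sp.adjusted_correctness(
    int(np.nansum(ds.y_bin == ds.u)), sp.max_expected_correct(ds.u, design)
)
print(f"observed adjusted correctness: {observed:.1f}%")
print(
    "posterior predictive: "
    f"median {np.median(bundle.adjusted_pct):.1f}%, "
    f"range [{bundle.adjusted_pct.min():.1f}, {bundle.adjusted_pct.max():.1f}]%"
)
print(f"inadmissible posterior draws: {bundle.invalid_fraction:.2f}")
print(f"log-RT variance marker trials: {bundle.marker_trials}")
# a well-calibrated model brackets the observed value inside its predictive
# range; the marker trials locate where predictive RT uncertainty peaks.
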