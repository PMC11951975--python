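# spirlhgf

Dual-stream generative modelling of probabilistic reward learning: a 3-level
Hierarchical Gaussian Filter (HGF) for binary inputs coupled to joint
choice/response-time response models, with the complete Bayesian workflow
around it — prior elicitation, predictive checks, multistart MAP inversion
with Laplace model evidence, parameter/model/family recovery, and
random-effects Bayesian model selection.

## Who this is for

Computational-psychiatry and decision-neuroscience researchers who model
trial-level behaviour from two-alternative probabilistic learning tasks and
want inference that uses *both* behavioural streams — the binary prediction
and its response time — instead of binary choices alone, which are often too
information-poor to identify volatility parameters.

## The model

The agent's perceptual model is a hierarchy of Gaussian random walks.  With
trial index k:

    x3 ~ N(x3', exp(omega3))                       (log-volatility)
    x2 ~ N(x2', exp(kappa2 * x3 + omega2))         (tendency towards option A)
    x1 ~ Bernoulli(s(x2)),  u = x1                 (observed outcome)

Variational inversion yields closed-form updates driven by precision-weighted
prediction errors; the level-2 belief moves as
`mu2(k) = mu2(k-1) + sigma2(k) * delta1(k)` with `delta1 = u - muhat1` and
`muhat1 = s(mu2(k-1))`, so the learning rate `sigma2` adapts to inferred
volatility.

Responses are modelled by two conditionally independent streams sharing the
belief trajectory:

* binary choice: unit-square sigmoid
  `p(y=1 | m, zeta) = m^zeta / (m^zeta + (1-m)^zeta)` with `m = muhat1`;
* log response time: a Gaussian GLM `log y_rt ~ N(X beta, Sigma)` in one of
  seven variants — an "informed" family (M1–M4) whose regressors are belief
  statistics (previous-outcome surprise, Bernoulli variance `sigmahat1`,
  level-2 uncertainty, volatility `exp(muhat3)`, environmental uncertainty
  `exp(kappa2*mu3 + omega2)`), and an "uninformed" family (M5–M7: constant,
  linear time decay, post-correct/post-incorrect intercepts).

Subjects are fit by multistart MAP in an unconstrained estimation space
(Sigma and zeta log-transformed) under independent Gaussian priors; the
Hessian of the negative log joint at the MAP gives the Laplace posterior
covariance and the approximate log model evidence
`LME = -NLJ + (d/2) log 2pi - 1/2 log det H`.  Evidence matrices feed
random-effects Bayesian model selection: a variational Dirichlet posterior
over model frequencies, exceedance probabilities (XP), the Bayes omnibus risk
(BOR) and protected exceedance probabilities
`PXP = (1 - BOR) * XP + BOR / K`, with family-level inference under a uniform
family prior.

## Worked example

```
$ python examples/03_model_comparison.py
model    Ef     XP     PXP
M1     0.846  0.999  0.998
M5     0.077  0.001  0.001
M6     0.077  0.001  0.001
Bayes omnibus risk: 0.001
family informed   Ef=0.917 XP=1.00
family uninformed Ef=0.083 XP=0.00
```

Ten subjects were simulated from the informed model M1 and fit by M1, M5 and
M6.  `Ef` is the posterior expected frequency of each model in the cohort;
`XP` the belief that it is the most frequent; `PXP` additionally protects
against the equal-frequency null, whose posterior probability is the Bayes
omnibus risk.  The informed model (and family) is correctly and decisively
recovered.  See `examples/` for the other stages: task simulation and belief
filtering, single-subject fitting, empirical prior elicitation, and posterior
predictive checks.

A thin CLI mirrors the workflow stages
(`spirlhgf simulate | fit | elicit-priors | compare | recover | ppc`), each a
pure function of a YAML config and a master seed, writing a manifest with the
seed and config digest.

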