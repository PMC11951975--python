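"""Joint response models: unit-square sigmoid choices plus log-RT GLMs.

Each candidate model couples the same perceptual filter to two conditionally
independent response streams.  Binary predictions follow a unit-square sigmoid
of the trial-wise outcome belief m = muhat1 with inverse decision temperature
zeta; log response times follow a trial-wise Gaussian GLM.  Seven GLM variants
span an "informed" family (M1-M4, regressors are belief-trajectory statistics
such as previous-outcome surprise, Bernoulli variance, level-2 uncertainty and
volatility) and an "uninformed" family (M5-M7: constant intercept, linear time
decay, and separate intercepts after correct vs incorrect trials).  The total
log-likelihood is the sum of the two streams' log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .hgf import BeliefTrajectory, PerceptualParams
from .task import Dataset, TaskDesign, TrialRecord

__all__ = [
    "ResponseParams",
    "ResponseModelSpec",
    "MODELS",
    "FAMILIES",
    "model_spec",
    "binary_choice_prob",
    "surprise",
    "build_design_matrix",
    "rt_means",
    "combined_loglik",
    "simulate_responses",
]

_EPS = 1e-8


@dataclass(frozen=True)
class ResponseModelSpec:
    """Identity and structure of one combined response model."""

    model_id: str
    regressors: tuple[str, ...]
    family: str
    rt_scale: float = 1000.0  # RT unit entering the log: 1000 => log-milliseconds

    @property
    def code(self) -> int:
        return int(self.model_id[1])

    @property
    def n_beta(self) -> int:
        # the two-intercept model parameterises its "design" via (a, b)
        return 0 if self.model_id == "M7" else len(self.regressors)


MODELS: dict[str, ResponseModelSpec] = {
    "M1": ResponseModelSpec(
        "M1", ("const", "surprise_prev", "sigmahat1", "sigmahat2", "exp_muhat3"),
        "informed",
    ),
    "M2": ResponseModelSpec("M2", ("const", "sigma2", "muhat3"), "informed"),
    "M3": ResponseModelSpec(
        "M3", ("const", "sigmahat1", "sigma2", "env_uncertainty"), "informed"
    ),
    "M4": ResponseModelSpec("M4", ("const", "sigma2", "env_uncertainty"), "informed"),
    "M5": ResponseModelSpec("M5", ("const",), "uninformed"),
    "M6": ResponseModelSpec("M6", ("const", "trial_frac"), "uninformed"),
    "M7": ResponseModelSpec("M7", ("prev_correct", "prev_incorrect"), "uninformed"),
}

FAMILIES: dict[str, tuple[str, ...]] = {
    "informed": ("M1", "M2", "M3", "M4"),
    "uninformed": ("M5", "M6", "M7"),
}


def model_spec(model_id: str) -> ResponseModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; expected M1..M7") from None


@dataclass(frozen=True)
class ResponseParams:
    """Response-side parameters: GLM weights, RT noise variance, decision noise."""

    beta: tuple[float, ...] = ()
    sigma: float = 0.05  # variance of Gaussian noise on log RT
    zeta: float = 48.0  # inverse decision temperature of the choice sigmoid
    a: float = 0.0  # post-correct intercept (two-intercept model)
    b: float = 0.0  # post-incorrect intercept

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.zeta <= 0:
            raise ValueError("sigma and zeta must be positive")

    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float) if self.beta else np.zeros(1)


def binary_choice_prob(m, zeta):
    """P(response = 1) under the unit-square sigmoid, m^z / (m^z + (1-m)^z).

    Computed in log space; ``m`` outside (0, 1) is clamped to [1e-8, 1-1e-8]
    first (the clamp lives in the likelihood only, never in the filter).
    """
    m = np.clip(np.asarray(m, dtype=float), _EPS, 1.0 - _EPS)
    x1 = zeta * np.log(m)
    x0 = zeta * np.log1p(-m)
    return np.exp(x1 - np.logaddexp(x1, x0))


def surprise(muhat1_prev, u_prev):
    """Shannon surprise (bits) of the previous outcome under the prediction."""
    m = np.asarray(muhat1_prev, dtype=float)
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("prediction at {0,1} gives infinite surprise")
    return np.where(np.asarray(u_prev) == 1, -np.log2(m), -np.log2(1.0 - m))


def build_design_matrix(
    spec: ResponseModelSpec,
    traj: BeliefTrajectory,
    u,
    y_bin=None,
    pparams: PerceptualParams | None = None,
    n_total: int | None = None,
) -> np.ndarray:
    """Trial x regressor matrix of the model's log-RT GLM.

    First-trial conventions: the previous-outcome surprise is 1 bit (the
    surprise of a uniform prediction), and the two-intercept model selects the
    post-correct column on trial 1 and on trials whose previous response is
    missing.
    """
    u = np.asarray(u)
    n = traj.n_trials
    K = n if n_total is None else n_total
    mid = spec.model_id
    if mid == "M1":
        m_prev = np.clip(traj.muhat1[:-1], _EPS, 1.0 - _EPS)
        s = np.concatenate(([1.0], surprise(m_prev, u[:-1])))
        X = np.column_stack(
            [np.ones(n), s, traj.sigmahat1, traj.sigmahat2, np.exp(traj.muhat3)]
        )
    elif mid == "M2":
        X = np.column_stack([np.ones(n), traj.sigma2, traj.muhat3])
    elif mid == "M3":
        X = np.column_stack([np.ones(n), traj.sigmahat1, traj.sigma2, traj.v2])
    elif mid == "M4":
        X = np.column_stack([np.ones(n), traj.sigma2, traj.v2])
    elif mid == "M5":
        X = np.ones((n, 1))
    elif mid == "M6":
        X = np.column_stack([np.ones(n), np.arange(1, n + 1) / K])
    elif mid == "M7":
        if y_bin is None:
            raise ValueError("the two-intercept model needs the binary responses")
        y_bin = np.asarray(y_bin, dtype=float)
        prev_ok = np.ones(n, dtype=bool)
        known = ~np.isnan(y_bin[:-1])
        prev_ok[1:] = np.where(known, y_bin[:-1] == u[:-1], True)
        X = np.column_stack([prev_ok.astype(float), (~prev_ok).astype(float)])
    else:
        raise KeyError(mid)
    return X


def rt_means(spec, traj, u, y_bin, rparams: ResponseParams) -> np.ndarray:
    """Per-trial GLM mean of log RT."""
    X = build_design_matrix(spec, traj, u, y_bin)
    w = np.array([rparams.a, rparams.b]) if spec.model_id == "M7" else rparams.beta_array()
    if X.shape[1] != w.size:
        raise ValueError(
            f"{spec.model_id} expects {X.shape[1]} weights, got {w.size}"
        )
    return X @ w


def combined_loglik(
    dataset: Dataset,
    traj: BeliefTrajectory,
    rparams: ResponseParams,
    spec: ResponseModelSpec,
    return_parts: bool = False,
):
    """Total log-likelihood of choices and log RTs, summed over valid trials.

    Ignored trials contribute nothing (though their inputs still drove the
    belief updates inside ``traj``); irregular trials contribute only the
    binary term.  Empty sums are 0.  Non-finite totals signal an inadmissible
    parameter vector via ValueError.
    """
    u = dataset.u
    y_bin = dataset.y_bin
    vb = dataset.valid_bin
    vr = dataset.valid_rt
    m = np.clip(traj.muhat1, _EPS, 1.0 - _EPS)
    x1 = rparams.zeta * np.log(m)
    x0 = rparams.zeta * np.log1p(-m)
    lse = np.logaddexp(x1, x0)
    ll_bin_trials = np.where(y_bin == 1, x1, x0) - lse
    ll_bin = float(np.sum(ll_bin_trials[vb])) if vb.any() else 0.0
    if vr.any():
        log_rt = np.log(dataset.y_rt[vr] * spec.rt_scale)
        mu = rt_means(spec, traj, u, y_bin, rparams)[vr]
        s = rparams.sigma
        ll_rt = float(
            np.sum(-0.5 * np.log(2 * np.pi * s) - 0.5 * (log_rt - mu) ** 2 / s)
        )
    else:
        ll_rt = 0.0
    total = ll_bin + ll_rt
    if not np.isfinite(total):
        raise ValueError("non-finite likelihood: inadmissible parameters")
    return (total, ll_bin, ll_rt) if return_parts else total


def simulate_responses(
    traj: BeliefTrajectory,
    rparams: ResponseParams,
    spec: ResponseModelSpec,
    design: TaskDesign,
    seed,
    u=None,
    clip_to_window: bool = False,
):
    """Draw one subject's choices and RTs from the model.

    Choices are Bernoulli with the unit-square sigmoid probability; log RTs are
    Gaussian around the GLM mean (drawn after the choices, since the
    two-intercept model conditions on the previous response).  RTs are returned
    in seconds; they are not truncated to the response window unless
    ``clip_to_window`` is set, since the likelihood is an untruncated Gaussian.
    """
    rng = np.random.default_rng(seed)
    n = traj.n_trials
    if u is None:
        raise ValueError("simulation needs the realised input sequence u")
    u = np.asarray(u)
    p1 = binary_choice_prob(traj.muhat1, rparams.zeta)
    y_bin = (rng.random(n) < p1).astype(np.int64)
    mu = rt_means(spec, traj, u, y_bin, rparams)
    log_rt = rng.normal(mu, np.sqrt(rparams.sigma))
    y_rt = np.exp(log_rt) / spec.rt_scale
    if clip_to_window:
        y_rt = np.minimum(y_rt, design.response_window)
    return y_bin, y_rt


def to_dataset(subject_id, u, y_bin, y_rt, design=None) -> Dataset:
    """Bundle simulated responses into a Dataset (flags left unset)."""
    trials = [
        TrialRecord(k=k + 1, u=int(u[k]), y_bin=int(y_bin[k]), y_rt=float(y_rt[k]))
        for k in range(len(u))
    ]
    return Dataset(str(subject_id), trials, design)
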