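"""Three-level Hierarchical Gaussian Filter for binary inputs.

The generative model stacks Gaussian random walks: the third level x3 tracks
log-volatility and evolves with tonic step variance exp(omega3); the second
level x2 (the tendency towards one of two stimulus categories) takes steps of
variance exp(kappa2*x3 + omega2); the binary state x1 is a sigmoid-noisy
readout of x2, and the input u is the observed category.  Variational
inversion yields closed-form trial-by-trial updates in which each level's
belief moves by a precision-weighted prediction error — a learning rate that
adapts to inferred volatility.

``predict_step``/``update_step`` implement one trial transparently in Python;
``filter_inputs`` runs the whole sequence through the compiled kernel.
Inadmissible parameter settings (a non-positive level-3 posterior precision or
numerical overflow) are reported via :class:`InadmissibleParameters`, never
clipped: silently repaired trajectories would distort the likelihood surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _fast

__all__ = [
    "PerceptualParams",
    "BeliefTrajectory",
    "InadmissibleParameters",
    "predict_step",
    "update_step",
    "filter_inputs",
]


class InadmissibleParameters(ValueError):
    """The parameter vector produced an invalid belief trajectory."""


@dataclass(frozen=True)
class PerceptualParams:
    """Parameters and initial conditions of the 3-level binary HGF.

    Only ``omega2`` (tonic level-2 log-volatility) and ``omega3``
    (meta-volatility) are estimated in practice; the coupling ``kappa2`` and
    the initial beliefs are fixed configuration, so each model carries exactly
    two free perceptual parameters.
    """

    omega2: float = -3.0
    omega3: float = -6.0
    kappa2: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 0.1
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    variant: str = "standard"  # or "ehgf" (stabilised level-3 update)

    def __post_init__(self) -> None:
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0 or self.kappa2 <= 0:
            raise ValueError("initial variances and kappa2 must be positive")
        if self.variant not in ("standard", "ehgf"):
            raise ValueError("variant must be 'standard' or 'ehgf'")


_FIELDS = [
    "muhat1", "sigmahat1", "muhat2", "sigmahat2", "mu2", "sigma2",
    "muhat3", "sigmahat3", "mu3", "sigma3", "delta1", "delta2", "v2", "w2",
]


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial belief sufficient statistics, prediction and posterior aligned.

    Row k holds the trial-k prediction (hat quantities, computed before the
    input arrives) and the trial-k posterior (computed after observing u_k).
    """

    data: np.ndarray  # (n_trials, 14), columns as in _fast

    def __getattr__(self, name):
        try:
            idx = _FIELDS.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.data[:, idx]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Wide per-trial table, one column per statistic (1-based trial index)."""
        df = pd.DataFrame(self.data, columns=_FIELDS)
        df.insert(0, "trial", np.arange(1, self.n_trials + 1))
        return df


def predict_step(state: dict, params: PerceptualParams) -> dict:
    """One trial's predictions from the previous posterior ``state``.

    ``state`` maps ``mu2, sigma2, mu3, sigma3`` to the trial-(k-1) posterior.
    """
    for v in state.values():
        if not np.isfinite(v):
            raise InadmissibleParameters("non-finite state")
    muhat2 = state["mu2"]
    muhat1 = 1.0 / (1.0 + np.exp(-muhat2))
    v2 = np.exp(params.kappa2 * state["mu3"] + params.omega2)
    return {
        "muhat1": muhat1,
        "sigmahat1": muhat1 * (1.0 - muhat1),
        "muhat2": muhat2,
        "sigmahat2": state["sigma2"] + v2,
        "muhat3": state["mu3"],
        "sigmahat3": state["sigma3"] + np.exp(params.omega3),
        "v2": v2,
    }


def update_step(pred: dict, u: int, state: dict, params: PerceptualParams) -> dict:
    """Posterior update after observing the binary input ``u``.

    The level-2 belief moves by its posterior variance times the input
    prediction error (mu2 <- muhat2 + sigma2*delta1); the level-3 belief moves
    by a volatility prediction error delta2 weighted by w2 = v2/sigmahat2.
    Raises :class:`InadmissibleParameters` when the level-3 posterior
    precision is not strictly positive.
    """
    ka = params.kappa2
    delta1 = u - pred["muhat1"]
    pi2 = 1.0 / pred["sigmahat2"] + pred["sigmahat1"]
    sigma2 = 1.0 / pi2
    mu2 = pred["muhat2"] + sigma2 * delta1
    w2 = pred["v2"] / pred["sigmahat2"]
    delta2 = (sigma2 + (mu2 - pred["muhat2"]) ** 2) / pred["sigmahat2"] - 1.0
    if params.variant == "ehgf":
        pihat3 = 1.0 / pred["sigmahat3"]
        mu3 = pred["muhat3"] + 0.5 * ka * pred["sigmahat3"] * w2 * delta2
        vv = np.exp(ka * mu3 + params.omega2)
        w2e = vv / (state["sigma2"] + vv)
        pi3 = pihat3 + 0.5 * ka * ka * w2e * (w2e + (2.0 * w2e - 1.0) * delta2)
    else:
        pi3 = 1.0 / pred["sigmahat3"] + 0.5 * ka * ka * w2 * (
            w2 + (2.0 * w2 - 1.0) * delta2
        )
        mu3 = pred["muhat3"] + 0.5 * ka * (w2 / pi3) * delta2
    if not np.isfinite(pi3) or pi3 <= 0 or not np.isfinite(mu2) or not np.isfinite(mu3):
        raise InadmissibleParameters("non-positive or non-finite level-3 precision")
    return {
        "mu2": mu2,
        "sigma2": sigma2,
        "mu3": mu3,
        "sigma3": 1.0 / pi3,
        "delta1": delta1,
        "delta2": delta2,
        "w2": w2,
    }


def filter_inputs(u, params: PerceptualParams) -> BeliefTrajectory:
    """Filter a whole binary input sequence into a belief trajectory."""
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("u must be a nonempty 1-d vector")
    if not np.all((u == 0) | (u == 1)):
        raise ValueError("inputs must be binary")
    T, ok = _fast.filter_kernel(
        u, params.kappa2, params.omega2, params.omega3,
        params.mu2_0, params.sigma2_0, params.mu3_0, params.sigma3_0,
        params.variant == "ehgf",
    )
    if not ok:
        raise InadmissibleParameters(
            f"filter failed for omega2={params.omega2:.3g}, omega3={params.omega3:.3g}"
        )
    return BeliefTrajectory(T)
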