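"""MAP inversion with multistart quasi-Newton optimisation and Laplace evidence.

Each free parameter carries an independent Gaussian prior in an unconstrained
*estimation space*: positivity-constrained parameters (the log-RT noise
variance Sigma and the inverse decision temperature zeta) are log-transformed,
everything else is estimated natively.  The posterior mode minimises the
negative log joint (negative combined log-likelihood minus log-priors); a
multistart scheme — the first start at the prior mean, the rest drawn from the
prior — guards against local minima.  At the MAP, the numerically
differentiated Hessian H of the negative log joint gives the Laplace posterior
covariance H^-1 and the approximate log model evidence

    LME = -NLJ(MAP) + (d/2) log(2 pi) - (1/2) log det H,

an accuracy-minus-complexity score that downstream model selection consumes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from . import _fast
from .hgf import PerceptualParams
from .responses import ResponseModelSpec, ResponseParams, model_spec
from .task import Dataset

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "FitResult",
    "to_native",
    "to_estimation",
    "neg_log_joint",
    "map_fit",
    "laplace_lme",
    "fit_dataset",
    "subject_model_seed",
]

_CAP = 1e10  # finite stand-in for +inf inside the optimiser
_GRAD_STEP = 1e-5


@dataclass(frozen=True)
class ParamPrior:
    """Gaussian prior of one parameter in estimation space; pC = 0 fixes it."""

    name: str
    transform: str  # "identity" | "log"
    pE: float
    pC: float

    def __post_init__(self) -> None:
        if self.pC < 0:
            raise ValueError("prior variance must be nonnegative")
        if self.transform not in ("identity", "log"):
            raise ValueError("transform must be 'identity' or 'log'")

    @property
    def fixed(self) -> bool:
        return self.pC == 0.0


@dataclass(frozen=True)
class PriorSpec:
    """Ordered per-parameter priors of one model."""

    model_id: str
    params: tuple[ParamPrior, ...]
    provenance: str = "initial"

    @property
    def free(self) -> tuple[ParamPrior, ...]:
        return tuple(p for p in self.params if not p.fixed)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.free)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def pE_free(self) -> np.ndarray:
        return np.array([p.pE for p in self.free])

    def pC_free(self) -> np.ndarray:
        return np.array([p.pC for p in self.free])

    def full_estimation_vector(self, theta_free: np.ndarray) -> dict[str, float]:
        """Estimation-space values of all parameters given the free subvector."""
        out, i = {}, 0
        for p in self.params:
            if p.fixed:
                out[p.name] = p.pE
            else:
                out[p.name] = float(theta_free[i])
                i += 1
        return out

    def updated(self, pE: dict[str, float], pC: dict[str, float], provenance: str):
        """New spec with replaced moments for the free parameters."""
        params = tuple(
            p if p.fixed else ParamPrior(p.name, p.transform, pE[p.name], pC[p.name])
            for p in self.params
        )
        return PriorSpec(self.model_id, params, provenance)


def to_native(prior: ParamPrior, value_est: float) -> float:
    return float(np.exp(value_est)) if prior.transform == "log" else float(value_est)


def to_estimation(prior: ParamPrior, value_native: float) -> float:
    return float(np.log(value_native)) if prior.transform == "log" else float(value_native)


def native_params(priors: PriorSpec, theta_free: np.ndarray):
    """(PerceptualParams-ready dict, ResponseParams) from a free vector."""
    est = priors.full_estimation_vector(theta_free)
    by_name = {p.name: p for p in priors.params}
    nat = {k: to_native(by_name[k], v) for k, v in est.items()}
    betas = tuple(
        nat[f"beta{i}"] for i in range(8) if f"beta{i}" in nat
    )
    rp = ResponseParams(
        beta=betas,
        sigma=nat["sigma"],
        zeta=nat["zeta"],
        a=nat.get("a", 0.0),
        b=nat.get("b", 0.0),
    )
    return nat, rp


@dataclass
class FitResult:
    """MAP fit of one model to one subject."""

    model_id: str
    free_names: tuple[str, ...]
    theta_est: np.ndarray  # MAP, free parameters, estimation space
    native: dict[str, float]  # all parameters, native space
    nlj: float  # negative log joint at the MAP
    start_objectives: np.ndarray
    start_converged: np.ndarray
    seed: int
    lme: float | None = None
    cov: np.ndarray | None = None
    hessian_repaired: bool = False

    @property
    def frac_converged(self) -> float:
        return float(np.mean(self.start_converged)) if self.start_converged.size else 1.0

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "free_names": list(self.free_names),
            "theta_est": self.theta_est.tolist(),
            "native": self.native,
            "nlj": self.nlj,
            "lme": self.lme,
            "cov": None if self.cov is None else self.cov.tolist(),
            "frac_converged": self.frac_converged,
            "hessian_repaired": self.hessian_repaired,
            "seed": self.seed,
        }


class _Problem:
    """Pre-extracted arrays plus the jitted objective for one (dataset, model)."""

    def __init__(self, dataset: Dataset, spec: ResponseModelSpec,
                 priors: PriorSpec, pparams: PerceptualParams):
        self.spec = spec
        self.priors = priors
        self.pp = pparams
        self.u = dataset.u.astype(np.float64)
        yb = dataset.y_bin
        self.y_bin = np.where(np.isnan(yb), -1, yb).astype(np.int64)
        self.valid_bin = dataset.valid_bin
        self.valid_rt = dataset.valid_rt.copy()
        rt = dataset.y_rt
        self.valid_rt &= np.nan_to_num(rt, nan=-1.0) > 0
        self.log_rt = np.where(self.valid_rt, np.log(np.where(self.valid_rt, rt, 1.0) * spec.rt_scale), 0.0)
        free = priors.free
        self._free_pE = np.array([p.pE for p in free])
        self._free_pC = np.array([p.pC for p in free])
        # constant part of the Gaussian log-prior
        self._prior_const = 0.5 * np.sum(np.log(2 * np.pi * self._free_pC)) if free else 0.0
        # index tables so the hot path avoids any per-eval dict work
        names = [p.name for p in priors.params]
        self._est_full = np.array([p.pE for p in priors.params])
        self._free_idx = np.array(
            [i for i, p in enumerate(priors.params) if not p.fixed], dtype=np.intp
        )
        self._log_mask = np.array([p.transform == "log" for p in priors.params])
        self._pos = {n: names.index(n) for n in names}
        nb = spec.n_beta
        self._beta_idx = np.array(
            [self._pos[f"beta{i}"] for i in range(nb)], dtype=np.intp
        )
        pos = self._pos
        self._kernel_args = (
            self._est_full, self._free_idx, self._log_mask, self._beta_idx,
            pos.get("a", -1), pos.get("b", -1),
            pos["omega2"], pos["omega3"], pos["sigma"], pos["zeta"],
            self._free_pE, self._free_pC, self._prior_const,
            spec.code, self.u, self.y_bin, self.log_rt,
            self.valid_bin, self.valid_rt,
            pparams.kappa2, pparams.mu2_0, pparams.sigma2_0,
            pparams.mu3_0, pparams.sigma3_0, pparams.variant == "ehgf",
        )

    def _native_vector(self, theta_free: np.ndarray) -> np.ndarray:
        est = self._est_full.copy()
        est[self._free_idx] = theta_free
        nat = est.copy()
        nat[self._log_mask] = np.exp(est[self._log_mask])
        return nat

    def nlj(self, theta_free: np.ndarray) -> float:
        """Negative log joint; +inf for inadmissible parameter vectors."""
        if not np.all(np.isfinite(theta_free)):
            return np.inf
        nat = self._native_vector(theta_free)
        pos = self._pos
        beta = nat[self._beta_idx] if self._beta_idx.size else np.zeros(1)
        nll = _fast.negloglik_kernel(
            self.spec.code, self.u, self.y_bin, self.log_rt,
            self.valid_bin, self.valid_rt,
            self.pp.kappa2, nat[pos["omega2"]], nat[pos["omega3"]],
            self.pp.mu2_0, self.pp.sigma2_0, self.pp.mu3_0, self.pp.sigma3_0,
            self.pp.variant == "ehgf",
            beta, nat[pos["a"]] if "a" in pos else 0.0,
            nat[pos["b"]] if "b" in pos else 0.0,
            nat[pos["sigma"]], nat[pos["zeta"]],
        )
        if not np.isfinite(nll):
            return np.inf
        if self._free_pC.size:
            z = theta_free - self._free_pE
            nll += self._prior_const + 0.5 * np.sum(z * z / self._free_pC)
        return float(nll)

    def nlj_capped(self, theta_free: np.ndarray) -> float:
        return float(
            _fast.nlj_theta_kernel(np.asarray(theta_free, dtype=float), _CAP,
                                   *self._kernel_args)
        )

    def grad(self, theta_free: np.ndarray) -> np.ndarray:
        """Central-difference gradient of the capped objective, step 1e-5."""
        return _fast.grad_theta_kernel(
            np.asarray(theta_free, dtype=float), _GRAD_STEP, _CAP,
            *self._kernel_args
        )


def neg_log_joint(
    theta_est,
    dataset: Dataset,
    spec: ResponseModelSpec | str,
    priors: PriorSpec,
    pparams: PerceptualParams | None = None,
) -> float:
    """Negative log joint density at a free-parameter vector (estimation space)."""
    spec = model_spec(spec) if isinstance(spec, str) else spec
    prob = _Problem(dataset, spec, priors, pparams or PerceptualParams())
    return prob.nlj(np.atleast_1d(np.asarray(theta_est, dtype=float)))


def map_fit(
    dataset: Dataset,
    spec: ResponseModelSpec | str,
    priors: PriorSpec,
    pparams: PerceptualParams | None = None,
    n_starts: int = 400,
    seed: int = 0,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> FitResult:
    """Multistart MAP estimation.

    Start 1 sits at the prior mean; the remaining starts are prior draws.  Each
    start runs BFGS with central-difference gradients; the MAP is the lowest
    converged objective (first found wins ties), falling back to the best
    non-converged start if nothing converged.
    """
    spec = model_spec(spec) if isinstance(spec, str) else spec
    pparams = pparams or PerceptualParams()
    prob = _Problem(dataset, spec, priors, pparams)
    d = priors.n_free
    if d == 0:
        nat, _ = native_params(priors, np.empty(0))
        return FitResult(spec.model_id, (), np.empty(0), nat,
                         prob.nlj(np.empty(0)), np.empty(0), np.empty(0, bool), seed)
    rng = np.random.default_rng(seed)
    pE, pC = priors.pE_free(), priors.pC_free()
    starts = np.vstack(
        [pE] + [rng.normal(pE, np.sqrt(pC)) for _ in range(max(0, n_starts - 1))]
    )
    objs = np.full(len(starts), np.inf)
    conv = np.zeros(len(starts), dtype=bool)
    sols = np.empty_like(starts)
    for i, x0 in enumerate(starts):
        res = minimize(
            prob.nlj_capped, x0, jac=prob.grad, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        sols[i] = res.x
        objs[i] = res.fun
        conv[i] = bool(res.success) and np.isfinite(res.fun) and res.fun < _CAP
    if conv.any():
        best = int(np.flatnonzero(conv)[np.argmin(objs[conv])])
    elif np.any(objs < _CAP):
        best = int(np.argmin(objs))
    else:
        raise RuntimeError("all starts inadmissible: fit failure")
    theta = sols[best]
    nat, _ = native_params(priors, theta)
    return FitResult(spec.model_id, priors.free_names, theta, nat,
                     prob.nlj(theta), objs, conv, seed)


def _hessian(f, x: np.ndarray) -> np.ndarray:
    """Central second differences with per-parameter step."""
    d = x.size
    h = 1e-3 * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def laplace_lme(
    fit: FitResult,
    dataset: Dataset,
    spec: ResponseModelSpec | str,
    priors: PriorSpec,
    pparams: PerceptualParams | None = None,
) -> FitResult:
    """Attach the Laplace evidence and posterior covariance to a fit.

    A non-positive-definite Hessian is repaired by escalating diagonal jitter
    (1e-8 to 1e-2 of the mean diagonal) and flagged; an unrecoverable Hessian
    raises.
    """
    spec = model_spec(spec) if isinstance(spec, str) else spec
    pparams = pparams or PerceptualParams()
    prob = _Problem(dataset, spec, priors, pparams)
    d = fit.theta_est.size
    if d == 0:
        fit.lme = -fit.nlj
        fit.cov = np.empty((0, 0))
        return fit
    H = _hessian(prob.nlj_capped, fit.theta_est)
    scale = float(np.mean(np.abs(np.diag(H)))) or 1.0
    jitter, repaired = 0.0, False
    while True:
        try:
            c, low = cho_factor(H + jitter * np.eye(d))
            break
        except np.linalg.LinAlgError:
            repaired = True
            jitter = 1e-8 * scale if jitter == 0.0 else jitter * 10
            if jitter > 1e-2 * scale:
                raise RuntimeError("Hessian not positive definite after repair")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    fit.cov = cho_solve((c, low), np.eye(d))
    fit.lme = float(-fit.nlj + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet)
    fit.hessian_repaired = repaired
    return fit


def subject_model_seed(master_seed: int, subject_id, model_id: str) -> int:
    """Stable per-(subject, model) stream so fits are order-independent."""
    tag = f"{subject_id}|{model_id}".encode()
    return (int(master_seed) * 1000003 + zlib.crc32(tag)) % (2**31 - 1)


def fit_dataset(
    dataset: Dataset,
    model_id: str,
    priors: PriorSpec,
    pparams: PerceptualParams | None = None,
    n_starts: int = 400,
    seed: int = 0,
) -> FitResult:
    """map_fit + laplace_lme with a per-(subject, model) random stream."""
    spec = model_spec(model_id)
    s = subject_model_seed(seed, dataset.subject_id, model_id)
    fit = map_fit(dataset, spec, priors, pparams, n_starts=n_starts, seed=s)
    return laplace_lme(fit, dataset, spec, priors, pparams)
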