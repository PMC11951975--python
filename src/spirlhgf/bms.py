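"""Random-effects Bayesian model selection over a subjects x models evidence matrix.

Model identity is treated as a random variable across subjects: model
frequencies r follow a Dirichlet(alpha0) prior, each subject's model a
categorical draw from r, and the per-subject log evidences L_nk connect data to
models.  A variational fixed point alternates soft model attributions

    g_nk  proportional to  exp(L_nk + psi(alpha_k) - psi(sum alpha))

with the Dirichlet update alpha = alpha0 + sum_n g_n.  From the posterior
Dirichlet we report expected frequencies Ef, exceedance probabilities XP
(belief that model k is the most frequent), the Bayes omnibus risk BOR
(posterior probability that all models are equally frequent, from the free
energies of the random-effects model F1 and the equal-frequency null F0) and
protected exceedance probabilities PXP = (1-BOR) XP + BOR/K.  Family-level
inference runs the same machinery with the prior mass split uniformly across
families and aggregated per family afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "BMSResult",
    "FamilyBMSResult",
    "rfx_bms",
    "exceedance_prob",
    "bor_pxp",
    "family_bms",
]


@dataclass
class BMSResult:
    model_ids: tuple[str, ...]
    alpha0: np.ndarray
    alpha: np.ndarray
    ef: np.ndarray
    g: np.ndarray  # subjects x models attribution weights
    converged: bool
    n_iter: int
    xp: np.ndarray | None = None
    pxp: np.ndarray | None = None
    bor: float | None = None

    def to_dict(self) -> dict:
        out = {
            "model_ids": list(self.model_ids),
            "alpha": self.alpha.tolist(),
            "Ef": self.ef.tolist(),
            "g": self.g.tolist(),
            "converged": self.converged,
        }
        for k in ("xp", "pxp"):
            v = getattr(self, k)
            out[k.upper()] = None if v is None else v.tolist()
        out["BOR"] = self.bor
        return out


def _as_matrix(L) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("evidence matrix must be subjects x models with >= 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("evidence matrix must be finite")
    return L


def rfx_bms(
    L,
    model_ids=None,
    alpha0=None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BMSResult:
    """Variational fixed point of the Dirichlet-multinomial random-effects model."""
    L = _as_matrix(L)
    n, k = L.shape
    ids = tuple(model_ids) if model_ids is not None else tuple(f"M{i+1}" for i in range(k))
    a0 = np.ones(k) if alpha0 is None else np.asarray(alpha0, dtype=float)
    if a0.shape != (k,) or np.any(a0 <= 0):
        raise ValueError("alpha0 must be positive, one entry per model")
    alpha = a0.copy()
    converged = False
    for it in range(1, max_iter + 1):
        w = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    return BMSResult(ids, a0, alpha, alpha / alpha.sum(), g, converged, it)


def exceedance_prob(alpha, n_samples: int = 100_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo P(r_k > r_j for all j != k) under Dirichlet(alpha), renormalised."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(alpha, size=int(n_samples))
    counts = np.bincount(np.argmax(r, axis=1), minlength=alpha.size)
    return counts / counts.sum()


def _dirichlet_free_energy(L: np.ndarray, a0: np.ndarray, alpha: np.ndarray,
                           g: np.ndarray) -> float:
    """Variational free energy F1 of the random-effects model at (alpha, g)."""
    dg = digamma(alpha) - digamma(alpha.sum())
    e_lik = float(np.sum(g * L))
    e_labels = float(np.sum(g * dg))
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_g = -float(np.nansum(g * np.log(np.where(g > 0, g, 1.0))))
    e_prior = float(
        gammaln(a0.sum()) - gammaln(a0).sum() + np.sum((a0 - 1) * dg)
    )
    ent_r = -float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + np.sum((alpha - 1) * dg)
    )
    return e_lik + e_labels + e_prior + ent_g + ent_r


def null_free_energy(L) -> float:
    """Exact log evidence of the equal-frequency null, sum_n log mean_k e^{L_nk}."""
    L = _as_matrix(L)
    return float(np.sum(logsumexp(L, axis=1) - np.log(L.shape[1])))


def bor_pxp(L, result: BMSResult, n_samples: int = 100_000, seed: int = 0) -> BMSResult:
    """Attach XP, the Bayes omnibus risk and protected exceedance probabilities.

    F0 — the exact evidence of the null in which every model is equally
    frequent — is sum_n [logsumexp(L_n) - log K]; BOR = 1/(1 + exp(F1 - F0)),
    and PXP mixes XP with the uniform vector with weight BOR.
    """
    L = _as_matrix(L)
    k = L.shape[1]
    xp = exceedance_prob(result.alpha, n_samples=n_samples, seed=seed)
    f1 = _dirichlet_free_energy(L, result.alpha0, result.alpha, result.g)
    f0 = null_free_energy(L)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    result.xp = xp
    result.bor = bor
    result.pxp = (1.0 - bor) * xp + bor / k
    return result


@dataclass
class FamilyBMSResult:
    families: tuple[str, ...]
    family_ef: np.ndarray
    family_xp: np.ndarray
    model_result: BMSResult

    def to_dict(self) -> dict:
        return {
            "families": list(self.families),
            "family_Ef": self.family_ef.tolist(),
            "family_XP": self.family_xp.tolist(),
            "model": self.model_result.to_dict(),
        }


def family_bms(
    L,
    model_ids,
    partition: dict[str, str],
    seed: int = 0,
    n_samples: int = 100_000,
    tol: float = 1e-6,
) -> FamilyBMSResult:
    """Family-level inference with a uniform prior over families.

    ``partition`` maps each model id to its family label.  Each family gets
    total prior mass 1, split evenly within (alpha0_m = 1/|family|), so the
    prior is uniform at the family level.  Family Ef sums member expected
    frequencies; family XP counts, per posterior Dirichlet draw, which family's
    summed frequency is largest.
    """
    L = _as_matrix(L)
    ids = tuple(model_ids)
    missing = set(ids) - set(partition)
    if missing:
        raise ValueError(f"partition misses models: {sorted(missing)}")
    fams = tuple(dict.fromkeys(partition[m] for m in ids))
    sizes = {f: sum(partition[m] == f for m in ids) for f in fams}
    if any(s == 0 for s in sizes.values()):
        raise ValueError("every family needs at least one member")
    a0 = np.array([1.0 / sizes[partition[m]] for m in ids])
    res = rfx_bms(L, ids, alpha0=a0, tol=tol)
    res = bor_pxp(L, res, n_samples=n_samples, seed=seed)
    member = {f: np.array([partition[m] == f for m in ids]) for f in fams}
    fam_ef = np.array([res.alpha[member[f]].sum() for f in fams]) / res.alpha.sum()
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(res.alpha, size=int(n_samples))
    fam_r = np.column_stack([r[:, member[f]].sum(axis=1) for f in fams])
    counts = np.bincount(np.argmax(fam_r, axis=1), minlength=len(fams))
    fam_xp = counts / counts.sum()
    return FamilyBMSResult(fams, fam_ef, fam_xp, res)
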