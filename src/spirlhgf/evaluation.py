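"""Absolute model-quality checks.

Model comparison only ranks candidates; these diagnostics ask whether the
winning model is any good in absolute terms: posterior predictive simulation
(new data from the Laplace posterior of each subject, summarised as adjusted
correctness densities and log-RT envelopes), residual diagnostics of the RT
GLM, group-average trajectory summaries, one-sample t-tests of GLM weights
against their zero prior mean, and the model-agnostic one-way ANOVA of average
log RTs across task phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hgf import InadmissibleParameters, PerceptualParams, filter_inputs
from .inversion import FitResult, PriorSpec, native_params
from .responses import model_spec, rt_means, simulate_responses
from .task import Dataset, TaskDesign, adjusted_correctness, max_expected_correct

__all__ = [
    "PPCBundle",
    "posterior_predictive",
    "rt_residuals",
    "group_summary",
    "beta_ttests",
    "phase_anova",
]


@dataclass
class PPCBundle:
    """Posterior predictive draws and their summaries for one subject."""

    model_id: str
    adjusted_pct: np.ndarray  # per accepted draw
    log_rt_sim: np.ndarray  # (n_accepted, n_trials)
    log_rt_map: np.ndarray  # MAP-predicted log-RT trace
    envelope: pd.DataFrame  # per-trial quantiles of simulated log RT
    marker_trials: dict[str, int]  # min/median/max variance trials (1-based)
    invalid_fraction: float

    def correctness_density(self, grid=None):
        """Gaussian KDE of the adjusted-correctness draws on a percent grid."""
        if grid is None:
            grid = np.linspace(0.0, 110.0, 221)
        kde = stats.gaussian_kde(self.adjusted_pct)
        return grid, kde(grid)


def posterior_predictive(
    fit: FitResult,
    priors: PriorSpec,
    design: TaskDesign,
    u,
    n_ppc: int = 100,
    seed: int = 0,
    pparams: PerceptualParams | None = None,
) -> PPCBundle:
    """Simulate new responses from the subject's Laplace posterior.

    Draws come from Normal(MAP, posterior covariance) in estimation space and
    are pushed through the filter and response model on the subject's realised
    input sequence ``u``.  Inadmissible draws are flagged and reported as a
    fraction, not silently resampled.
    """
    if fit.cov is None:
        raise ValueError("fit carries no posterior covariance; run laplace_lme first")
    pparams = pparams or PerceptualParams()
    spec = model_spec(fit.model_id)
    rng = np.random.default_rng(seed)
    u = np.asarray(u)
    d = fit.theta_est.size
    if d:
        draws = rng.multivariate_normal(fit.theta_est, fit.cov, size=n_ppc)
    else:
        draws = np.zeros((n_ppc, 0))
    pcts, sims = [], []
    for theta in draws:
        nat, rp = native_params(priors, theta)
        pp = PerceptualParams(
            omega2=nat["omega2"], omega3=nat["omega3"], kappa2=pparams.kappa2,
            mu2_0=pparams.mu2_0, sigma2_0=pparams.sigma2_0,
            mu3_0=pparams.mu3_0, sigma3_0=pparams.sigma3_0, variant=pparams.variant,
        )
        try:
            traj = filter_inputs(u, pp)
        except InadmissibleParameters:
            continue
        y_bin, y_rt = simulate_responses(traj, rp, spec, design, rng, u=u)
        if not np.all(np.isfinite(y_rt)):
            continue
        mx = max_expected_correct(u, design)
        pcts.append(adjusted_correctness(int(np.sum(y_bin == u)), mx))
        sims.append(np.log(y_rt * spec.rt_scale))
    sims = np.vstack(sims) if sims else np.empty((0, u.size))
    # MAP-predicted trace
    nat, rp = native_params(priors, fit.theta_est)
    pp_map = PerceptualParams(
        omega2=nat["omega2"], omega3=nat["omega3"], kappa2=pparams.kappa2,
        mu2_0=pparams.mu2_0, sigma2_0=pparams.sigma2_0,
        mu3_0=pparams.mu3_0, sigma3_0=pparams.sigma3_0, variant=pparams.variant,
    )
    traj_map = filter_inputs(u, pp_map)
    y_map = (traj_map.muhat1 > 0.5).astype(int)
    log_rt_map = rt_means(spec, traj_map, u, y_map.astype(float), rp)
    if len(sims):
        env = pd.DataFrame(
            {
                "trial": np.arange(1, u.size + 1),
                "q05": np.quantile(sims, 0.05, axis=0),
                "q50": np.quantile(sims, 0.50, axis=0),
                "q95": np.quantile(sims, 0.95, axis=0),
            }
        )
        var = sims.var(axis=0)
        order = np.argsort(var)
        markers = {
            "min_var": int(order[0] + 1),
            "median_var": int(order[len(order) // 2] + 1),
            "max_var": int(order[-1] + 1),
        }
    else:
        env = pd.DataFrame(columns=["trial", "q05", "q50", "q95"])
        markers = {}
    return PPCBundle(
        fit.model_id,
        np.asarray(pcts),
        sims,
        log_rt_map,
        env,
        markers,
        invalid_fraction=1.0 - len(pcts) / n_ppc,
    )


def rt_residuals(fit: FitResult, dataset: Dataset, priors: PriorSpec,
                 pparams: PerceptualParams | None = None) -> dict:
    """Residuals of the fitted log-RT GLM on valid RT trials, with moments."""
    pparams = pparams or PerceptualParams()
    spec = model_spec(fit.model_id)
    mask = dataset.valid_rt
    if not mask.any():
        raise ValueError("no valid RT trials")
    nat, rp = native_params(priors, fit.theta_est)
    pp = PerceptualParams(
        omega2=nat["omega2"], omega3=nat["omega3"], kappa2=pparams.kappa2,
        mu2_0=pparams.mu2_0, sigma2_0=pparams.sigma2_0,
        mu3_0=pparams.mu3_0, sigma3_0=pparams.sigma3_0, variant=pparams.variant,
    )
    traj = filter_inputs(dataset.u, pp)
    mu = rt_means(spec, traj, dataset.u, dataset.y_bin, rp)
    resid = np.log(dataset.y_rt[mask] * spec.rt_scale) - mu[mask]
    hist, edges = np.histogram(resid, bins="auto")
    out = {
        "residuals": resid,
        "mean": float(resid.mean()),
        "variance": float(resid.var(ddof=1)) if resid.size > 1 else 0.0,
        "skewness": float(stats.skew(resid)) if resid.size > 2 else 0.0,
        "hist_counts": hist,
        "hist_edges": edges,
    }
    if resid.size >= 8:
        k2, p = stats.normaltest(resid)
        out["normality_p"] = float(p)
    return out


def group_summary(fits, datasets, priors_by_model,
                  pparams: PerceptualParams | None = None) -> pd.DataFrame:
    """Missing-aware per-trial means over subjects of data and model traces."""
    if not datasets:
        raise ValueError("need at least one subject")
    pparams = pparams or PerceptualParams()
    y_bin, muhat1, log_rt, pred_rt, abs_d1 = [], [], [], [], []
    for fit, ds in zip(fits, datasets):
        spec = model_spec(fit.model_id)
        priors = priors_by_model[fit.model_id]
        nat, rp = native_params(priors, fit.theta_est)
        pp = PerceptualParams(
            omega2=nat["omega2"], omega3=nat["omega3"], kappa2=pparams.kappa2,
            mu2_0=pparams.mu2_0, sigma2_0=pparams.sigma2_0,
            mu3_0=pparams.mu3_0, sigma3_0=pparams.sigma3_0, variant=pparams.variant,
        )
        traj = filter_inputs(ds.u, pp)
        y_bin.append(ds.y_bin)
        muhat1.append(traj.muhat1)
        with np.errstate(invalid="ignore"):
            log_rt.append(np.where(ds.valid_rt, np.log(np.where(ds.valid_rt, ds.y_rt, 1.0) * spec.rt_scale), np.nan))
        pred_rt.append(rt_means(spec, traj, ds.u, ds.y_bin, rp))
        abs_d1.append(np.abs(traj.delta1))
    n = datasets[0].n_trials
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "mean_y_bin": np.nanmean(np.vstack(y_bin), axis=0),
            "mean_muhat1": np.mean(np.vstack(muhat1), axis=0),
            "mean_log_rt": np.nanmean(np.vstack(log_rt), axis=0),
            "mean_pred_log_rt": np.mean(np.vstack(pred_rt), axis=0),
            "mean_abs_delta1": np.mean(np.vstack(abs_d1), axis=0),
        }
    )


def beta_ttests(map_table: pd.DataFrame, null: float = 0.0) -> pd.DataFrame:
    """One-sample t-tests of each GLM weight column against the prior mean.

    Bonferroni correction across the tested columns; ``significant`` flags
    corrected p < 0.05.
    """
    if len(map_table) < 2:
        raise ValueError("need at least two subjects")
    out = []
    m = map_table.shape[1]
    for col in map_table.columns:
        x = map_table[col].to_numpy(dtype=float)
        if np.allclose(x.var(ddof=1), 0.0):
            if np.allclose(x.mean(), null):
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(x.mean() - null), 0.0
        else:
            t, p = stats.ttest_1samp(x, null)
        p_adj = min(1.0, float(p) * m)
        out.append(
            {"param": col, "t": float(t), "p": float(p), "p_bonferroni": p_adj,
             "significant": p_adj < 0.05}
        )
    return pd.DataFrame(out).set_index("param")


def phase_anova(subject_phase_means: pd.DataFrame):
    """One-way fixed-effects ANOVA of subject-average log RTs across phases.

    Treats subjects as independent observations within each phase column
    (stable / volatile / unpredictable).  Returns (F, p).
    """
    if len(subject_phase_means) < 2:
        raise ValueError("need at least two subjects")
    groups = [subject_phase_means[c].dropna().to_numpy() for c in subject_phase_means.columns]
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
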