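"""Jitted kernels for the trial-sequential filter and the combined likelihood.

The belief filter is inherently sequential (each trial's prediction depends on
the previous posterior), and multistart MAP estimation evaluates the joint
density tens of thousands of times per subject, so the hot path lives here as
numba-compiled loops.  The readable reference implementations in ``hgf`` and
``responses`` are the public API; the test suite asserts agreement between the
two routes.

Trajectory column layout (one row per trial):
  0 muhat1   1 sigmahat1  2 muhat2  3 sigmahat2  4 mu2     5 sigma2
  6 muhat3   7 sigmahat3  8 mu3     9 sigma3    10 delta1 11 delta2
 12 v2      13 w2
"""

import numpy as np
from numba import njit

N_COLS = 14
(
    MUHAT1, SIGMAHAT1, MUHAT2, SIGMAHAT2, MU2, SIGMA2,
    MUHAT3, SIGMAHAT3, MU3, SIGMA3, DELTA1, DELTA2, V2, W2,
) = range(N_COLS)

_EPS = 1e-8


@njit(cache=True)
def filter_kernel(u, ka, om2, om3, mu2_0, sa2_0, mu3_0, sa3_0, ehgf):
    """Run the 3-level binary-input filter; returns (trajectory, ok)."""
    n = u.shape[0]
    T = np.empty((n, N_COLS))
    mu2, sa2, mu3, sa3 = mu2_0, sa2_0, mu3_0, sa3_0
    for k in range(n):
        # predictions from the trial-(k-1) posterior
        muhat2 = mu2
        muhat1 = 1.0 / (1.0 + np.exp(-muhat2))
        sahat1 = muhat1 * (1.0 - muhat1)
        v2 = np.exp(ka * mu3 + om2)
        sahat2 = sa2 + v2
        muhat3 = mu3
        sahat3 = sa3 + np.exp(om3)
        if not (np.isfinite(sahat2) and np.isfinite(sahat3)) or sahat2 <= 0.0:
            return T, False
        # level-2 update from the input prediction error
        d1 = u[k] - muhat1
        pi2 = 1.0 / sahat2 + sahat1
        sa2n = 1.0 / pi2
        mu2n = muhat2 + sa2n * d1
        # level-3 update from the volatility prediction error
        w2 = v2 / sahat2
        d2 = (sa2n + (mu2n - muhat2) ** 2) / sahat2 - 1.0
        if ehgf:
            # stabilised variant: mean first, with the predicted precision;
            # precision update re-evaluates the weight at the new mean
            pihat3 = 1.0 / sahat3
            mu3n = muhat3 + 0.5 * ka * sahat3 * w2 * d2
            vv = np.exp(ka * mu3n + om2)
            w2e = vv / (sa2 + vv)
            pi3 = pihat3 + 0.5 * ka * ka * w2e * (w2e + (2.0 * w2e - 1.0) * d2)
        else:
            pi3 = 1.0 / sahat3 + 0.5 * ka * ka * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
            mu3n = muhat3 + 0.5 * ka * (w2 / pi3) * d2
        if pi3 <= 0.0 or not (np.isfinite(pi3) and np.isfinite(mu2n) and np.isfinite(mu3n)):
            return T, False
        sa3n = 1.0 / pi3
        T[k, MUHAT1] = muhat1
        T[k, SIGMAHAT1] = sahat1
        T[k, MUHAT2] = muhat2
        T[k, SIGMAHAT2] = sahat2
        T[k, MU2] = mu2n
        T[k, SIGMA2] = sa2n
        T[k, MUHAT3] = muhat3
        T[k, SIGMAHAT3] = sahat3
        T[k, MU3] = mu3n
        T[k, SIGMA3] = sa3n
        T[k, DELTA1] = d1
        T[k, DELTA2] = d2
        T[k, V2] = v2
        T[k, W2] = w2
        mu2, sa2, mu3, sa3 = mu2n, sa2n, mu3n, sa3n
    return T, True


@njit(cache=True)
def rt_means_kernel(model, T, u, y_bin, beta, a, b):
    """Per-trial GLM mean of log RT for model codes 1..7.

    First-trial conventions: the previous-outcome surprise regressor is 1 bit
    (a uniform prediction); the two-intercept model uses the post-correct
    intercept ``a`` on trial 1 and whenever the previous response is missing.
    """
    n = T.shape[0]
    mu = np.empty(n)
    for k in range(n):
        if model == 1:
            if k == 0:
                s = 1.0
            else:
                m = T[k - 1, MUHAT1]
                if m < _EPS:
                    m = _EPS
                elif m > 1.0 - _EPS:
                    m = 1.0 - _EPS
                s = -np.log2(m) if u[k - 1] == 1 else -np.log2(1.0 - m)
            mu[k] = (
                beta[0]
                + beta[1] * s
                + beta[2] * T[k, SIGMAHAT1]
                + beta[3] * T[k, SIGMAHAT2]
                + beta[4] * np.exp(T[k, MUHAT3])
            )
        elif model == 2:
            mu[k] = beta[0] + beta[1] * T[k, SIGMA2] + beta[2] * T[k, MUHAT3]
        elif model == 3:
            mu[k] = (
                beta[0]
                + beta[1] * T[k, SIGMAHAT1]
                + beta[2] * T[k, SIGMA2]
                + beta[3] * T[k, V2]
            )
        elif model == 4:
            mu[k] = beta[0] + beta[1] * T[k, SIGMA2] + beta[2] * T[k, V2]
        elif model == 5:
            mu[k] = beta[0]
        elif model == 6:
            mu[k] = beta[0] + beta[1] * (k + 1.0) / n
        else:  # two intercepts keyed to previous-trial correctness
            if k == 0 or y_bin[k - 1] < 0:
                mu[k] = a
            elif y_bin[k - 1] == u[k - 1]:
                mu[k] = a
            else:
                mu[k] = b
    return mu


@njit(cache=True)
def loglik_kernel(model, T, u, y_bin, log_rt, valid_bin, valid_rt,
                  beta, a, b, sigma, zeta):
    """Combined log-likelihood: unit-square sigmoid choices + Gaussian log RTs."""
    n = T.shape[0]
    mu_rt = rt_means_kernel(model, T, u, y_bin, beta, a, b)
    ll = 0.0
    for k in range(n):
        if valid_bin[k]:
            m = T[k, MUHAT1]
            if m < _EPS:
                m = _EPS
            elif m > 1.0 - _EPS:
                m = 1.0 - _EPS
            x1 = zeta * np.log(m)
            x0 = zeta * np.log(1.0 - m)
            hi = x1 if x1 > x0 else x0
            lse = hi + np.log(np.exp(x1 - hi) + np.exp(x0 - hi))
            ll += (x1 if y_bin[k] == 1 else x0) - lse
        if valid_rt[k]:
            r = log_rt[k] - mu_rt[k]
            ll += -0.5 * np.log(2.0 * np.pi * sigma) - 0.5 * r * r / sigma
    return ll


@njit(cache=True)
def negloglik_kernel(model, u, y_bin, log_rt, valid_bin, valid_rt,
                     ka, om2, om3, mu2_0, sa2_0, mu3_0, sa3_0, ehgf,
                     beta, a, b, sigma, zeta):
    """Filter + likelihood in one call; +inf for inadmissible parameters."""
    if sigma <= 0.0 or zeta <= 0.0:
        return np.inf
    T, ok = filter_kernel(u, ka, om2, om3, mu2_0, sa2_0, mu3_0, sa3_0, ehgf)
    if not ok:
        return np.inf
    ll = loglik_kernel(model, T, u, y_bin, log_rt, valid_bin, valid_rt,
                       beta, a, b, sigma, zeta)
    if not np.isfinite(ll):
        return np.inf
    return -ll


@njit(cache=True)
def nlj_theta_kernel(theta_free, cap,
                     est_full, free_idx, log_mask, beta_idx,
                     i_a, i_b, i_om2, i_om3, i_sigma, i_zeta,
                     pE, pC, prior_const,
                     model, u, y_bin, log_rt, valid_bin, valid_rt,
                     ka, mu2_0, sa2_0, mu3_0, sa3_0, ehgf):
    """Negative log joint as a function of the free estimation-space vector.

    Inadmissible vectors evaluate to ``cap`` so finite-difference gradients
    stay representable for the optimiser.
    """
    for j in range(theta_free.size):
        if not np.isfinite(theta_free[j]):
            return cap
    est = est_full.copy()
    for j in range(free_idx.size):
        est[free_idx[j]] = theta_free[j]
    nat = est.copy()
    for j in range(nat.size):
        if log_mask[j]:
            nat[j] = np.exp(nat[j])
    nb = beta_idx.size
    beta = np.zeros(max(nb, 1))
    for j in range(nb):
        beta[j] = nat[beta_idx[j]]
    a = nat[i_a] if i_a >= 0 else 0.0
    b = nat[i_b] if i_b >= 0 else 0.0
    nll = negloglik_kernel(
        model, u, y_bin, log_rt, valid_bin, valid_rt,
        ka, nat[i_om2], nat[i_om3], mu2_0, sa2_0, mu3_0, sa3_0, ehgf,
        beta, a, b, nat[i_sigma], nat[i_zeta],
    )
    if not np.isfinite(nll):
        return cap
    for j in range(pC.size):
        z = theta_free[j] - pE[j]
        nll += 0.5 * z * z / pC[j]
    nll += prior_const
    if nll > cap or not np.isfinite(nll):
        return cap
    return nll


@njit(cache=True)
def grad_theta_kernel(theta_free, step, cap,
                      est_full, free_idx, log_mask, beta_idx,
                      i_a, i_b, i_om2, i_om3, i_sigma, i_zeta,
                      pE, pC, prior_const,
                      model, u, y_bin, log_rt, valid_bin, valid_rt,
                      ka, mu2_0, sa2_0, mu3_0, sa3_0, ehgf):
    """Central-difference gradient of the capped negative log joint."""
    d = theta_free.size
    g = np.empty(d)
    x = theta_free.copy()
    for i in range(d):
        xi = x[i]
        x[i] = xi + step
        fp = nlj_theta_kernel(x, cap, est_full, free_idx, log_mask, beta_idx,
                              i_a, i_b, i_om2, i_om3, i_sigma, i_zeta,
                              pE, pC, prior_const,
                              model, u, y_bin, log_rt, valid_bin, valid_rt,
                              ka, mu2_0, sa2_0, mu3_0, sa3_0, ehgf)
        x[i] = xi - step
        fm = nlj_theta_kernel(x, cap, est_full, free_idx, log_mask, beta_idx,
                              i_a, i_b, i_om2, i_om3, i_sigma, i_zeta,
                              pE, pC, prior_const,
                              model, u, y_bin, log_rt, valid_bin, valid_rt,
                              ka, mu2_0, sa2_0, mu3_0, sa3_0, ehgf)
        x[i] = xi
        g[i] = (fp - fm) / (2.0 * step)
    return g
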