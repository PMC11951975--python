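"""Posterior predictive checks, RT residuals, group traces, t-tests and the phase ANOVA."""

import numpy as np
import pandas as pd
import pytest

import spirlhgf as sp
from conftest import make_dataset


def injected_fit(model_id, priors, theta_est, cov_scale=0.0):
    """FitResult with a hand-set estimate (no optimisation)."""
    from spirlhgf.inversion import FitResult, native_params

    theta = np.asarray(theta_est, dtype=float)
    nat, _ = native_params(priors, theta)
    d = theta.size
    return FitResult(model_id, priors.free_names, theta, nat, 0.0,
                     np.empty(0), np.empty(0, bool), 0,
                     lme=0.0, cov=np.eye(d) * cov_scale)


class TestPosteriorPredictive:
    def test_point_posterior_degenerates_to_map(self, design40):
        priors = sp.initial_priors("M5")
        fit = injected_fit("M5", priors, [-3.0, -6.0, 6.0, np.log(0.04), np.log(3.0)])
        u = sp.sample_outcomes(design40, 1)
        b = sp.posterior_predictive(fit, priors, design40, u, n_ppc=20, seed=0)
        assert b.invalid_fraction == 0.0
        assert np.ptp(b.adjusted_pct) <= 45.0  # residual choice noise only
        # with zero covariance all draws share the same parameters
        assert len(b.adjusted_pct) == 20
        assert b.log_rt_sim.shape == (20, 40)
        assert set(b.marker_trials) == {"min_var", "median_var", "max_var"}

    def test_density_integrates_to_one(self, design40):
        priors = sp.initial_priors("M5")
        fit = injected_fit("M5", priors, [-3.0, -6.0, 6.0, np.log(0.04), np.log(3.0)],
                           cov_scale=0.01)
        u = sp.sample_outcomes(design40, 2)
        b = sp.posterior_predictive(fit, priors, design40, u, n_ppc=50, seed=1)
        grid = np.linspace(-50, 160, 2101)
        g, dens = b.correctness_density(grid)
        assert np.trapezoid(dens, g) == pytest.approx(1.0, abs=1e-3)

    def test_self_simulation_covered(self, design40):
        """PPC draws bracket the adjusted correctness of self-generated data."""
        priors = sp.initial_priors("M5")
        theta = [-3.0, -6.0, 6.0, np.log(0.04), np.log(3.0)]
        fit = injected_fit("M5", priors, theta, cov_scale=0.01)
        u = sp.sample_outcomes(design40, 3)
        traj = sp.filter_inputs(u, sp.PerceptualParams(omega2=-3.0, omega3=-6.0))
        rp = sp.ResponseParams(beta=(6.0,), sigma=0.04, zeta=3.0)
        y_bin, _ = sp.simulate_responses(traj, rp, sp.model_spec("M5"), design40, 9, u=u)
        pct = sp.adjusted_correctness(int(np.sum(y_bin == u)),
                                      sp.max_expected_correct(u, design40))
        b = sp.posterior_predictive(fit, priors, design40, u, n_ppc=100, seed=4)
        assert b.adjusted_pct.min() - 1e-9 <= pct <= b.adjusted_pct.max() + 1e-9


class TestRtResiduals:
    def test_noise_free_simulation_zero_residuals(self, design40):
        priors = sp.initial_priors("M5")
        theta = [-3.0, -6.0, 5.0, np.log(0.04), np.log(3.0)]
        fit = injected_fit("M5", priors, theta)
        u = sp.sample_outcomes(design40, 0)
        rt = np.full(40, np.exp(5.0) / 1000.0)
        ds = make_dataset(u, y_bin=u, y_rt=rt, design=design40)
        res = sp.rt_residuals(fit, ds, priors)
        assert np.allclose(res["residuals"], 0.0, atol=1e-12)
        assert res["mean"] == 0.0

    def test_noise_variance_recovered(self, design160):
        priors = sp.initial_priors("M5")
        s_true = 0.04
        theta = [-3.0, -6.0, 6.0, np.log(s_true), np.log(3.0)]
        fit = injected_fit("M5", priors, theta)
        u = sp.sample_outcomes(design160, 5)
        traj = sp.filter_inputs(u, sp.PerceptualParams(omega2=-3.0, omega3=-6.0))
        rp = sp.ResponseParams(beta=(6.0,), sigma=s_true, zeta=3.0)
        y_bin, y_rt = sp.simulate_responses(traj, rp, sp.model_spec("M5"),
                                            design160, 6, u=u)
        ds = make_dataset(u, y_bin=y_bin, y_rt=y_rt, design=design160)
        res = sp.rt_residuals(fit, ds, priors)
        assert abs(res["variance"] - s_true) / s_true < 0.35
        assert abs(res["mean"]) < 3 * np.sqrt(s_true / 160)

    def test_no_valid_rt_trials_rejected(self, design40):
        priors = sp.initial_priors("M5")
        fit = injected_fit("M5", priors, [-3.0, -6.0, 6.0, -3.0, 1.0])
        u = sp.sample_outcomes(design40, 0)
        ds = make_dataset(u, design=design40, ignored=np.ones(40, bool))
        with pytest.raises(ValueError):
            sp.rt_residuals(fit, ds, priors)


class TestGroupSummary:
    def test_single_subject_identity(self, design40):
        priors = sp.initial_priors("M5")
        theta = [-3.0, -6.0, 6.0, np.log(0.04), np.log(3.0)]
        fit = injected_fit("M5", priors, theta)
        u = sp.sample_outcomes(design40, 1)
        rng = np.random.default_rng(0)
        ds = make_dataset(u, y_bin=(rng.random(40) < 0.5).astype(int),
                          y_rt=rng.uniform(0.3, 1.0, 40), design=design40)
        df = sp.group_summary([fit], [ds], {"M5": priors})
        assert np.allclose(df["mean_y_bin"], ds.y_bin)
        assert np.allclose(df["mean_log_rt"], np.log(ds.y_rt * 1000.0))

    def test_mirrored_responses_average_to_half(self, design40):
        priors = sp.initial_priors("M5")
        theta = [-3.0, -6.0, 6.0, np.log(0.04), np.log(3.0)]
        fit = injected_fit("M5", priors, theta)
        u = sp.sample_outcomes(design40, 2)
        rng = np.random.default_rng(1)
        y = (rng.random(40) < 0.5).astype(int)
        rt = np.full(40, 0.5)
        d1 = make_dataset(u, y_bin=y, y_rt=rt, design=design40, subject_id="a")
        d2 = make_dataset(u, y_bin=1 - y, y_rt=rt, design=design40, subject_id="b")
        df = sp.group_summary([fit, fit], [d1, d2], {"M5": priors})
        assert np.allclose(df["mean_y_bin"], 0.5)

    def test_prediction_error_spikes_after_reversals(self):
        """Group-average |delta1| rises right after a probability reversal."""
        design = sp.generate_design([(20, 0.9, "stable"), (20, 0.1, "volatile")])
        priors = sp.initial_priors("M5")
        theta = [-2.0, -6.0, 6.0, np.log(0.04), np.log(3.0)]
        fit = injected_fit("M5", priors, theta)
        fits, datasets = [], []
        for s in range(12):
            u = sp.sample_outcomes(design, s)
            traj = sp.filter_inputs(u, sp.PerceptualParams(omega2=-2.0, omega3=-6.0))
            rp = sp.ResponseParams(beta=(6.0,), sigma=0.04, zeta=3.0)
            y_bin, y_rt = sp.simulate_responses(traj, rp, sp.model_spec("M5"),
                                                design, 100 + s, u=u)
            datasets.append(make_dataset(u, y_bin=y_bin, y_rt=y_rt, design=design,
                                         subject_id=f"s{s}"))
            fits.append(fit)
        df = sp.group_summary(fits, datasets, {"M5": priors})
        before = df["mean_abs_delta1"][15:20].mean()
        after = df["mean_abs_delta1"][20:25].mean()
        assert after > before


class TestBetaTtests:
    def test_hand_computed_t(self):
        table = pd.DataFrame({"beta1": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = sp.beta_ttests(table)
        assert out.loc["beta1", "t"] == pytest.approx(4.2426, abs=1e-4)

    def test_zero_column_not_significant(self):
        table = pd.DataFrame({"b": np.zeros(10)})
        out = sp.beta_ttests(table)
        assert out.loc["b", "t"] == 0.0 and not out.loc["b", "significant"]

    def test_tiny_jitter_around_constant_is_significant(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"b": 1.0 + rng.normal(0, 1e-6, 10),
                              "c": rng.normal(0, 1.0, 10)})
        out = sp.beta_ttests(table)
        assert out.loc["b", "significant"]

    def test_column_order_invariance(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(12, 3)), columns=["x", "y", "z"])
        a = sp.beta_ttests(table)
        b = sp.beta_ttests(table[["z", "x", "y"]])
        for c in "xyz":
            assert a.loc[c, "t"] == pytest.approx(b.loc[c, "t"])
            assert a.loc[c, "p_bonferroni"] == pytest.approx(b.loc[c, "p_bonferroni"])


class TestPhaseAnova:
    def test_identical_groups_give_zero_f(self):
        df = pd.DataFrame({"stable": [1.0, 2.0, 3.0], "volatile": [1.0, 2.0, 3.0],
                           "unpredictable": [1.0, 2.0, 3.0]})
        f, p = sp.phase_anova(df)
        assert f == pytest.approx(0.0)

    def test_textbook_three_group_example(self):
        df = pd.DataFrame({"stable": [1.0, 2.0, 3.0], "volatile": [2.0, 3.0, 4.0],
                           "unpredictable": [3.0, 4.0, 5.0]})
        f, p = sp.phase_anova(df)
        assert f == pytest.approx(3.0)  # between MS 3, within MS 1

    def test_null_simulation_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            df = pd.DataFrame(rng.normal(size=(12, 3)),
                              columns=["stable", "volatile", "unpredictable"])
            ps.append(sp.phase_anova(df)[1])
        ps = np.array(ps)
        # coarse uniformity: each third of [0,1] holds roughly a third of p-values
        for lo in (0.0, 1 / 3, 2 / 3):
            frac = np.mean((ps >= lo) & (ps < lo + 1 / 3))
            assert 0.2 < frac < 0.47

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            sp.phase_anova(pd.DataFrame({"stable": [1.0], "volatile": [1.0],
                                         "unpredictable": [2.0]}))
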