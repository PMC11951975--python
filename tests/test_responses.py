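"""Unit-square sigmoid, surprise, the seven log-RT GLMs and response simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spirlhgf as sp
from spirlhgf import _fast
from conftest import make_dataset


@pytest.fixture(scope="module")
def traj40(design40):
    u = sp.sample_outcomes(design40, 17)
    return u, sp.filter_inputs(u, sp.PerceptualParams(omega2=-2.5, omega3=-5.0))


class TestChoiceRule:
    def test_indifference_point(self):
        for z in (0.5, 1.0, 7.0):
            assert sp.binary_choice_prob(0.5, z) == pytest.approx(0.5)

    def test_identity_at_unit_temperature(self):
        m = np.linspace(0.05, 0.95, 11)
        assert np.allclose(sp.binary_choice_prob(m, 1.0), m, atol=1e-12)

    def test_hand_value(self):
        assert sp.binary_choice_prob(0.8, 2.0) == pytest.approx(0.64 / 0.68, abs=1e-9)

    @given(m=st.floats(0.01, 0.99), z=st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_complement_sums_to_one(self, m, z):
        p = sp.binary_choice_prob(m, z) + sp.binary_choice_prob(1 - m, z)
        assert p == pytest.approx(1.0, abs=1e-10)


class TestSurprise:
    def test_uniform_prediction_is_one_bit(self):
        assert sp.surprise(0.5, 1) == pytest.approx(1.0)
        assert sp.surprise(0.5, 0) == pytest.approx(1.0)

    def test_unexpected_outcome(self):
        assert sp.surprise(0.75, 0) == pytest.approx(2.0)

    def test_certain_prediction_rejected(self):
        with pytest.raises(ValueError):
            sp.surprise(1.0, 1)


class TestDesignMatrices:
    def test_null_model_is_constant(self, traj40):
        u, traj = traj40
        X = sp.build_design_matrix(sp.model_spec("M5"), traj, u)
        assert X.shape == (40, 1) and np.all(X == 1.0)

    def test_time_decay_ramp(self, traj40):
        u, traj = traj40
        X = sp.build_design_matrix(sp.model_spec("M6"), traj, u, n_total=160)
        assert X[0, 1] == pytest.approx(1 / 160)
        # on a full-length trajectory the ramp ends at 1
        X = sp.build_design_matrix(sp.model_spec("M6"), traj, u)
        assert X[-1, 1] == pytest.approx(1.0)

    def test_two_intercept_selector(self, traj40):
        u, traj = traj40
        y = u.astype(float).copy()  # always correct
        y[5] = 1 - y[5]  # one error
        X = sp.build_design_matrix(sp.model_spec("M7"), traj, u, y_bin=y)
        assert X[0, 0] == 1.0  # first trial uses the post-correct intercept
        assert X[6, 1] == 1.0  # trial after the error selects b
        assert np.all(X.sum(axis=1) == 1.0)

    def test_informed_regressors_from_trajectory(self, traj40):
        u, traj = traj40
        X = sp.build_design_matrix(sp.model_spec("M1"), traj, u)
        assert X.shape == (40, 5)
        assert X[0, 1] == pytest.approx(1.0)  # 1-bit first-trial surprise
        assert np.allclose(X[1:, 1], sp.surprise(traj.muhat1[:-1], u[:-1]))
        assert np.allclose(X[:, 2], traj.sigmahat1)
        assert np.allclose(X[:, 4], np.exp(traj.muhat3))
        X3 = sp.build_design_matrix(sp.model_spec("M3"), traj, u)
        assert np.allclose(X3[:, 3], traj.v2)  # env. uncertainty exp(k2*mu3+om2)

    @pytest.mark.parametrize("mid", ["M1", "M2", "M3", "M4", "M5", "M6", "M7"])
    def test_numpy_means_match_kernel(self, mid, traj40):
        u, traj = traj40
        rng = np.random.default_rng(3)
        spec = sp.model_spec(mid)
        nb = max(spec.n_beta, 1)
        rp = sp.ResponseParams(beta=tuple(rng.normal(size=spec.n_beta)),
                               sigma=0.05, zeta=2.0,
                               a=rng.normal(), b=rng.normal())
        y = (rng.random(40) < 0.5).astype(float)
        mu_py = sp.rt_means(spec, traj, u, y, rp)
        beta = np.array(rp.beta) if rp.beta else np.zeros(1)
        mu_k = _fast.rt_means_kernel(spec.code, traj.data, u.astype(float),
                                     y.astype(np.int64), beta, rp.a, rp.b)
        assert np.allclose(mu_py, mu_k, atol=1e-12)


class TestCombinedLikelihood:
    def test_all_ignored_gives_zero(self, design40, traj40):
        u, traj = traj40
        ds = make_dataset(u, design=design40, ignored=np.ones(40, bool))
        rp = sp.ResponseParams(beta=(0.0,), sigma=1.0, zeta=1.0)
        assert sp.combined_loglik(ds, traj, rp, sp.model_spec("M5")) == 0.0

    def test_gaussian_at_its_mean(self, design40, traj40):
        u, traj = traj40
        spec = sp.model_spec("M5")
        b0, s = 5.0, 0.3
        rt = np.full(40, np.exp(b0) / spec.rt_scale)
        ds = make_dataset(u, y_rt=rt, design=design40)
        rp = sp.ResponseParams(beta=(b0,), sigma=s, zeta=1.0)
        total, ll_bin, ll_rt = sp.combined_loglik(ds, traj, rp, spec, return_parts=True)
        assert ll_bin == 0.0  # no binary responses present
        assert ll_rt == pytest.approx(-(40 / 2) * np.log(2 * np.pi * s))

    def test_two_trial_hand_computation(self, design40):
        u = np.array([1, 0])
        params = sp.PerceptualParams(omega2=-2.0, omega3=-6.0)
        traj = sp.filter_inputs(u, params)
        spec = sp.model_spec("M5")
        b0, s, z = 6.0, 0.2, 2.0
        rt = np.array([0.4, 0.6])
        ds = make_dataset(u, y_bin=[1, 1], y_rt=rt)
        rp = sp.ResponseParams(beta=(b0,), sigma=s, zeta=z)
        total = sp.combined_loglik(ds, traj, rp, spec)
        # independent arithmetic straight from the two density formulas
        m = traj.muhat1
        p1 = m**z / (m**z + (1 - m) ** z)
        expected = np.log(p1[0]) + np.log(p1[1])
        lr = np.log(rt * 1000.0)
        expected += np.sum(-0.5 * np.log(2 * np.pi * s) - (lr - b0) ** 2 / (2 * s))
        assert total == pytest.approx(expected, rel=1e-12)

    def test_decomposes_into_parts(self, design40, traj40):
        u, traj = traj40
        rng = np.random.default_rng(0)
        ds = make_dataset(u, y_bin=(rng.random(40) < 0.5).astype(int),
                          y_rt=rng.uniform(0.3, 1.2, 40), design=design40)
        rp = sp.ResponseParams(beta=(6.0, 0.5), sigma=0.2, zeta=3.0)
        total, ll_bin, ll_rt = sp.combined_loglik(
            ds, traj, rp, sp.model_spec("M6"), return_parts=True
        )
        assert total == pytest.approx(ll_bin + ll_rt)

    def test_irregular_trials_keep_binary_term_only(self, design40, traj40):
        u, traj = traj40
        rng = np.random.default_rng(1)
        y = (rng.random(40) < 0.5).astype(int)
        rt = rng.uniform(0.3, 1.2, 40)
        rp = sp.ResponseParams(beta=(6.0,), sigma=0.2, zeta=3.0)
        spec = sp.model_spec("M5")
        full = make_dataset(u, y_bin=y, y_rt=rt, design=design40)
        rt2 = rt.copy(); rt2[10] = 0.05
        irr = np.zeros(40, bool); irr[10] = True
        flagged = make_dataset(u, y_bin=y, y_rt=rt2, design=design40, irregular=irr)
        _, b_full, r_full = sp.combined_loglik(full, traj, rp, spec, return_parts=True)
        _, b_flag, r_flag = sp.combined_loglik(flagged, traj, rp, spec, return_parts=True)
        assert b_flag == pytest.approx(b_full)  # binary term untouched
        lr = np.log(rt[10] * 1000.0)
        dropped = -0.5 * np.log(2 * np.pi * 0.2) - (lr - 6.0) ** 2 / 0.4
        assert r_flag == pytest.approx(r_full - dropped)

    def test_uninformed_family_rt_invariant_to_perception(self, design40):
        u = sp.sample_outcomes(design40, 4)
        rng = np.random.default_rng(2)
        ds = make_dataset(u, y_bin=(rng.random(40) < 0.5).astype(int),
                          y_rt=rng.uniform(0.3, 1.2, 40), design=design40)
        rp = sp.ResponseParams(beta=(6.0, -0.3), sigma=0.2, zeta=3.0)
        t1 = sp.filter_inputs(u, sp.PerceptualParams(omega2=-2.0, omega3=-6.0))
        t2 = sp.filter_inputs(u, sp.PerceptualParams(omega2=-5.0, omega3=-3.0))
        for mid in sp.FAMILIES["uninformed"]:
            spec = sp.model_spec(mid)
            kw = dict(beta=(6.0,) if mid == "M5" else (6.0, -0.3),
                      sigma=0.2, zeta=3.0, a=6.0, b=5.5)
            if mid == "M7":
                kw["beta"] = ()
            rpm = sp.ResponseParams(**kw)
            _, _, r1 = sp.combined_loglik(ds, t1, rpm, spec, return_parts=True)
            _, _, r2 = sp.combined_loglik(ds, t2, rpm, spec, return_parts=True)
            assert r1 == pytest.approx(r2)


class TestSimulation:
    def test_seeded_reproducibility(self, design40, traj40):
        u, traj = traj40
        rp = sp.ResponseParams(beta=(6.0,), sigma=0.05, zeta=4.0)
        a = sp.simulate_responses(traj, rp, sp.model_spec("M5"), design40, 8, u=u)
        b = sp.simulate_responses(traj, rp, sp.model_spec("M5"), design40, 8, u=u)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_steep_sigmoid_limit(self, design40, traj40):
        u, traj = traj40
        rp = sp.ResponseParams(beta=(6.0,), sigma=0.05, zeta=1e6)
        y_bin, _ = sp.simulate_responses(traj, rp, sp.model_spec("M5"), design40, 0, u=u)
        assert np.array_equal(y_bin, (traj.muhat1 > 0.5).astype(int))

    def test_noise_free_rt_limit(self, design40, traj40):
        u, traj = traj40
        rp = sp.ResponseParams(beta=(6.0,), sigma=1e-18, zeta=2.0)
        _, y_rt = sp.simulate_responses(traj, rp, sp.model_spec("M5"), design40, 0, u=u)
        assert np.allclose(np.log(y_rt * 1000.0), 6.0, atol=1e-6)

    def test_choice_frequency_matches_choice_rule(self):
        """Long-run response-1 frequency reproduces the sigmoid probability."""
        n = 10_000
        traj = sp.BeliefTrajectory(np.zeros((n, 14)))
        traj.data[:, 0] = 0.8  # muhat1
        design = sp.generate_design([(n, 0.5, "unpredictable")])
        rp = sp.ResponseParams(beta=(6.0,), sigma=0.05, zeta=2.0)
        y_bin, _ = sp.simulate_responses(traj, rp, sp.model_spec("M5"), design, 0,
                                         u=np.ones(n, int))
        p = 0.64 / 0.68
        assert abs(y_bin.mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_window_clipping_optional(self, design40, traj40):
        u, traj = traj40
        rp = sp.ResponseParams(beta=(9.0,), sigma=0.05, zeta=2.0)  # ~8 s RTs
        _, free = sp.simulate_responses(traj, rp, sp.model_spec("M5"), design40, 0, u=u)
        _, clip = sp.simulate_responses(traj, rp, sp.model_spec("M5"), design40, 0,
                                        u=u, clip_to_window=True)
        assert free.max() > design40.response_window
        assert clip.max() <= design40.response_window
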