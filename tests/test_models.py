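import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import streamtemp as st
from streamtemp._mcmc import ar1_path
from streamtemp.draws import PosteriorDraws
from streamtemp.model_m1 import extrema_from, decomposition_from
from streamtemp.params import DEFAULT_PHASE

from conftest import circ_diff


def quiet_fit(model, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(**kw)


class TestExtremaTransforms:
    def test_examples(self):
        x_max, x_min = extrema_from(12.0, 13.0)
        assert (x_max, x_min) == (25.0, -1.0)
        a, b = decomposition_from(25.0, -1.0)
        assert (a, b) == (12.0, 13.0)
        x_max, x_min = extrema_from(5.0, 0.0)
        assert x_max == x_min == 5.0

    @given(hst.floats(-50, 50), hst.floats(0, 30))
    def test_round_trip(self, alpha, beta):
        a, b = decomposition_from(*extrema_from(alpha, beta))
        assert abs(a - alpha) < 1e-12 and abs(b - beta) < 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            extrema_from(1.0, -0.5)
        with pytest.raises(ValueError):
            decomposition_from(1.0, 2.0)


class TestBuildM1:
    def test_grid_mismatch(self):
        wt = st.RegularSeries(1, np.zeros(73))
        at = st.RegularSeries(2, np.zeros(73))
        with pytest.raises(ValueError, match="grid"):
            st.build_m1(wt, at)

    def test_nonpositive_discharge(self):
        wt = st.RegularSeries(1, np.ones(73))
        q = st.RegularSeries(1, np.ones(73))
        q.values[3] = -1.0
        with pytest.raises(ValueError, match="positive"):
            st.build_m1(wt, wt, q)

    def test_latent_node_bookkeeping(self):
        vals = np.ones(146) + np.sin(np.arange(146))
        wt = st.RegularSeries(1, vals.copy())
        at = st.RegularSeries(1, vals.copy())
        assert st.build_m1(wt, at).n_latent_missing == 0
        wt.values[[3, 50, 99]] = np.nan
        model = st.build_m1(wt, at)
        assert model.n_latent_missing == 3
        post = quiet_fit(model, n_chains=2, n_burn=60, n_keep=40, seed=0)
        assert post["wt_missing"].shape == (2, 40, 3)


class TestFitM1:
    def test_same_seed_identical_draws(self):
        pa, pq, lk = st.default_recovery_setup(2)
        truth = st.simulate_m1_generative(pa, pq, lk, seed=5)
        model = st.build_m1(truth.wt, truth.at, truth.q)
        p1 = quiet_fit(model, n_chains=2, n_burn=80, n_keep=80, seed=9)
        p2 = quiet_fit(model, n_chains=2, n_burn=80, n_keep=80, seed=9)
        for nm in p1.names():
            np.testing.assert_array_equal(p1[nm], p2[nm])

    def test_phase_recovery_low_noise(self):
        pa, pq, lk = st.default_recovery_setup(6)
        pa.innov_var, pq.innov_var = 0.05, 0.02
        lk = st.LinkageParams(lk.a0, lk.a_at, lk.a_q, lk.b0, lk.b_at, lk.b_q, 0.01, 0.01)
        truth = st.simulate_m1_generative(pa, pq, lk, wt_noise=(0.3, 0.05), seed=6)
        model = st.build_m1(truth.wt, truth.at, truth.q)
        post = quiet_fit(model, n_chains=3, n_burn=600, n_keep=600, seed=7)
        for nm, tv in (("at_phi", pa.phi), ("q_phi", pq.phi), ("wt_phi", truth.params_wt.phi)):
            err = circ_diff(post.pooled(nm).mean(), tv)
            assert abs(err) < 0.05, nm

    def test_ar_coefficient_recovery(self, recovery_8y):
        # the posterior should track the realised autocorrelation of this
        # particular draw (which itself scatters around the generating 0.5)
        post = recovery_8y["post"]
        truth = recovery_8y["truth"]
        eps = truth.wt.values - truth.params_wt.mean_series()
        realized = eps[:-1] @ eps[1:] / (eps[:-1] @ eps[:-1])
        assert realized == pytest.approx(0.5, abs=0.1)
        assert post.pooled("wt_rho").mean() == pytest.approx(realized, abs=0.1)
        assert post.meta["neg_amplitude_freq"] < 0.01

    def test_convergence_on_well_identified_fixture(self, recovery_8y):
        assert recovery_8y["post"].max_rhat() < 1.1

    def test_linkage_sign_recovery(self, recovery_8y):
        # generating signs: a_at > 0, b_at > 0 are identifiable even on the
        # short fixture; the discharge terms are weak at 16 windows, so for
        # them we only require the credible interval to cover the truth
        post = recovery_8y["post"]
        lk = recovery_8y["lk"]
        assert np.mean(post.pooled("a_at") > 0) > 0.9
        assert np.mean(post.pooled("b_at") > 0) > 0.9
        for nm, tv in (("a_q", lk.a_q), ("b_q", lk.b_q)):
            lo, hi = np.percentile(post.pooled(nm), [2.5, 97.5])
            assert lo <= tv <= hi, nm

    def test_likelihood_peaks_at_generating_parameters(self):
        # brute-force grid over phi and one window mean on near-noiseless data
        pa, pq, lk = st.default_recovery_setup(2)
        pa = st.DecompositionParams(pa.alpha, pa.beta, pa.phi, 0.3, 0.05)
        out = st.simulate_m1_generative(pa, None, lk, wt_noise=(0.3, 0.05), seed=8)
        at = out.at

        def loglik(phi, alpha0):
            alpha = pa.alpha.copy()
            alpha[0] = alpha0
            mu = st.DecompositionParams(alpha, pa.beta, phi, pa.rho, 1.0).mean_series()
            eps = at.values - mu
            rho = pa.rho
            ssq = (1 - rho**2) * eps[0] ** 2 + np.sum((eps[1:] - rho * eps[:-1]) ** 2)
            return -ssq

        best = loglik(pa.phi, pa.alpha[0])
        for dphi in (-0.2, -0.1, 0.1, 0.2):
            assert loglik(pa.phi + dphi, pa.alpha[0]) < best
        for da in (-0.5, -0.2, 0.2, 0.5):
            assert loglik(pa.phi, pa.alpha[0] + da) < best


class TestForecastM1:
    def test_training_scenario_tracks_fitted_signal(self, recovery_8y):
        truth, model, post = (
            recovery_8y["truth"],
            recovery_8y["model"],
            recovery_8y["post"],
        )
        pred = model.forecast(post, truth.at, truth.q, seed=3, n_draws=300)
        resid_sd = np.sqrt(0.8 / (1 - 0.25))  # stationary sd of generating noise
        rmse = np.sqrt(np.mean((pred.mean - truth.params_wt.mean_series()) ** 2))
        assert rmse < resid_sd

    def test_scenario_argument_validation(self, recovery_8y):
        model, post = recovery_8y["model"], recovery_8y["post"]
        at_p = recovery_8y["truth"].at
        with pytest.raises(ValueError, match="discharge"):
            model.forecast(post, at_p, None)

    def test_degenerate_posterior_gives_zero_width(self):
        names = ["wt_phi", "wt_rho", "wt_ivar", "at_phi", "a0", "a_at", "b0",
                 "b_at", "var_max", "var_min"]
        vals = dict.fromkeys(names, 0.0)
        vals.update(wt_phi=DEFAULT_PHASE, at_phi=DEFAULT_PHASE, a_at=1.0, b_at=1.0)
        post = PosteriorDraws({k: np.full((1, 40), v) for k, v in vals.items()})
        at_p = st.simulate_sinusoid_ar1(
            st.SinusoidTrendSpec(12, 0, 6, ar_innov_var=0.0, years=2), 0
        )
        pred = st.forecast_from_draws(post, at_p, seed=0, n_draws=20)
        lo, hi = pred.interval()
        assert np.max(hi - lo) == 0.0

    def test_forecast_pools_chains(self, recovery_8y):
        # relabelling chains must not change the forecast distribution
        truth, model, post = (
            recovery_8y["truth"], recovery_8y["model"], recovery_8y["post"],
        )
        perm = {nm: post[nm][::-1].copy() for nm in post.names()}
        shuffled = PosteriorDraws(perm, meta=post.meta)
        a = model.forecast(post, truth.at, truth.q, seed=11, n_draws=2000)
        b = model.forecast(shuffled, truth.at, truth.q, seed=12, n_draws=2000)
        assert np.mean(a.draws) == pytest.approx(np.mean(b.draws), abs=0.1)
        assert np.std(a.draws) == pytest.approx(np.std(b.draws), rel=0.05)


class TestImpute:
    def test_requesting_observed_cell_fails(self):
        pa, pq, lk = st.default_recovery_setup(2)
        truth = st.simulate_m1_generative(pa, pq, lk, seed=5)
        truth.wt.values[[7, 20]] = np.nan
        model = st.build_m1(truth.wt, truth.at, truth.q)
        post = quiet_fit(model, n_chains=2, n_burn=80, n_keep=80, seed=1)
        pred = model.impute(post)
        assert pred.draws.shape[1] == 2
        with pytest.raises(ValueError, match="observed"):
            model.impute(post, cells=[3])

    def test_noiseless_point_recovery(self):
        # with near-zero noise a masked cell is pinned by the seasonal signal
        pa, pq, lk = st.default_recovery_setup(2)
        pa.innov_var, pq.innov_var = 0.01, 0.01
        lk = st.LinkageParams(lk.a0, lk.a_at, lk.a_q, lk.b0, lk.b_at, lk.b_q, 0.005, 0.005)
        truth = st.simulate_m1_generative(pa, pq, lk, wt_noise=(0.3, 0.01), seed=6)
        hidden = truth.wt.values[30]
        truth.wt.values[30] = np.nan
        model = st.build_m1(truth.wt, truth.at, truth.q)
        post = quiet_fit(model, n_chains=3, n_burn=400, n_keep=400, seed=2)
        pred = model.impute(post)
        assert pred.mean[0] == pytest.approx(hidden, abs=0.3)


class TestM0:
    def test_noiseless_linear_recovery(self):
        at = st.simulate_sinusoid_ar1(st.SinusoidTrendSpec(12, 0, 6, years=3), 0)
        wt = st.RegularSeries(1, 1.0 + 2.0 * at.values)
        post = quiet_fit(st.build_m0(wt, at), n_chains=3, n_burn=400, n_keep=400, seed=1)
        assert post.pooled("slope").mean() == pytest.approx(2.0, abs=0.01)
        assert post.pooled("intercept").mean() == pytest.approx(1.0, abs=0.1)

    def test_slope_recovery_under_ar1_noise(self):
        at = st.simulate_sinusoid_ar1(
            st.SinusoidTrendSpec(12, 0, 6, ar_innov_var=1.0, years=20),
            np.random.default_rng(8),
        )
        eps = ar1_path(np.random.default_rng(9), 0.5, 2.0, len(at))
        wt = st.RegularSeries(1, 1.0 + 0.8 * at.values + eps)
        post = quiet_fit(st.build_m0(wt, at), n_chains=3, n_burn=1000, n_keep=1000, seed=10)
        assert post.pooled("slope").mean() == pytest.approx(0.8, abs=0.05)
        assert post.pooled("rho0").mean() == pytest.approx(0.5, abs=0.1)

    def test_same_seed_identical(self):
        at = st.simulate_sinusoid_ar1(st.SinusoidTrendSpec(years=2), 0)
        wt = st.RegularSeries(1, 2 + 0.5 * at.values)
        m = st.build_m0(wt, at)
        p1 = quiet_fit(m, n_chains=2, n_burn=50, n_keep=50, seed=3)
        p2 = quiet_fit(m, n_chains=2, n_burn=50, n_keep=50, seed=3)
        np.testing.assert_array_equal(p1["slope"], p2["slope"])

    def test_all_missing_air_temperature(self):
        wt = st.RegularSeries(1, np.ones(73))
        at = st.RegularSeries(1, np.full(73, np.nan))
        with pytest.raises(ValueError, match="missing"):
            st.build_m0(wt, at)

    def test_missing_cells_become_latent_nodes(self):
        at = st.simulate_sinusoid_ar1(
            st.SinusoidTrendSpec(12, 0, 6, ar_innov_var=0.5, years=2), 4
        )
        eps = ar1_path(np.random.default_rng(5), 0.4, 0.5, len(at))
        wt = st.RegularSeries(1, 1.0 + 0.9 * at.values + eps)
        wt.values[[5, 6]] = np.nan
        at.values[[40, 90]] = np.nan
        post = quiet_fit(st.build_m0(wt, at), n_chains=2, n_burn=200, n_keep=200, seed=6)
        assert post["wt_missing"].shape[2] == 2
        assert post["at_missing"].shape[2] == 2
        # imputed air temperatures stay within a plausible range
        assert np.all(np.abs(post.pooled("at_missing").mean(axis=0)) < 30)

    def test_degenerate_forecast_is_affine(self):
        post = PosteriorDraws(
            {
                "intercept": np.full((1, 30), 2.0),
                "slope": np.full((1, 30), 0.5),
                "rho0": np.zeros((1, 30)),
                "ivar0": np.zeros((1, 30)),
            }
        )
        at_p = st.simulate_sinusoid_ar1(
            st.SinusoidTrendSpec(10, 0, 5, ar_innov_var=0, years=1), 0
        )
        pred = st.forecast_m0(post, at_p, seed=0, n_draws=10)
        np.testing.assert_allclose(pred.mean, 2.0 + 0.5 * at_p.values, atol=1e-12)
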