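"""Baseline Bayesian linear regression of water on air temperature.

``WT_t = a + b * AT_t + eps_t`` on the 5-day grid, with AR(1) residuals.
Air temperature is a fixed covariate (it is not modelled); missing WT cells
are latent variables of the AR(1) process and missing AT cells get an
independent vague Normal prior.  The model deliberately confounds seasonal
synchrony with long-term association — it is the approach whose forecasting
bias the hierarchical model corrects.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from ._mcmc import (
    AdaptiveScale,
    ar1_path,
    metropolis_rho,
    metropolis_var,
    sample_mvn_prec,
)
from .draws import PosteriorDraws, PredictiveSeries
from .grid import RegularSeries
from .model_m1 import _Setup
from .params import MCMCProfile, PriorConfig

__all__ = ["M0Model", "build_m0", "fit_m0", "forecast_m0"]


class M0Model:
    def __init__(self, wt: RegularSeries, at: RegularSeries, priors: PriorConfig):
        if len(wt) != len(at) or wt.start_year != at.start_year:
            raise ValueError("grid mismatch between wt and at")
        if not np.isfinite(at.values).any():
            raise ValueError("air temperature series is entirely missing")
        self.wt, self.at, self.priors = wt, at, priors

    def fit(
        self,
        n_chains: int = 3,
        n_burn: int = 20000,
        n_keep: int = 20000,
        seed: int = 0,
        profile: MCMCProfile | None = None,
        thin: int = 1,
    ) -> PosteriorDraws:
        if profile is not None:
            n_chains, n_burn, n_keep = profile.n_chains, profile.n_burn, profile.n_keep
        rng = np.random.default_rng(seed)
        C, N = n_chains, len(self.wt)
        pri = self.priors
        wt_obs = ~self.wt.missing_mask
        at_obs = ~self.at.missing_mask
        miss_wt = np.nonzero(~wt_obs)[0]
        miss_at = np.nonzero(~at_obs)[0]

        # completed series, per chain
        wt_c = np.where(wt_obs, self.wt.values, np.nanmean(self.wt.values))
        at_c = np.where(at_obs, self.at.values, np.nanmean(self.at.values))
        wt_c = np.broadcast_to(wt_c, (C, N)).copy()
        at_c = np.broadcast_to(at_c, (C, N)).copy()

        # initial OLS + jitter
        b0 = np.polyfit(at_c[0], wt_c[0], 1)
        slope = b0[0] + 0.1 * rng.standard_normal(C)
        icept = b0[1] + 0.3 * rng.standard_normal(C)
        resid0 = wt_c[0] - (b0[1] + b0[0] * at_c[0])
        r = float(np.clip(resid0[:-1] @ resid0[1:] / max(resid0 @ resid0, 1e-12), -0.85, 0.85))
        rho = np.clip(r + 0.1 * rng.standard_normal(C), -0.9, 0.9)
        ivar = max(np.var(resid0) * (1 - r**2), 1e-3) * np.exp(
            0.3 * rng.standard_normal(C)
        )
        sc_rho = AdaptiveScale(C, 0.1)
        sc_var = AdaptiveScale(C, 0.3)

        kept = n_keep // thin
        store = {
            "intercept": np.empty((C, kept)),
            "slope": np.empty((C, kept)),
            "rho0": np.empty((C, kept)),
            "ivar0": np.empty((C, kept)),
        }
        if miss_wt.size:
            store["wt_missing"] = np.empty((C, kept, miss_wt.size))
        if miss_at.size:
            store["at_missing"] = np.empty((C, kept, miss_at.size))
        miss_wt_par = [miss_wt[miss_wt % 2 == 0], miss_wt[miss_wt % 2 == 1]]
        miss_at_par = [miss_at[miss_at % 2 == 0], miss_at[miss_at % 2 == 1]]
        eye2 = np.eye(2)

        def quad_stats(eps):
            a = np.einsum("ij,ij->i", eps[:, 1:], eps[:, 1:])
            b = np.einsum("ij,ij->i", eps[:, 1:], eps[:, :-1])
            c = np.einsum("ij,ij->i", eps[:, :-1], eps[:, :-1])
            return a, b, c, eps[:, 0] ** 2

        for it in range(n_burn + n_keep):
            # --- (intercept, slope): conjugate via whitened regression
            sq = np.sqrt(1 - rho**2)
            ones = np.ones((C, N))
            U1 = np.empty((C, N))
            U2 = np.empty((C, N))
            Dv = np.empty((C, N))
            U1[:, 0] = sq
            U2[:, 0] = sq * at_c[:, 0]
            Dv[:, 0] = sq * wt_c[:, 0]
            U1[:, 1:] = 1.0 - rho[:, None]
            U2[:, 1:] = at_c[:, 1:] - rho[:, None] * at_c[:, :-1]
            Dv[:, 1:] = wt_c[:, 1:] - rho[:, None] * wt_c[:, :-1]
            U = np.stack([U1, U2], axis=2)
            prec = np.einsum("cnk,cnl->ckl", U, U) / ivar[:, None, None] + eye2 / pri.mean_var
            lin = np.einsum("cnk,cn->ck", U, Dv) / ivar[:, None]
            coef = sample_mvn_prec(rng, prec, lin)
            icept, slope = coef[:, 0], coef[:, 1]

            # --- rho, innovation variance
            eps = wt_c - icept[:, None] - slope[:, None] * at_c
            quad = quad_stats(eps)
            rho = metropolis_rho(rng, rho, quad, ivar, sc_rho)
            a, b, c, e0 = quad
            ssq = (1 - rho**2) * e0 + a - 2 * rho * b + rho**2 * c
            ivar = metropolis_var(rng, ivar, ssq, N, pri, sc_var)

            # --- latent missing WT cells (AR(1) bridge)
            mu = icept[:, None] + slope[:, None] * at_c
            for J in miss_wt_par:
                if not J.size:
                    continue
                eps = wt_c - mu
                hp = (J > 0).astype(float)
                hn = (J < N - 1).astype(float)
                prev = eps[:, np.maximum(J - 1, 0)]
                nxt = eps[:, np.minimum(J + 1, N - 1)]
                rr, iv = rho[:, None], ivar[:, None]
                prc = (hp + hn * rr**2 + (1 - hp) * (1 - rr**2)) / iv
                ln = (hp * rr * prev + hn * rr * nxt) / iv
                wt_c[:, J] = mu[:, J] + ln / prc + rng.standard_normal((C, J.size)) / np.sqrt(prc)

            # --- latent missing AT cells (vague Normal prior)
            for J in miss_at_par:
                if not J.size:
                    continue
                eps = wt_c - icept[:, None] - slope[:, None] * at_c
                qv = wt_c[:, J] - icept[:, None]  # = b*z + eps at cell J
                hp = (J > 0).astype(float)
                hn = (J < N - 1).astype(float)
                first = (J == 0).astype(float)
                prev = eps[:, np.maximum(J - 1, 0)]
                nxt = eps[:, np.minimum(J + 1, N - 1)]
                rr, iv, bb = rho[:, None], ivar[:, None], slope[:, None]
                prc = (hp * bb**2 + hn * rr**2 * bb**2 + first * (1 - rr**2) * bb**2) / iv
                prc = prc + 1.0 / pri.mean_var
                ln = (
                    hp * bb * (qv - rr * prev)
                    - hn * rr * bb * (nxt - rr * qv)
                    + first * (1 - rr**2) * bb * qv
                ) / iv
                at_c[:, J] = ln / prc + rng.standard_normal((C, J.size)) / np.sqrt(prc)

            if it == n_burn - 1:
                sc_rho.frozen = sc_var.frozen = True
            if it >= n_burn and (it - n_burn) % thin == 0:
                j = (it - n_burn) // thin
                store["intercept"][:, j] = icept
                store["slope"][:, j] = slope
                store["rho0"][:, j] = rho
                store["ivar0"][:, j] = ivar
                if miss_wt.size:
                    store["wt_missing"][:, j] = wt_c[:, miss_wt]
                if miss_at.size:
                    store["at_missing"][:, j] = at_c[:, miss_at]

        post = PosteriorDraws(
            store,
            meta={
                "model": "M0",
                "seed": seed,
                "n_chains": C,
                "n_burn": n_burn,
                "n_keep": n_keep,
                "start_year": self.wt.start_year,
                "missing_index": {"wt": miss_wt.tolist(), "at": miss_at.tolist()},
            },
        )
        mr = post.max_rhat()
        post.meta["max_rhat"] = mr
        if mr > 1.05:
            warnings.warn(
                f"maximum split R-hat {mr:.3f} exceeds 1.05; consider a longer run",
                stacklevel=2,
            )
        return post

    def forecast(
        self,
        posterior: PosteriorDraws,
        at_prime: RegularSeries,
        seed: int = 0,
        n_draws: int = 400,
    ) -> PredictiveSeries:
        return forecast_m0(posterior, at_prime, seed=seed, n_draws=n_draws)

    # -------------------------------------------- diagnostics ingredients --

    def _completed(self, sub: dict, shape) -> tuple:
        wt_obs = ~self.wt.missing_mask
        at_obs = ~self.at.missing_mask
        at_c = np.broadcast_to(np.where(at_obs, self.at.values, 0.0), shape).copy()
        if "at_missing" in sub:
            at_c[:, ~at_obs] = sub["at_missing"]
        wt_c = np.broadcast_to(np.where(wt_obs, self.wt.values, 0.0), shape).copy()
        if "wt_missing" in sub:
            wt_c[:, ~wt_obs] = sub["wt_missing"]
        return wt_c, at_c, wt_obs

    def predictive_setup(self, sub: dict) -> _Setup:
        D = sub["slope"].shape[0]
        shape = (D, len(self.wt))
        wt_c, at_c, wt_obs = self._completed(sub, shape)
        mu = sub["intercept"][:, None] + sub["slope"][:, None] * at_c
        return _Setup(mu, sub["rho0"], sub["ivar0"], wt_c, wt_obs)

    def point_setup(self, posterior: PosteriorDraws) -> _Setup:
        sub = {nm: posterior.pooled(nm).mean(axis=0, keepdims=True) for nm in posterior.names()}
        return self.predictive_setup(sub)


def build_m0(wt, at, priors: PriorConfig | None = None) -> M0Model:
    return M0Model(wt, at, priors or PriorConfig())


def fit_m0(wt, at, priors=None, seed: int = 0, profile: MCMCProfile | None = None, **kw):
    """Convenience: build and fit in one call."""
    return build_m0(wt, at, priors).fit(seed=seed, profile=profile, **kw)


def forecast_m0(
    posterior: PosteriorDraws,
    at_prime: RegularSeries,
    seed: int = 0,
    n_draws: int = 400,
) -> PredictiveSeries:
    """Posterior-predictive WT' = a + b AT' + AR(1) noise per draw."""
    if not np.isfinite(at_prime.values).all():
        raise ValueError("scenario air temperature must be complete")
    rng = np.random.default_rng(seed)
    sub = posterior.subsample(n_draws, rng)
    mu = sub["intercept"][:, None] + sub["slope"][:, None] * at_prime.values[None, :]
    eps = ar1_path(rng, sub["rho0"], sub["ivar0"], len(at_prime))
    return PredictiveSeries(at_prime.start_year, mu + eps)
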