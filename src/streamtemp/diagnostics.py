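"""Posterior checking, model comparison and descriptive statistics.

The chi-square discrepancy and the deviance both condition on the AR(1)
one-step-ahead moments of the water-temperature series,

    E_t = mu_t + rho (x_{t-1} - mu_{t-1}),   Var_t = innov_var,

with the stationary moments (mu_0, innov_var / (1 - rho^2)) for the first
step; products over these conditionals are the exact joint AR(1) density.
Only observed cells enter the sums; latent (imputed) cells contribute via
the conditioning values, which is also how the fitted latent nodes inflate
the effective number of parameters pD when data are missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from ._mcmc import ar1_path
from .draws import PosteriorDraws, split_rhat
from .grid import RegularSeries
from .model_m0 import M0Model
from .model_m1 import M1Model
from .params import MCMCProfile

__all__ = [
    "DiscrepancyResult",
    "DicResult",
    "CvResult",
    "chi2_check",
    "dic",
    "cross_validate",
    "pearson_r",
    "gelman_rubin",
]

LOG2PI = float(np.log(2 * np.pi))


@dataclass
class DiscrepancyResult:
    d_obs: np.ndarray
    d_rep: np.ndarray
    bayes_p: float


@dataclass
class DicResult:
    dev_mean: float  # posterior mean deviance (Dbar)
    pd: float  # effective number of parameters
    dic: float


@dataclass
class CvResult:
    rmse: float
    n_forecast: int


def _conditional_moments(setup, x=None):
    """One-step conditional mean/variance arrays (D, N) given parameters."""
    x = setup.x if x is None else x
    mu, rho, ivar = setup.mu, setup.rho[:, None], setup.ivar[:, None]
    E = np.empty_like(mu)
    V = np.empty_like(mu)
    E[:, 0] = mu[:, 0]
    V[:, 0] = (ivar / (1 - rho**2))[:, 0]
    E[:, 1:] = mu[:, 1:] + rho * (x[:, :-1] - mu[:, :-1])
    V[:, 1:] = ivar
    return E, V


def _chi2_sum(x, E, V, obs):
    return (((x - E) ** 2 / V)[:, obs]).sum(axis=1)


def chi2_check(model, posterior: PosteriorDraws, seed: int = 0, n_draws: int = 300) -> DiscrepancyResult:
    """Posterior-predictive chi-square check of the water-temperature fit.

    For each posterior draw the realised discrepancy (observed data) is
    compared with the discrepancy of a replicate series simulated under the
    same parameters; the Bayesian p-value is P(D_rep >= D_obs), with values
    near 0.5 indicating self-consistency.
    """
    rng = np.random.default_rng(seed)
    sub = posterior.subsample(n_draws, rng)
    setup = model.predictive_setup(sub)
    if np.any(setup.ivar <= 0):
        raise ValueError("zero conditional variance in a posterior draw")
    E, V = _conditional_moments(setup)
    d_obs = _chi2_sum(setup.x, E, V, setup.obs)
    x_rep = setup.mu + ar1_path(rng, setup.rho, setup.ivar, setup.mu.shape[1])
    E_rep, V_rep = _conditional_moments(setup, x_rep)
    d_rep = _chi2_sum(x_rep, E_rep, V_rep, setup.obs)
    return DiscrepancyResult(d_obs, d_rep, float(np.mean(d_rep >= d_obs)))


def _deviance(setup) -> np.ndarray:
    E, V = _conditional_moments(setup)
    ll = -0.5 * (LOG2PI + np.log(V) + (setup.x - E) ** 2 / V)
    dev = -2.0 * ll[:, setup.obs].sum(axis=1)
    if not np.isfinite(dev).all():
        bad = np.nonzero(~np.isfinite(dev))[0]
        raise ValueError(f"non-finite deviance in draws {bad.tolist()}")
    return dev


def dic(model, posterior: PosteriorDraws, n_draws: int = 500, seed: int = 0) -> DicResult:
    """Deviance Information Criterion of the water-temperature likelihood.

    ``Dbar`` is the posterior-mean deviance, the plug-in deviance is taken
    at the posterior mean of all parameters and latent nodes (circular mean
    for phases), ``pD = Dbar - D(thetabar)`` and ``DIC = Dbar + pD``.
    """
    rng = np.random.default_rng(seed)
    sub = posterior.subsample(n_draws, rng)
    dev = _deviance(model.predictive_setup(sub))
    d_hat = float(_deviance(model.point_setup(posterior))[0])
    dbar = float(dev.mean())
    pd_ = dbar - d_hat
    return DicResult(dbar, pd_, dbar + pd_)


def cross_validate(
    model_builder: Callable,
    wt: RegularSeries,
    at: RegularSeries,
    q: Optional[RegularSeries] = None,
    split: float = 2 / 3,
    seed: int = 0,
    profile: MCMCProfile | None = None,
    n_draws: int = 400,
    **fit_kw,
) -> CvResult:
    """Fit on the first ``split`` of the years, forecast the rest, score RMSE.

    ``model_builder(wt, at, q)`` must return a built model exposing
    ``fit``/``forecast`` (``q`` is ignored by the baseline model).  The RMSE
    compares the posterior-predictive mean against held-out observed WT.
    """
    ny = wt.n_years
    n_train = int(round(split * ny))
    if n_train < 1 or ny - n_train < 1:
        raise ValueError("split leaves fewer than 2 windows in one segment")
    parts = {}
    for nm, s in (("wt", wt), ("at", at), ("q", q)):
        if s is None:
            parts[nm] = (None, None)
        else:
            parts[nm] = (s.slice_years(0, n_train), s.slice_years(n_train, ny - n_train))
    model = model_builder(parts["wt"][0], parts["at"][0], parts["q"][0])
    post = model.fit(seed=seed, profile=profile, **fit_kw)

    at_test = parts["at"][1]
    if at_test.missing_mask.any():  # fill from training climatology
        clim = np.array(
            [np.nanmean(parts["at"][0].values[parts["at"][0].t == tt]) for tt in range(1, 74)]
        )
        vals = at_test.values.copy()
        vals[at_test.missing_mask] = clim[at_test.t[at_test.missing_mask] - 1]
        at_test = RegularSeries(at_test.start_year, vals, at_test.name)
    if isinstance(model, M0Model):
        pred = model.forecast(post, at_test, seed=seed + 1, n_draws=n_draws)
    else:
        pred = model.forecast(post, at_test, parts["q"][1], seed=seed + 1, n_draws=n_draws)

    wt_test = parts["wt"][1]
    ok = ~wt_test.missing_mask
    err = pred.mean[ok] - wt_test.values[ok]
    return CvResult(float(np.sqrt(np.mean(err**2))), int(ok.sum()))


def pearson_r(x, y):
    """Pearson correlation over pairwise-complete cells, with p-value."""
    x = x.values if hasattr(x, "values") else np.asarray(x, float)
    y = y.values if hasattr(y, "values") else np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-missing values")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance in an input")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def gelman_rubin(draws, min_draws: int = 10):
    """Potential scale reduction factor(s).

    Accepts a (chains, iterations) array (returns a float) or a
    :class:`PosteriorDraws` (returns a dict over scalar components).
    """
    if isinstance(draws, PosteriorDraws):
        return draws.rhat()
    a = np.asarray(draws, float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    if a.shape[1] < min_draws:
        raise ValueError(f"need at least {min_draws} draws per chain")
    return split_rhat(a)
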