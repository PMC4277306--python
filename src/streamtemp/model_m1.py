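"""Hierarchical Bayesian time-series model of stream water temperature.

The joint model couples three sub-models in one posterior:

1. *Decomposition* — air temperature and log-discharge each follow
   ``X_{y,t} = alpha_y + beta_y sin(2 pi t/73 + phi) + eps`` with 6-month
   window means/amplitudes, a shared phase and AR(1) residuals.
2. *Linkage* — the water-temperature window extrema are linear functions of
   the predictor extrema:
   ``WT_max,y = a0 + a_at AT_max,y + a_q Q_min,y + N(0, var_max)`` and
   ``WT_min,y = b0 + b_at AT_min,y + b_q Q_max,y + N(0, var_min)``
   (discharge on the log scale; the a_q/b_q terms drop out of the reduced,
   air-temperature-only variant).
3. *Forecasting* — scenario series AT', Q' are decomposed window by window
   (least-squares projection onto {1, sin} at each posterior phase draw) and
   pushed through the linkage and the AR(1) noise to give the posterior
   predictive distribution of WT'.

Missing observations in any series are latent variables sampled along with
the parameters, so fitting doubles as imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np

from ._mcmc import (
    AdaptiveScale,
    SeriesBlock,
    ar1_path,
    metropolis_var,
    sample_mvn_prec,
)
from .draws import PosteriorDraws, PredictiveSeries
from .grid import STEPS_PER_YEAR, RegularSeries
from .params import TWO_PI, MCMCProfile, PriorConfig, decomposition_from, extrema_from

__all__ = [
    "M1Model",
    "build_m1",
    "forecast_from_draws",
    "extrema_from",
    "decomposition_from",
]

RHAT_WARN = 1.05


@dataclass
class _Setup:
    """Per-draw conditional ingredients of the WT likelihood."""

    mu: np.ndarray  # (D, N) seasonal mean
    rho: np.ndarray  # (D,)
    ivar: np.ndarray  # (D,)
    x: np.ndarray  # (D, N) data with latent values filled in
    obs: np.ndarray  # (N,) bool


class M1Model:
    """Built model specification; see :func:`build_m1`."""

    def __init__(self, wt, at, q, priors: PriorConfig):
        self.wt, self.at, self.q = wt, at, q
        self.priors = priors
        self.reduced = q is None

    @property
    def n_latent_missing(self) -> int:
        n = int(self.wt.missing_mask.sum() + self.at.missing_mask.sum())
        if self.q is not None:
            n += int(self.q.missing_mask.sum())
        return n

    # ----------------------------------------------------------------- fit --

    def fit(
        self,
        n_chains: int = 3,
        n_burn: int = 20000,
        n_keep: int = 20000,
        seed: int = 0,
        profile: MCMCProfile | None = None,
        thin: int = 1,
    ) -> PosteriorDraws:
        """Run the Metropolis-within-Gibbs sampler.

        Returns labelled draws with split-chain R-hat attached; a warning is
        emitted when any R-hat exceeds 1.05.
        """
        if profile is not None:
            n_chains, n_burn, n_keep = profile.n_chains, profile.n_burn, profile.n_keep
        rng = np.random.default_rng(seed)
        C = n_chains
        wt, at, q = self.wt, self.at, self.q
        win = wt.window - 1
        t = wt.t
        pri = self.priors

        at_b = SeriesBlock(at.values, win, t, C, rng, pri, "amp_uniform")
        q_b = (
            SeriesBlock(np.log(q.values), win, t, C, rng, pri, "amp_uniform")
            if q is not None
            else None
        )
        wt_b = SeriesBlock(wt.values, win, t, C, rng, pri, "linked")
        Y = wt_b.Y
        k = 2 if self.reduced else 3

        # linkage state: start from an LS fit on the initial window extrema
        acoef = np.zeros((C, k))
        bcoef = np.zeros((C, k))
        var_max = np.ones(C)
        var_min = np.ones(C)
        sc_vmax = AdaptiveScale(C, 0.3)
        sc_vmin = AdaptiveScale(C, 0.3)
        sc_vmax_nc = AdaptiveScale(C, 0.5)
        sc_vmin_nc = AdaptiveScale(C, 0.5)

        kept = n_keep // thin
        store = {
            "at_alpha": np.empty((C, kept, Y)),
            "at_beta": np.empty((C, kept, Y)),
            "at_phi": np.empty((C, kept)),
            "at_rho": np.empty((C, kept)),
            "at_ivar": np.empty((C, kept)),
            "wt_max": np.empty((C, kept, Y)),
            "wt_min": np.empty((C, kept, Y)),
            "wt_phi": np.empty((C, kept)),
            "wt_rho": np.empty((C, kept)),
            "wt_ivar": np.empty((C, kept)),
            "a0": np.empty((C, kept)),
            "a_at": np.empty((C, kept)),
            "b0": np.empty((C, kept)),
            "b_at": np.empty((C, kept)),
            "var_max": np.empty((C, kept)),
            "var_min": np.empty((C, kept)),
        }
        if q is not None:
            for nm in ("q_alpha", "q_beta"):
                store[nm] = np.empty((C, kept, Y))
            for nm in ("q_phi", "q_rho", "q_ivar"):
                store[nm] = np.empty((C, kept))
            store["a_q"] = np.empty((C, kept))
            store["b_q"] = np.empty((C, kept))
        miss_ix = {
            "wt": np.nonzero(wt.missing_mask)[0],
            "at": np.nonzero(at.missing_mask)[0],
        }
        if q is not None:
            miss_ix["q"] = np.nonzero(q.missing_mask)[0]
        for nm, ix in miss_ix.items():
            if ix.size:
                store[f"{nm}_missing"] = np.empty((C, kept, ix.size))

        eye = np.eye(k)
        for it in range(n_burn + n_keep):
            at_b.update_all(rng)
            if q_b is not None:
                q_b.update_all(rng)

            at_max = at_b.alpha + at_b.beta
            at_min = at_b.alpha - at_b.beta
            cols_max = [np.ones((C, Y)), at_max]
            cols_min = [np.ones((C, Y)), at_min]
            if q_b is not None:
                cols_max.append(q_b.alpha - q_b.beta)  # Q_min
                cols_min.append(q_b.alpha + q_b.beta)  # Q_max
            Xmax = np.stack(cols_max, axis=2)  # (C, Y, k)
            Xmin = np.stack(cols_min, axis=2)

            pm_max = np.einsum("cyk,ck->cy", Xmax, acoef)
            pm_min = np.einsum("cyk,ck->cy", Xmin, bcoef)
            wt_b.update_windows(rng, pm_max, pm_min, var_max, var_min)
            wt_b.update_phi(rng)
            wt_b.update_rho(rng)
            wt_b.update_ivar(rng)
            wt_b.update_missing(rng)

            y_max = wt_b.alpha + wt_b.beta
            y_min = wt_b.alpha - wt_b.beta
            for X, yv, v, which in (
                (Xmax, y_max, var_max, "max"),
                (Xmin, y_min, var_min, "min"),
            ):
                prec = (
                    np.einsum("cyk,cyl->ckl", X, X) / v[:, None, None]
                    + eye / pri.mean_var
                )
                lin = np.einsum("cyk,cy->ck", X, yv) / v[:, None]
                coef = sample_mvn_prec(rng, prec, lin)
                resid = yv - np.einsum("cyk,ck->cy", X, coef)
                ssq = np.einsum("cy,cy->c", resid, resid)
                if which == "max":
                    acoef = coef
                    var_max = metropolis_var(rng, v, ssq, Y, pri, sc_vmax)
                else:
                    bcoef = coef
                    var_min = metropolis_var(rng, v, ssq, Y, pri, sc_vmin)

            # Interweaving (ancillarity-sufficiency) sweep: the centred
            # updates above mix poorly when var_max/var_min are small, so we
            # re-sample the linkage coefficients with the window-level
            # *residuals* held fixed, and make a non-centred variance move
            # that rescales those residuals.  Together the two
            # parameterisations mix well across all variance regimes.
            acoef, var_max = _interweave_side(
                rng, wt_b, Xmax, acoef, var_max, "max", pri, sc_vmax_nc
            )
            bcoef, var_min = _interweave_side(
                rng, wt_b, Xmin, bcoef, var_min, "min", pri, sc_vmin_nc
            )

            if it == n_burn - 1:
                for blk in filter(None, (at_b, q_b, wt_b)):
                    blk.freeze_adaptation()
                sc_vmax.frozen = sc_vmin.frozen = True
                sc_vmax_nc.frozen = sc_vmin_nc.frozen = True
            if it >= n_burn and (it - n_burn) % thin == 0:
                j = (it - n_burn) // thin
                store["at_alpha"][:, j] = at_b.alpha
                store["at_beta"][:, j] = at_b.beta
                store["at_phi"][:, j] = at_b.phi
                store["at_rho"][:, j] = at_b.rho
                store["at_ivar"][:, j] = at_b.ivar
                store["wt_max"][:, j] = y_max
                store["wt_min"][:, j] = y_min
                store["wt_phi"][:, j] = wt_b.phi
                store["wt_rho"][:, j] = wt_b.rho
                store["wt_ivar"][:, j] = wt_b.ivar
                store["a0"][:, j] = acoef[:, 0]
                store["a_at"][:, j] = acoef[:, 1]
                store["b0"][:, j] = bcoef[:, 0]
                store["b_at"][:, j] = bcoef[:, 1]
                store["var_max"][:, j] = var_max
                store["var_min"][:, j] = var_min
                if q_b is not None:
                    store["q_alpha"][:, j] = q_b.alpha
                    store["q_beta"][:, j] = q_b.beta
                    store["q_phi"][:, j] = q_b.phi
                    store["q_rho"][:, j] = q_b.rho
                    store["q_ivar"][:, j] = q_b.ivar
                    store["a_q"][:, j] = acoef[:, 2]
                    store["b_q"][:, j] = bcoef[:, 2]
                for nm, blk in (("wt", wt_b), ("at", at_b), ("q", q_b)):
                    if blk is None or not miss_ix[nm].size:
                        continue
                    vals = blk.xc[:, miss_ix[nm]]
                    if nm == "q":
                        vals = np.exp(vals)
                    store[f"{nm}_missing"][:, j] = vals

        post = PosteriorDraws(
            store,
            meta={
                "model": "M1-reduced" if self.reduced else "M1",
                "seed": seed,
                "n_chains": C,
                "n_burn": n_burn,
                "n_keep": n_keep,
                "thin": thin,
                "start_year": self.wt.start_year,
                "missing_index": {k_: v.tolist() for k_, v in miss_ix.items()},
                "neg_amplitude_freq": float(np.mean(store["wt_max"] < store["wt_min"])),
            },
        )
        mr = post.max_rhat()
        post.meta["max_rhat"] = mr
        if mr > RHAT_WARN:
            warnings.warn(
                f"maximum split R-hat {mr:.3f} exceeds {RHAT_WARN}; "
                "consider a longer run",
                stacklevel=2,
            )
        return post

    # ------------------------------------------------------------ forecast --

    def forecast(
        self,
        posterior: PosteriorDraws,
        at_prime: RegularSeries,
        q_prime: Optional[RegularSeries] = None,
        seed: int = 0,
        n_draws: int = 400,
    ) -> PredictiveSeries:
        if self.reduced and q_prime is not None:
            raise ValueError("reduced model takes no discharge scenario")
        if not self.reduced and q_prime is None:
            raise ValueError("full model requires a discharge scenario")
        return forecast_from_draws(posterior, at_prime, q_prime, seed, n_draws)

    # -------------------------------------------------------------- impute --

    def impute(self, posterior: PosteriorDraws, cells=None) -> PredictiveSeries:
        """Posterior draws of missing water-temperature cells.

        ``cells``: 0-based offsets into the WT series; defaults to every
        missing cell.  Requesting an observed cell is an error.
        """
        miss = np.asarray(posterior.meta["missing_index"]["wt"], int)
        if miss.size == 0:
            raise ValueError("model was fitted to fully observed WT data")
        if cells is None:
            cells = miss
        cells = np.atleast_1d(np.asarray(cells, int))
        bad = np.setdiff1d(cells, miss)
        if bad.size:
            raise ValueError(f"cells {bad.tolist()} were observed at fit time")
        pos = np.searchsorted(miss, cells)
        draws = posterior.pooled("wt_missing")[:, pos]
        return PredictiveSeries(self.wt.start_year, draws, index=cells)

    # -------------------------------------------- diagnostics ingredients --

    def _mu_from(self, sub: dict) -> np.ndarray:
        win = self.wt.window - 1
        s = np.sin(TWO_PI * self.wt.t[None, :] / STEPS_PER_YEAR + sub["wt_phi"][:, None])
        alpha = (sub["wt_max"] + sub["wt_min"]) / 2.0
        beta = (sub["wt_max"] - sub["wt_min"]) / 2.0
        return alpha[:, win] + beta[:, win] * s

    def predictive_setup(self, sub: dict) -> _Setup:
        mu = self._mu_from(sub)
        obs = ~self.wt.missing_mask
        x = np.broadcast_to(np.where(obs, self.wt.values, 0.0), mu.shape).copy()
        if "wt_missing" in sub:
            x[:, ~obs] = sub["wt_missing"]
        return _Setup(mu, sub["wt_rho"], sub["wt_ivar"], x, obs)

    def point_setup(self, posterior: PosteriorDraws) -> _Setup:
        """Plug-in setup at the posterior mean (circular mean for the phase)."""
        sub = {}
        for nm in posterior.names():
            if not (nm.startswith("wt_") or nm in ()):
                continue
            a = posterior.pooled(nm)
            if nm.endswith("_phi"):
                sub[nm] = np.atleast_1d(
                    np.arctan2(np.sin(a).mean(), np.cos(a).mean()) % TWO_PI
                )
            else:
                sub[nm] = a.mean(axis=0, keepdims=True)
        return self.predictive_setup(sub)


def _interweave_side(rng, wt_b, X, coef, v, side, pri, sc_nc):
    """Non-centred re-sample of one linkage regression (max or min side).

    With the window residuals eta_y = extremum_y - x_y' coef held fixed, the
    coefficients enter the WT likelihood linearly and get a conjugate
    Gaussian update; the variance then moves by a random-walk on its log
    with the standardised residuals held fixed (the extrema rescale with
    sqrt(v'/v)).
    """
    C, N, k = X.shape[0], wt_b.N, X.shape[2]
    s = wt_b.sin_t()
    win = wt_b.win
    if side == "max":
        ce, co = (1 + s) / 2.0, (1 - s) / 2.0
        e = wt_b.alpha + wt_b.beta
        o = wt_b.alpha - wt_b.beta
    else:
        ce, co = (1 - s) / 2.0, (1 + s) / 2.0
        e = wt_b.alpha - wt_b.beta
        o = wt_b.alpha + wt_b.beta
    line = np.einsum("cyk,ck->cy", X, coef)
    eta = e - line

    # conjugate coefficient draw given eta
    G = ce[:, :, None] * X[:, win, :]
    W = np.stack([wt_b._whiten(G[:, :, j]) for j in range(k)], axis=2)
    target = wt_b.xc - co * o[:, win] - ce * eta[:, win]
    Dw = wt_b._whiten(target)
    iv = wt_b.ivar[:, None, None]
    prec = np.einsum("cnk,cnl->ckl", W, W) / iv + np.eye(k) / pri.mean_var
    lin = np.einsum("cnk,cn->ck", W, Dw) / iv[:, :, 0]
    coef = sample_mvn_prec(rng, prec, lin)
    line = np.einsum("cyk,ck->cy", X, coef)
    e = line + eta

    # non-centred variance move: rescale residuals with sqrt(v'/v)
    from ._mcmc import VAR_FLOOR

    v_new = v * np.exp(sc_nc.scale * rng.standard_normal(C))
    ok = v_new > VAR_FLOOR
    v_new = np.where(ok, v_new, v)
    e_prop = line + eta * np.sqrt(v_new / v)[:, None]

    def ll(ev):
        eps = wt_b.xc - ce * ev[:, win] - co * o[:, win]
        return -0.5 * wt_b.sum_sq(eps) / wt_b.ivar

    logr = (
        ll(e_prop) - ll(e)
        + pri.var_logpdf(v_new) - pri.var_logpdf(v)
        + np.log(v_new) - np.log(v)
    )
    acc = (np.log(rng.uniform(size=C)) < logr) & ok
    sc_nc.record(acc)
    v = np.where(acc, v_new, v)
    e = np.where(acc[:, None], e_prop, e)

    if side == "max":
        wt_b.alpha = (e + o) / 2.0
        wt_b.beta = (e - o) / 2.0
    else:
        wt_b.alpha = (o + e) / 2.0
        wt_b.beta = (o - e) / 2.0
    return coef, v


def build_m1(
    wt: RegularSeries,
    at: RegularSeries,
    q: Optional[RegularSeries] = None,
    priors: PriorConfig | None = None,
) -> M1Model:
    """Assemble the joint hierarchical model.

    ``q=None`` selects the reduced variant using air temperature as the only
    predictor.  All series must share the same grid; discharge must be
    strictly positive wherever observed (it is modelled on the log scale).
    """
    priors = priors or PriorConfig()
    for other, nm in ((at, "at"), (q, "q")):
        if other is None:
            continue
        if len(other) != len(wt) or other.start_year != wt.start_year:
            raise ValueError(f"grid mismatch between wt and {nm}")
    if q is not None:
        bad = (~q.missing_mask) & (q.values <= 0)
        if bad.any():
            raise ValueError(
                f"discharge must be positive where observed; first offending "
                f"cell offset {int(np.nonzero(bad)[0][0])}"
            )
    return M1Model(wt, at, q, priors)


def _decompose_scenario(values, t, win, Y, phi):
    """Window-wise least-squares projection onto {1, sin(. + phi)} per draw.

    ``phi``: (D,).  Returns (alpha, beta) each (D, Y).  Missing cells are
    ignored; every window needs at least 3 finite values.
    """
    finite = np.isfinite(values)
    counts = np.bincount(win, weights=finite.astype(float), minlength=Y)
    if counts.min() < 3:
        raise ValueError("scenario has a window with fewer than 3 finite values")
    v = np.where(finite, values, 0.0)
    s = np.sin(TWO_PI * t[None, :] / STEPS_PER_YEAR + phi[:, None])
    s = np.where(finite[None, :], s, 0.0)
    n = counts[None, :]
    ssum = np.stack([np.bincount(win, weights=s[d], minlength=Y) for d in range(s.shape[0])])
    s2 = np.stack([np.bincount(win, weights=s[d] ** 2, minlength=Y) for d in range(s.shape[0])])
    xsum = np.bincount(win, weights=v, minlength=Y)[None, :]
    xs = np.stack([np.bincount(win, weights=s[d] * v, minlength=Y) for d in range(s.shape[0])])
    det = n * s2 - ssum**2
    alpha = (s2 * xsum - ssum * xs) / det
    beta = (n * xs - ssum * xsum) / det
    return alpha, beta


def forecast_from_draws(
    posterior: PosteriorDraws,
    at_prime: RegularSeries,
    q_prime: Optional[RegularSeries] = None,
    seed: int = 0,
    n_draws: int = 400,
) -> PredictiveSeries:
    """Posterior-predictive forecast of WT' from scenario series.

    For each retained draw the scenario predictors are decomposed at that
    draw's phases, mapped through the linkage regressions (with regression
    noise), and completed with AR(1) residual noise.
    """
    if at_prime.n_years < 1:
        raise ValueError("scenario must span at least one full window")
    rng = np.random.default_rng(seed)
    sub = posterior.subsample(n_draws, rng)
    D = sub["wt_phi"].shape[0]
    t, win = at_prime.t, at_prime.window - 1
    Y = at_prime.n_windows

    a_at, b_at = _decompose_scenario(at_prime.values, t, win, Y, sub["at_phi"])
    at_max, at_min = a_at + b_at, a_at - b_at
    wt_max = sub["a0"][:, None] + sub["a_at"][:, None] * at_max
    wt_min = sub["b0"][:, None] + sub["b_at"][:, None] * at_min
    if "a_q" in sub:
        if q_prime is None:
            raise ValueError("posterior includes discharge terms; q_prime required")
        if (q_prime.values[np.isfinite(q_prime.values)] <= 0).any():
            raise ValueError("scenario discharge must be positive")
        a_q, b_q = _decompose_scenario(
            np.log(q_prime.values), t, win, Y, sub["q_phi"]
        )
        q_max, q_min = a_q + b_q, a_q - b_q
        wt_max = wt_max + sub["a_q"][:, None] * q_min
        wt_min = wt_min + sub["b_q"][:, None] * q_max
    wt_max = wt_max + np.sqrt(sub["var_max"])[:, None] * rng.standard_normal((D, Y))
    wt_min = wt_min + np.sqrt(sub["var_min"])[:, None] * rng.standard_normal((D, Y))

    alpha = (wt_max + wt_min) / 2.0
    beta = (wt_max - wt_min) / 2.0
    s = np.sin(TWO_PI * t[None, :] / STEPS_PER_YEAR + sub["wt_phi"][:, None])
    mu = alpha[:, win] + beta[:, win] * s
    eps = ar1_path(rng, sub["wt_rho"], sub["wt_ivar"], len(at_prime))
    return PredictiveSeries(at_prime.start_year, mu + eps)
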