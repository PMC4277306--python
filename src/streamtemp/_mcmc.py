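"""Adaptive Metropolis-within-Gibbs machinery for the AR(1)-sinusoid models.

All state arrays carry a leading chain axis so the parallel chains advance
in lock-step through vectorised updates.  Window-level parameters are
updated in two passes over windows of even and odd index: adjacent 6-month
windows share exactly one AR(1) innovation term, so windows of equal parity
are conditionally independent and can be sampled jointly.

Conjugate Gaussian steps are used for window means/amplitudes (or extrema),
regression coefficients and latent missing cells; random-walk Metropolis
steps (scales adapted during burn-in towards ~40% acceptance) handle the
phase, the AR coefficient and the variances, whose Gamma prior on the
variance scale is non-conjugate.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

from .grid import STEPS_PER_YEAR
from .params import TWO_PI, PriorConfig

_ADAPT_BATCH = 50
_TARGET_ACC = 0.40


def ar1_path(rng: np.random.Generator, rho, innov_var, n: int) -> np.ndarray:
    """Stationary AR(1) sample paths.

    ``rho``/``innov_var`` may be scalars or arrays of shape (...,); the
    result has shape (..., n).  The first state is drawn from the stationary
    distribution N(0, innov_var / (1 - rho^2)).
    """
    rho = np.asarray(rho, float)
    innov_var = np.broadcast_to(np.asarray(innov_var, float), rho.shape)
    shape = rho.shape
    out = np.empty(shape + (n,))
    sd = np.sqrt(innov_var)
    z = rng.standard_normal(shape + (n,))
    out[..., 0] = z[..., 0] * sd / np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        out[..., i] = rho * out[..., i - 1] + sd * z[..., i]
    return out


def truncnorm(rng, mean, sd, lo, hi):
    """Vectorised truncated-normal draws via inverse-CDF."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(size=np.shape(mean))
    p = np.clip(a + u * (b - a), 1e-12, 1 - 1e-12)
    return mean + sd * ndtri(p)


class AdaptiveScale:
    """Per-chain random-walk scales tuned during burn-in."""

    def __init__(self, n_chains: int, init: float):
        self.scale = np.full(n_chains, float(init))
        self._acc = np.zeros(n_chains)
        self._count = 0
        self._batches = 0
        self.frozen = False

    def record(self, accepted: np.ndarray) -> None:
        if self.frozen:
            return
        self._acc += accepted
        self._count += 1
        if self._count >= _ADAPT_BATCH:
            rate = self._acc / self._count
            delta = min(0.25, 2.0 / np.sqrt(self._batches + 2))
            self.scale *= np.exp(delta * (rate - _TARGET_ACC))
            self._acc[:] = 0.0
            self._count = 0
            self._batches += 1


def fit_sinusoid_ls(values: np.ndarray, t: np.ndarray, period: float):
    """Least-squares fit of m + A sin(2 pi t/period + phi) to complete data.

    Returns (mean, amplitude, phase, residuals).
    """
    x = TWO_PI * t / period
    X = np.column_stack([np.ones_like(x), np.sin(x), np.cos(x)])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    m, bs, bc = coef
    amp = float(np.hypot(bs, bc))
    phi = float(np.arctan2(bc, bs) % TWO_PI)
    return float(m), amp, phi, values - X @ coef


class SeriesBlock:
    """Sampler state for one decomposed series (AT, log-Q or WT).

    ``prior_kind`` is ``"amp_uniform"`` (independent Normal prior on the
    window mean, Uniform[0, 20] on the amplitude; used for AT and log-Q) or
    ``"linked"`` (Gaussian priors on the window extrema, supplied each
    iteration by the linkage regressions; used for WT).
    """

    def __init__(
        self,
        x_obs: np.ndarray,
        win: np.ndarray,
        t: np.ndarray,
        n_chains: int,
        rng: np.random.Generator,
        priors: PriorConfig,
        prior_kind: str = "amp_uniform",
        period: int = STEPS_PER_YEAR,
    ):
        self.priors = priors
        self.prior_kind = prior_kind
        self.period = period
        self.C = n_chains
        self.N = x_obs.size
        self.win = np.asarray(win, int)  # 0-based window index per step
        self.t = np.asarray(t, float)
        self.Y = int(self.win.max()) + 1
        self.obs = np.isfinite(x_obs)
        if not self.obs.any():
            raise ValueError("series has no observed value")

        # window bookkeeping
        self.wstart = np.array([np.argmax(self.win == y) for y in range(self.Y)])
        self.wnext = np.append(self.wstart[1:], self.N)
        self._parity = []
        for p in (0, 1):
            ys = np.arange(p, self.Y, 2)
            offs, seg_sel = [], []
            k = 0
            for y in ys:
                lo = int(self.wstart[y])
                hi = int(min(self.wnext[y] + 1, self.N))
                offs += [lo, hi]
            # reduceat offsets must stay < N; a trailing hi == N is implicit
            if offs and offs[-1] == self.N:
                offs = offs[:-1]
            seg_sel = np.arange(0, 2 * len(ys), 2)
            self._parity.append((ys, np.array(offs), seg_sel))

        # missing cells, split by index parity so neighbours stay fixed
        miss = np.nonzero(~self.obs)[0]
        self.miss_idx = [miss[miss % 2 == 0], miss[miss % 2 == 1]]

        self._s_cache = None
        self._init_state(x_obs, rng)
        self.sc_phi = AdaptiveScale(n_chains, 0.05)
        self.sc_rho = AdaptiveScale(n_chains, 0.1)
        self.sc_var = AdaptiveScale(n_chains, 0.3)

    # ------------------------------------------------------------- init --

    def _init_state(self, x_obs: np.ndarray, rng) -> None:
        C, N, Y = self.C, self.N, self.Y
        xf = x_obs.copy()
        # fill missing with per-step climatology, then overall mean
        for tt in np.unique(self.t[~self.obs]):
            sel = self.t == tt
            m = xf[sel & self.obs]
            xf[sel & ~self.obs] = m.mean() if m.size else np.nan
        xf[~np.isfinite(xf)] = np.nanmean(x_obs)

        wmean = np.array([xf[self.win == y].mean() for y in range(Y)])
        centred = xf - wmean[self.win]
        _, amp0, phi0, _ = fit_sinusoid_ls(centred, self.t, self.period)
        s0 = np.sin(TWO_PI * self.t / self.period + phi0)
        beta0 = np.empty(Y)
        for y in range(Y):
            sel = self.win == y
            ss = s0[sel]
            beta0[y] = float(ss @ centred[sel] / max(ss @ ss, 1e-9))
        lo, hi = self.priors.amp_bounds
        beta0 = np.clip(beta0, lo + 0.05, hi - 0.05)
        resid = centred - beta0[self.win] * s0
        r = resid[:-1] @ resid[1:] / max(resid @ resid, 1e-12)
        rho0 = float(np.clip(r, -0.85, 0.85))
        iv0 = float(max(np.var(resid) * (1 - rho0**2), 1e-3))

        self.xc = np.broadcast_to(xf, (C, N)).copy()
        self.alpha = wmean + 0.3 * rng.standard_normal((C, Y))
        self.beta = np.clip(beta0 + 0.2 * rng.standard_normal((C, Y)), lo + 1e-3, hi - 1e-3)
        self.phi = (phi0 + 0.1 * rng.standard_normal(C)) % TWO_PI
        self.rho = np.clip(rho0 + 0.1 * rng.standard_normal(C), -0.9, 0.9)
        self.ivar = iv0 * np.exp(0.3 * rng.standard_normal(C))

    # ---------------------------------------------------------- helpers --

    def sin_t(self, phi=None) -> np.ndarray:
        if phi is None:
            if self._s_cache is None:
                self._s_cache = np.sin(
                    TWO_PI * self.t[None, :] / self.period + self.phi[:, None]
                )
            return self._s_cache
        return np.sin(TWO_PI * self.t[None, :] / self.period + phi[:, None])

    def mu(self, s=None) -> np.ndarray:
        s = self.sin_t() if s is None else s
        return self.alpha[:, self.win] + self.beta[:, self.win] * s

    def resid_quad(self, eps: np.ndarray):
        """Sufficient statistics of the AR(1) residual likelihood."""
        a = np.einsum("ij,ij->i", eps[:, 1:], eps[:, 1:])
        b = np.einsum("ij,ij->i", eps[:, 1:], eps[:, :-1])
        c = np.einsum("ij,ij->i", eps[:, :-1], eps[:, :-1])
        return a, b, c, eps[:, 0] ** 2

    def sum_sq(self, eps: np.ndarray, rho=None) -> np.ndarray:
        """(1-rho^2) eps_0^2 + sum (eps_i - rho eps_{i-1})^2 per chain."""
        rho = self.rho if rho is None else rho
        a, b, c, e0 = self.resid_quad(eps)
        return (1 - rho**2) * e0 + a - 2 * rho * b + rho**2 * c

    def loglik(self, eps=None) -> np.ndarray:
        """AR(1) log-likelihood of the residuals, per chain."""
        if eps is None:
            eps = self.xc - self.mu()
        return (
            0.5 * np.log(1 - self.rho**2)
            - 0.5 * self.N * np.log(self.ivar)
            - 0.5 * self.sum_sq(eps) / self.ivar
        )

    def _whiten(self, arr: np.ndarray) -> np.ndarray:
        """Innovation transform: row 0 scaled by sqrt(1-rho^2), rows i>=1
        mapped to arr_i - rho * arr_{i-1}."""
        out = np.empty_like(arr)
        out[:, 0] = np.sqrt(1 - self.rho**2) * arr[:, 0]
        out[:, 1:] = arr[:, 1:] - self.rho[:, None] * arr[:, :-1]
        return out

    def _window_suffstats(self, parity: int, c1, c2, d):
        """Per-window Gaussian sufficient statistics for one parity pass."""
        ys, offs, seg_sel = self._parity[parity]
        U1, U2, D = self._whiten(c1), self._whiten(c2), self._whiten(d)
        iv = self.ivar[:, None]
        res = []
        for prod in (U1 * U1, U1 * U2, U2 * U2, U1 * D, U2 * D):
            segs = np.add.reduceat(prod, offs, axis=1)[:, seg_sel]
            res.append(segs / iv)
        return ys, res  # A11, A12, A22, b1, b2  each (C, len(ys))

    # ---------------------------------------------------------- updates --

    def update_windows(self, rng, prior_mean_max=None, prior_mean_min=None,
                       var_max=None, var_min=None) -> None:
        """Sample window-level parameters, parity pass by parity pass.

        For ``amp_uniform`` the pair is (alpha_y, beta_y); for ``linked`` it
        is the extrema (x_max,y, x_min,y) with Gaussian prior means supplied
        per window (arrays (C, Y)) and variances per chain.
        """
        s = self.sin_t()
        for parity in (0, 1):
            m = (self.win % 2 == parity).astype(float)[None, :]
            contrib = (self.alpha[:, self.win] + self.beta[:, self.win] * s) * m
            d = self.xc - self.mu(s) + contrib
            if self.prior_kind == "amp_uniform":
                c1, c2 = m * np.ones_like(s), m * s
            else:
                c1, c2 = m * (1 + s) / 2.0, m * (1 - s) / 2.0
            ys, (A11, A12, A22, b1, b2) = self._window_suffstats(parity, c1, c2, d)

            if self.prior_kind == "amp_uniform":
                L11 = A11 + 1.0 / self.priors.mean_var
                L22 = A22
                alpha_y = self.alpha[:, ys]
                beta_y = self.beta[:, ys]
                mean_a = (b1 - A12 * beta_y) / L11
                alpha_y = mean_a + rng.standard_normal(mean_a.shape) / np.sqrt(L11)
                lo, hi = self.priors.amp_bounds
                mean_b = (b2 - A12 * alpha_y) / L22
                beta_y = truncnorm(rng, mean_b, 1.0 / np.sqrt(L22), lo, hi)
                self.alpha[:, ys] = alpha_y
                self.beta[:, ys] = beta_y
            else:
                pv_max = var_max[:, None]
                pv_min = var_min[:, None]
                L11 = A11 + 1.0 / pv_max
                L22 = A22 + 1.0 / pv_min
                e1 = b1 + prior_mean_max[:, ys] / pv_max
                e2 = b2 + prior_mean_min[:, ys] / pv_min
                det = L11 * L22 - A12**2
                m1 = (L22 * e1 - A12 * e2) / det
                m2 = (L11 * e2 - A12 * e1) / det
                # sample with precision Cholesky
                l11 = np.sqrt(L11)
                l21 = A12 / l11
                l22 = np.sqrt(L22 - l21**2)
                z1 = rng.standard_normal(m1.shape)
                z2 = rng.standard_normal(m1.shape)
                # solve L^T theta = z: theta2 = z2/l22, theta1 = (z1 - l21*theta2)/l11
                x2 = m2 + z2 / l22
                x1 = m1 + (z1 - l21 * (x2 - m2)) / l11
                self.alpha[:, ys] = (x1 + x2) / 2.0
                self.beta[:, ys] = (x1 - x2) / 2.0

    def update_phi(self, rng) -> None:
        eps = self.xc - self.mu()
        ll0 = -0.5 * self.sum_sq(eps) / self.ivar
        phi_new = (self.phi + self.sc_phi.scale * rng.standard_normal(self.C)) % TWO_PI
        s_new = self.sin_t(phi_new)
        eps_new = self.xc - self.mu(s_new)
        ll1 = -0.5 * self.sum_sq(eps_new) / self.ivar
        acc = np.log(rng.uniform(size=self.C)) < ll1 - ll0
        self.phi = np.where(acc, phi_new, self.phi)
        if acc.any():
            self._s_cache = np.where(acc[:, None], s_new, self.sin_t())
        self.sc_phi.record(acc)

    def update_rho(self, rng) -> None:
        quad = self.resid_quad(self.xc - self.mu())
        self.rho = metropolis_rho(rng, self.rho, quad, self.ivar, self.sc_rho)

    def update_ivar(self, rng) -> None:
        ssq = self.sum_sq(self.xc - self.mu())
        self.ivar = metropolis_var(
            rng, self.ivar, ssq, self.N, self.priors, self.sc_var
        )

    def update_missing(self, rng) -> None:
        if not (self.miss_idx[0].size or self.miss_idx[1].size):
            return
        mu = self.mu()
        for J in self.miss_idx:
            if not J.size:
                continue
            eps = self.xc - mu
            has_prev = (J > 0).astype(float)
            has_next = (J < self.N - 1).astype(float)
            prev = eps[:, np.maximum(J - 1, 0)]
            nxt = eps[:, np.minimum(J + 1, self.N - 1)]
            rho = self.rho[:, None]
            iv = self.ivar[:, None]
            prec = (has_prev + has_next * rho**2 + (1 - has_prev) * (1 - rho**2)) / iv
            lin = (has_prev * rho * prev + has_next * rho * nxt) / iv
            e = lin / prec + rng.standard_normal((self.C, J.size)) / np.sqrt(prec)
            self.xc[:, J] = mu[:, J] + e

    def update_all(self, rng) -> None:
        """One full Gibbs sweep for an ``amp_uniform`` series."""
        self.update_windows(rng)
        self.update_phi(rng)
        self.update_rho(rng)
        self.update_ivar(rng)
        self.update_missing(rng)

    def freeze_adaptation(self) -> None:
        for sc in (self.sc_phi, self.sc_rho, self.sc_var):
            sc.frozen = True


def rho_loglik(rho, quad, ivar):
    """AR(1) residual log-likelihood as a function of rho (stationary init)."""
    a, b, c, e0 = quad
    s = (1 - rho**2) * e0 + a - 2 * rho * b + rho**2 * c
    return 0.5 * np.log1p(-(rho**2)) - 0.5 * s / ivar


def metropolis_rho(rng, rho, quad, ivar, sc: AdaptiveScale):
    """Random-walk Metropolis step for the AR coefficient, Uniform(-1,1) prior."""
    C = rho.size
    prop = rho + sc.scale * rng.standard_normal(C)
    ok = np.abs(prop) < 1
    prop = np.where(ok, prop, rho)
    ll0 = rho_loglik(rho, quad, ivar)
    ll1 = np.where(ok, rho_loglik(prop, quad, ivar), -np.inf)
    acc = np.log(rng.uniform(size=C)) < ll1 - ll0
    sc.record(acc)
    return np.where(acc, prop, rho)


VAR_FLOOR = 1e-8  # numerical support floor; the Gamma(0.01, .) prior has an
# integrable spike at 0 that would otherwise underflow to exactly zero


def metropolis_var(rng, v, ssq, n, priors: PriorConfig, sc: AdaptiveScale):
    """Log-scale random-walk Metropolis step for an innovation/regression
    variance with the Gamma prior of the models."""
    C = v.size
    prop = v * np.exp(sc.scale * rng.standard_normal(C))
    ok = prop > VAR_FLOOR
    prop = np.where(ok, prop, v)

    def logpost(x):
        # -n/2 log x - ssq/2x + Gamma prior + log-scale Jacobian
        return -0.5 * n * np.log(x) - 0.5 * ssq / x + priors.var_logpdf(x) + np.log(x)

    acc = (np.log(rng.uniform(size=C)) < logpost(prop) - logpost(v)) & ok
    sc.record(acc)
    return np.where(acc, prop, v)


def sample_mvn_prec(rng, prec: np.ndarray, lin: np.ndarray) -> np.ndarray:
    """Draw from N(prec^{-1} lin, prec^{-1}) for stacked small systems.

    ``prec``: (C, k, k); ``lin``: (C, k).  Returns (C, k).
    """
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, lin[..., None])[..., 0]
    z = rng.standard_normal(lin.shape)
    # solve L^T x = z
    x = np.linalg.solve(np.swapaxes(L, -1, -2), z[..., None])[..., 0]
    return mean + x
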