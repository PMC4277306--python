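"""Parameter containers shared by the simulators and the Bayesian models.

The seasonal decomposition of a series X on the 5-day grid is

    X_{y,t} = alpha_y + beta_y * sin(2 pi t / 73 + phi) + eps_{y,t}

with a 6-month window mean ``alpha_y``, window amplitude ``beta_y``, a phase
``phi`` shared across windows, and AR(1) residuals
``eps_i = rho * eps_{i-1} + N(0, innov_var)``.  A window's sinusoid can
equivalently be described by its extrema ``x_max = alpha + beta`` and
``x_min = alpha - beta``; the water-temperature model links those extrema to
the extrema of air temperature and (log) discharge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import STEPS_PER_YEAR

TWO_PI = 2.0 * math.pi

def phase_for_peak(t_peak: float, period: float = STEPS_PER_YEAR) -> float:
    """Phase placing the sine maximum at step ``t_peak`` of ``period``."""
    return (math.pi / 2 - TWO_PI * t_peak / period) % TWO_PI


def balanced_phase(period: int = STEPS_PER_YEAR) -> float:
    """Phase with a mid-summer maximum at which both 6-month window means of
    the sine vanish exactly.

    The year splits 36/73 vs 37/73 (steps 1-36 and 37-73, scaled for other
    resolutions), so the balancing peak sits slightly before the window
    boundary; with this phase the window means of a sinusoidal series carry
    only the long-term signal, none of the seasonal cycle.
    """
    h = round(period * 36 / STEPS_PER_YEAR)
    g = np.exp(2j * math.pi * np.arange(1, h + 1) / period).sum()
    for phi in ((-np.angle(g)) % TWO_PI, (math.pi - np.angle(g)) % TWO_PI):
        t_peak = ((math.pi / 2 - phi) * period / TWO_PI) % period
        if 0.25 * period < t_peak < 0.75 * period:
            return float(phi)
    raise RuntimeError("no mid-year balancing phase found")  # pragma: no cover


#: default phase: sine maximum in mid-summer, placed so the two 6-month
#: window means contain no seasonal component
DEFAULT_PHASE = balanced_phase()


def extrema_from(alpha, beta):
    """(alpha, beta) -> (x_max, x_min) = (alpha + beta, alpha - beta)."""
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    if np.any(beta < 0):
        raise ValueError("amplitude beta must be non-negative")
    return alpha + beta, alpha - beta


def decomposition_from(x_max, x_min):
    """(x_max, x_min) -> (alpha, beta); inverse of :func:`extrema_from`."""
    x_max = np.asarray(x_max, float)
    x_min = np.asarray(x_min, float)
    if np.any(x_max < x_min):
        raise ValueError("x_max must be >= x_min")
    return (x_max + x_min) / 2.0, (x_max - x_min) / 2.0


@dataclass
class DecompositionParams:
    """Sinusoidal decomposition parameters of one series.

    ``alpha`` and ``beta`` hold one value per 6-month window; ``phi`` is the
    shared phase (radians); ``rho`` and ``innov_var`` describe the AR(1)
    residual process.
    """

    alpha: np.ndarray
    beta: np.ndarray
    phi: float
    rho: float
    innov_var: float

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, float))
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have equal length")
        if np.any(self.beta < 0):
            raise ValueError("beta must be non-negative")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not self.innov_var >= 0:
            raise ValueError("innov_var must be >= 0")

    @property
    def n_windows(self) -> int:
        return self.alpha.size

    @property
    def n_years(self) -> int:
        return self.alpha.size // 2

    def extrema(self):
        return extrema_from(self.alpha, self.beta)

    def mean_series(self) -> np.ndarray:
        """Noise-free series alpha_y + beta_y sin(2 pi t/73 + phi) on the grid."""
        from .grid import RegularSeries

        n = self.n_years * STEPS_PER_YEAR
        tmp = RegularSeries(1, np.zeros(n))
        w = tmp.window - 1
        s = np.sin(TWO_PI * tmp.t / STEPS_PER_YEAR + self.phi)
        return self.alpha[w] + self.beta[w] * s


@dataclass
class LinkageParams:
    """Window-level regressions linking WT extrema to AT / discharge extrema.

        WT_max,y = a0 + a_at * AT_max,y + a_q * Q_min,y + N(0, var_max)
        WT_min,y = b0 + b_at * AT_min,y + b_q * Q_max,y + N(0, var_min)

    Discharge enters on the log scale.  Setting ``a_q = b_q = 0`` (or fitting
    with ``q=None``) gives the reduced air-temperature-only variant.
    """

    a0: float
    a_at: float
    a_q: float
    b0: float
    b_at: float
    b_q: float
    var_max: float
    var_min: float

    def __post_init__(self) -> None:
        if self.var_max < 0 or self.var_min < 0:
            raise ValueError("residual variances must be >= 0")


@dataclass
class PriorConfig:
    """Weakly informative priors for both models.

    Means and regression coefficients get Normal(0, ``mean_var``); amplitudes
    Uniform over ``amp_bounds``; AR coefficients Uniform(-1, 1); variances
    Gamma with mean ``var_mean`` and coefficient of variation ``var_cv``
    (CV 10 = 1000%, i.e. shape 0.01, scale 100); phases Uniform[0, 2 pi).
    """

    mean_var: float = 1000.0
    amp_bounds: tuple = (0.0, 20.0)
    var_mean: float = 1.0
    var_cv: float = 10.0

    @property
    def var_shape(self) -> float:
        return 1.0 / self.var_cv**2

    @property
    def var_scale(self) -> float:
        return self.var_mean / self.var_shape

    def var_logpdf(self, v):
        """Log density of the Gamma prior on a variance (unnormalised)."""
        k, th = self.var_shape, self.var_scale
        v = np.asarray(v, float)
        return (k - 1.0) * np.log(v) - v / th


@dataclass
class MCMCProfile:
    """Run-length profile for the samplers."""

    n_chains: int = 3
    n_burn: int = 20000
    n_keep: int = 20000

    @classmethod
    def full(cls) -> "MCMCProfile":
        return cls(3, 20000, 20000)

    @classmethod
    def fast(cls) -> "MCMCProfile":
        return cls(3, 2000, 2000)
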