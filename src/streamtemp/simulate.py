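"""Synthetic-data generators.

Three generators are provided:

* :func:`simulate_sinusoid_ar1` — a single series with annual sinusoid,
  linear trend in the annual mean and AR(1) noise; with the default
  parameters a pair of such series (opposed trends) reproduces the
  illustrative air/water example in which short- and long-scale
  correlations have opposite signs.
* :func:`simulate_m1_generative` — the full hierarchical generative
  process (decomposition + extrema linkage) used for parameter-recovery
  and model-comparison studies.
* :func:`make_warming_scenario` — 50-year climate scenarios: linearly
  warming air temperature and a discharge series with constant seasonal
  shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ._mcmc import ar1_path, fit_sinusoid_ls
from .grid import STEPS_PER_YEAR, RegularSeries
from .params import (
    TWO_PI,
    DEFAULT_PHASE,
    DecompositionParams,
    LinkageParams,
    balanced_phase,
    decomposition_from,
    extrema_from,
    phase_for_peak,
)

DAYS_PER_YEAR = 365  # idealised year of the daily simulator (73 x 5)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SinusoidTrendSpec:
    """Sinusoid-plus-trend-plus-AR(1) series specification.

    ``trend_total`` is the signed change of the annual mean over the whole
    horizon; the annual mean steps linearly across years (piecewise constant
    within a year).  ``amplitude`` is the sine coefficient, i.e. half the
    seasonal peak-to-peak range.
    """

    base_mean: float = 12.0
    trend_total: float = 0.0
    amplitude: float = 13.0
    period_steps: int = STEPS_PER_YEAR
    phase: float | None = None
    ar_rho: float = 0.5
    ar_innov_var: float = 2.0
    years: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if not abs(self.ar_rho) < 1:
            raise ValueError("|ar_rho| must be < 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.years == 1 and self.trend_total != 0:
            raise ValueError("trend undefined for a single year")
        if self.phase is None:
            self.phase = balanced_phase(self.period_steps)

    def deterministic(self) -> np.ndarray:
        """Trend + sinusoid component on the full grid (no noise)."""
        P, J = self.period_steps, self.years
        t = np.tile(np.arange(1, P + 1), J)
        yr = np.repeat(np.arange(J), P)
        trend = 0.0 if J == 1 else self.trend_total * yr / (J - 1)
        return (
            self.base_mean
            + trend
            + self.amplitude * np.sin(TWO_PI * t / P + self.phase)
        )


def simulate_sinusoid_ar1(spec: SinusoidTrendSpec, seed=None):
    """Simulate one series from ``spec``.

    Returns a :class:`~streamtemp.grid.RegularSeries` when
    ``spec.period_steps == 73`` (the 5-day grid) and a bare array for other
    resolutions (e.g. 365 for an idealised daily grid).
    """
    rng = _as_rng(spec.seed if seed is None else seed)
    n = spec.period_steps * spec.years
    vals = spec.deterministic()
    if spec.ar_innov_var > 0:
        vals = vals + ar1_path(rng, spec.ar_rho, spec.ar_innov_var, n)
    if spec.period_steps == STEPS_PER_YEAR:
        return RegularSeries(1, vals)
    return vals


def daily_to_regular(daily_values: np.ndarray, start_year: int = 1) -> RegularSeries:
    """5-day block means of an idealised daily series (365 days/year)."""
    x = np.asarray(daily_values, float)
    if x.size % DAYS_PER_YEAR:
        raise ValueError("daily series must span whole 365-day years")
    return RegularSeries(start_year, x.reshape(-1, 5).mean(axis=1))


def illustrative_example(seed=0, years: int = 20, daily: bool = True):
    """Paired water/air temperature series with opposed long-term trends.

    Water: mean 12 °C, trend −0.5 °C over the horizon; air: trend +0.5 °C;
    both share an annual sinusoid of amplitude 13 °C plus independent AR(1)
    noise (rho 0.5, innovation variance 2).  With ``daily=True`` the series
    are simulated on an idealised 365-day grid and returned both daily and
    aggregated to the 5-day grid.

    Returns a dict with keys ``wt``/``at`` (RegularSeries) and, when daily,
    ``wt_daily``/``at_daily`` (arrays).
    """
    rng = _as_rng(seed)
    period = DAYS_PER_YEAR if daily else STEPS_PER_YEAR
    wt_spec = SinusoidTrendSpec(
        base_mean=12.0, trend_total=-0.5, amplitude=13.0,
        period_steps=period, years=years,
    )
    at_spec = replace(wt_spec, trend_total=+0.5)
    wt = simulate_sinusoid_ar1(wt_spec, rng)
    at = simulate_sinusoid_ar1(at_spec, rng)
    if daily:
        return {
            "wt_daily": wt,
            "at_daily": at,
            "wt": daily_to_regular(wt),
            "at": daily_to_regular(at),
        }
    return {"wt": wt, "at": at}


@dataclass
class M1Truth:
    """Generative output of the hierarchical model with its ground truth."""

    wt: RegularSeries
    at: RegularSeries
    q: Optional[RegularSeries]
    params_at: DecompositionParams
    params_q: Optional[DecompositionParams]
    params_wt: DecompositionParams  # realised WT decomposition (incl. linkage noise)
    linkage: LinkageParams
    wt_max: np.ndarray
    wt_min: np.ndarray


def simulate_m1_generative(
    params_at: DecompositionParams,
    params_q: Optional[DecompositionParams],
    linkage: LinkageParams,
    wt_noise=(0.5, 0.8),
    phi_wt: float = DEFAULT_PHASE,
    seed=None,
) -> M1Truth:
    """Forward-simulate (AT, Q, WT) from the hierarchical model.

    AT and log-Q follow their decompositions; the WT window extrema are
    linear functions of the AT extrema and (log) discharge extrema plus
    Gaussian regression noise, and WT follows its own sinusoid with AR(1)
    residuals.  Q is returned on the natural scale.
    """
    rng = _as_rng(seed)
    wt_rho, wt_ivar = wt_noise
    n = params_at.n_years * STEPS_PER_YEAR

    at_vals = params_at.mean_series() + ar1_path(
        rng, params_at.rho, params_at.innov_var, n
    )
    at = RegularSeries(1, at_vals, "at")
    at_max, at_min = params_at.extrema()

    if params_q is not None:
        if params_q.n_windows != params_at.n_windows:
            raise ValueError("AT and Q must cover the same windows")
        logq = params_q.mean_series() + ar1_path(
            rng, params_q.rho, params_q.innov_var, n
        )
        q = RegularSeries(1, np.exp(logq), "q")
        q_max, q_min = params_q.extrema()
    else:
        q = None
        q_max = q_min = np.zeros_like(at_max)

    wt_max = (
        linkage.a0
        + linkage.a_at * at_max
        + linkage.a_q * q_min
        + math.sqrt(linkage.var_max) * rng.standard_normal(at_max.size)
    )
    wt_min = (
        linkage.b0
        + linkage.b_at * at_min
        + linkage.b_q * q_max
        + math.sqrt(linkage.var_min) * rng.standard_normal(at_min.size)
    )
    if np.any(wt_max < wt_min):
        raise ValueError(
            "linkage produced WT_max < WT_min (negative amplitude); "
            "increase the separation of the linkage intercepts/slopes or "
            "reduce var_max/var_min"
        )
    alpha_wt, beta_wt = decomposition_from(wt_max, wt_min)
    params_wt = DecompositionParams(alpha_wt, beta_wt, phi_wt, wt_rho, wt_ivar)
    wt_vals = params_wt.mean_series() + ar1_path(rng, wt_rho, wt_ivar, n)
    wt = RegularSeries(1, wt_vals, "wt")
    return M1Truth(wt, at, q, params_at, params_q, params_wt, linkage, wt_max, wt_min)


def default_recovery_setup(years: int = 20, seed: int = 12345):
    """Generating parameters for recovery studies: a temperate-stream-like
    configuration with the sign structure expected of the linkage
    (a_at > 0, a_q < 0, b_at > 0, b_q > 0).

    Window-to-window variation of the predictor means/amplitudes is drawn
    once from the given ``seed`` so the "truth" is reproducible.
    """
    rng = np.random.default_rng(seed)
    Y = 2 * years
    yr = np.repeat(np.arange(years), 2)
    at_alpha = 11.0 + 1.0 * yr / max(years - 1, 1) + 0.7 * rng.standard_normal(Y)
    at_beta = np.clip(6.0 + 0.6 * rng.standard_normal(Y), 0.5, 19.5)
    params_at = DecompositionParams(at_alpha, at_beta, DEFAULT_PHASE, 0.5, 2.0)

    q_alpha = 0.2 + 0.5 * rng.standard_normal(Y)
    q_beta = np.clip(0.6 + 0.2 * rng.standard_normal(Y), 0.05, 3.0)
    params_q = DecompositionParams(
        q_alpha, q_beta, phase_for_peak(0.0), 0.6, 0.15
    )

    linkage = LinkageParams(
        a0=3.0, a_at=0.8, a_q=-0.8, b0=1.0, b_at=0.6, b_q=0.8,
        var_max=0.25, var_min=0.25,
    )
    return params_at, params_q, linkage


@dataclass
class ScenarioSpec:
    """Climate-scenario specification for the forecasting module."""

    warming_total: float = 3.2
    years: int = 50
    discharge_mean: float | None = None  # log-scale window mean
    discharge_amplitude: float | None = None
    discharge_phase: float | None = None
    noise: bool = True

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")


def make_warming_scenario(
    base_at: RegularSeries,
    spec: ScenarioSpec,
    seed=None,
    base_q: Optional[RegularSeries] = None,
):
    """Build (AT', Q') scenario series from a historical baseline.

    AT' keeps the seasonal shape (mean, amplitude, phase) and residual AR(1)
    character estimated from ``base_at`` by least squares, with the annual
    mean increasing linearly by ``warming_total`` over the horizon.  Q' is a
    noise-free log-discharge sinusoid with constant window mean and
    amplitude; when ``base_q`` is given and the spec leaves them unset, they
    are the averages over the last 10 years of the baseline.

    Returns ``(at_prime, q_prime)`` with ``q_prime=None`` when no discharge
    information is available.
    """
    rng = _as_rng(seed)
    obs = ~base_at.missing_mask
    m, amp, phi, _ = fit_sinusoid_ls(
        base_at.values[obs], base_at.t[obs], STEPS_PER_YEAR
    )
    resid = np.full(len(base_at), np.nan)
    resid[obs] = base_at.values[obs] - (
        m + amp * np.sin(TWO_PI * base_at.t[obs] / STEPS_PER_YEAR + phi)
    )
    rr = resid[:-1] * resid[1:]
    ok = np.isfinite(rr)
    rho = float(np.clip(np.nansum(rr[ok]) / max(np.nansum(resid[np.isfinite(resid)] ** 2), 1e-12), -0.95, 0.95))
    ivar = float(np.nanvar(resid) * (1 - rho**2))

    at_spec = SinusoidTrendSpec(
        base_mean=m,
        trend_total=spec.warming_total,
        amplitude=amp,
        phase=phi,
        ar_rho=rho,
        ar_innov_var=ivar if spec.noise else 0.0,
        years=spec.years,
    )
    at_prime = simulate_sinusoid_ar1(at_spec, rng)
    at_prime.start_year = base_at.start_year + base_at.n_years
    at_prime.name = "at"

    qm, qa, qphi = spec.discharge_mean, spec.discharge_amplitude, spec.discharge_phase
    if base_q is not None and (qm is None or qa is None):
        last = base_q.slice_years(max(base_q.n_years - 10, 0), min(10, base_q.n_years))
        qobs = (~last.missing_mask) & (last.values > 0)
        if not qobs.any():
            raise ValueError("baseline discharge has no positive observations")
        qm_fit, qa_fit, qphi_fit, _ = fit_sinusoid_ls(
            np.log(last.values[qobs]), last.t[qobs], STEPS_PER_YEAR
        )
        qm = qm_fit if qm is None else qm
        qa = qa_fit if qa is None else qa
        qphi = qphi_fit if qphi is None else qphi
    if qm is None or qa is None:
        return at_prime, None
    if qphi is None:
        qphi = phase_for_peak(0.0)
    t = at_prime.t
    logq = qm + abs(qa) * np.sin(TWO_PI * t / STEPS_PER_YEAR + qphi)
    q_prime = RegularSeries(at_prime.start_year, np.exp(logq), "q")
    return at_prime, q_prime
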