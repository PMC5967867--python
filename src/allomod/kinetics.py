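"""Relaxation-kinetics analysis: exponential onset/offset fits, pseudo-
first-order rate regression for k_ON / k_OFF / K_d, and first-order
racemization half-lives.

The modulation onset after a concentration jump is treated as a single
exponential, ``dI(t) = A * (1 - exp(-t/tau)) + c``, optionally summed with a
linear drift ``m*t`` for traces showing a slow second phase.  Observed onset
rates obey the pseudo-first-order law ``1/tau = k_ON*[M] + k_OFF``; ordinary
least squares of rate on concentration yields the association rate (slope)
and dissociation rate (intercept), cross-checked against washout time
constants when supplied, and the kinetically determined affinity
``K_d = k_OFF / k_ON``.

Enantiomer racemization in aqueous solution is first order: functional
activity relaxes exponentially toward the racemic level, and the half-life
is ``ln 2 / rate`` (reported in minutes, the conventional unit for
bench-timescale solution chemistry; receptor kinetics use seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import NoAssociationError, ValidationError
from .receptor import RelaxationTrace


@dataclass(frozen=True)
class KineticFit:
    """Exponential (± linear) relaxation fit.

    ``A`` is the exponential amplitude in response units, ``tau`` the time
    constant in seconds, ``c`` the offset, ``m`` the linear slope (only for
    the exp_linear form).  ``converged`` is honest: degenerate traces with no
    resolvable exponential are flagged and their parameters should not be
    interpreted.
    """

    A: float
    tau: float | None
    c: float
    m: float | None
    residual_norm: float
    converged: bool
    form: str
    message: str = ""

    @property
    def rate(self) -> float:
        """Observed relaxation rate 1/tau (1/s)."""
        return 1.0 / self.tau


@dataclass(frozen=True)
class RateRegression:
    k_on: float        # 1/(µM*s)
    k_off: float       # 1/s, regression intercept
    kd: float          # µM, k_off / k_on
    r_squared: float
    concentrations: tuple
    rates: tuple
    washout_k_off: float | None = None
    washout_discrepancy: bool = False


@dataclass(frozen=True)
class RacemizationFit:
    rate_per_min: float | None
    half_life_min: float | None
    asymptote: float
    amplitude: float
    residual_norm: float
    determined: bool
    message: str = ""


def _as_arrays(trace):
    if isinstance(trace, RelaxationTrace):
        return trace.time, trace.response
    if isinstance(trace, pd.DataFrame):
        return (trace["time"].to_numpy(dtype=float),
                trace["response"].to_numpy(dtype=float))
    t, y = trace
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def _profile_exponential(t, y, extra_linear):
    """Least squares with the time constant profiled out.

    For fixed tau the model is linear in (A, c[, m]); a decade grid over the
    trace duration followed by a bounded scalar refinement locates the best
    tau robustly without nonlinear multi-start failures.
    """
    span = t[-1] - t[0]
    dt = np.diff(t).min()

    def sse_for(log_tau):
        tau = math.exp(log_tau)
        cols = [1.0 - np.exp(-t / tau), np.ones_like(t)]
        if extra_linear:
            cols.append(t)
        X = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = X @ coef - y
        return float(r @ r), coef

    grid = np.log(np.geomspace(max(dt / 10, 1e-12), 10 * span, 40))
    sses = [sse_for(g)[0] for g in grid]
    k = int(np.argmin(sses))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda g: sse_for(g)[0], bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    log_tau = float(res.x)
    sse, coef = sse_for(log_tau)
    return math.exp(log_tau), coef, sse


def fit_relaxation(trace, form: str = "exp") -> KineticFit:
    """Fit a relaxation trace with ``A*(1 - exp(-t/tau)) + c`` (+ ``m*t``).

    ``trace`` may be a :class:`RelaxationTrace`, a DataFrame with ``time`` /
    ``response`` columns, or a ``(time, response)`` pair.  Time is taken
    relative to the first sample.  Traces with no resolvable exponential
    component (constant, or amplitude indistinguishable from the residual
    noise) are returned with ``converged=False``.
    """
    if form not in ("exp", "exp_linear"):
        raise ValidationError("form", f"unknown form {form!r}")
    t, y = _as_arrays(trace)
    if t.size < 8:
        raise ValidationError("trace", f"need >=8 samples, got {t.size}")
    if (np.diff(t) <= 0).any():
        raise ValidationError("trace", "time must be strictly increasing")
    t = t - t[0]

    tau, coef, sse = _profile_exponential(t, y, form == "exp_linear")
    A = float(coef[0])
    c = float(coef[1])
    m = float(coef[2]) if form == "exp_linear" else None
    n_par = 3 + (1 if form == "exp_linear" else 0)
    dof = max(t.size - n_par, 1)
    sigma = math.sqrt(sse / dof)
    # amplitude must beat both the residual noise and a machine-level floor
    # relative to the trace scale (a constant trace has A ~ 0, sigma ~ 0)
    floor = 1e-9 * max(float(np.abs(y).max()), 1e-30)
    resolvable = (abs(A) > max(3 * sigma, floor)
                  and np.diff(t).min() / 10 < tau < 10 * t[-1])
    msg = "" if resolvable else "no resolvable exponential component"
    return KineticFit(A=A, tau=float(tau) if resolvable else None, c=c, m=m,
                      residual_norm=math.sqrt(sse), converged=resolvable,
                      form=form, message=msg)


def rate_regression(onset_fits, washout_fits=None) -> RateRegression:
    """Pseudo-first-order regression of observed onset rates on concentration.

    ``onset_fits`` is an iterable of ``(concentration_um, fit)`` pairs where
    ``fit`` is a converged :class:`KineticFit` (or a bare time constant in
    seconds).  The slope is k_ON, the intercept k_OFF; a washout estimate of
    k_OFF (mean of 1/tau over ``washout_fits``) is cross-checked and a
    greater-than-2-fold disagreement flagged.  A non-positive slope raises
    :class:`NoAssociationError` (K_d undefined without association).
    """
    concs, rates = [], []
    for conc, fit in onset_fits:
        tau = fit.tau if isinstance(fit, KineticFit) else float(fit)
        if isinstance(fit, KineticFit) and not fit.converged:
            continue
        concs.append(float(conc))
        rates.append(1.0 / tau)
    if len(set(concs)) < 3:
        raise ValidationError("onset_fits",
                              "need >=3 distinct onset concentrations")
    concs = np.array(concs)
    rates = np.array(rates)
    reg = stats.linregress(concs, rates)
    if reg.slope <= 0:
        raise NoAssociationError(
            f"observed rates do not increase with concentration "
            f"(slope {reg.slope:.3g} 1/(µM*s)); K_d undefined")
    k_on = float(reg.slope)
    k_off = float(reg.intercept)

    washout_k_off = None
    discrepancy = False
    if washout_fits is not None:
        taus = [f.tau if isinstance(f, KineticFit) else float(f)
                for f in washout_fits]
        taus = [t for t in taus if t is not None]
        if taus:
            washout_k_off = float(np.mean([1.0 / t for t in taus]))
            if k_off > 0:
                ratio = max(k_off, washout_k_off) / min(k_off, washout_k_off)
                discrepancy = ratio > 2.0
            else:
                discrepancy = True
    return RateRegression(
        k_on=k_on, k_off=k_off, kd=k_off / k_on,
        r_squared=float(reg.rvalue ** 2),
        concentrations=tuple(concs.tolist()), rates=tuple(rates.tolist()),
        washout_k_off=washout_k_off, washout_discrepancy=discrepancy,
    )


def fit_racemization(time_min, activity) -> RacemizationFit:
    """Fit a first-order approach to the racemic asymptote.

    Model: ``y(t) = asymptote + amplitude * exp(-k*t)`` with t in minutes.
    Returns the rate, the half-life ``ln 2 / k`` and the asymptote; series
    with no resolvable decay are flagged ``determined=False`` with the
    half-life withheld.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(activity, dtype=float)
    if t.size < 5:
        raise ValidationError("series", f"need >=5 time points, got {t.size}")
    if (np.diff(t) <= 0).any():
        raise ValidationError("series", "times must be strictly increasing")
    t0 = t - t[0]

    span = t0[-1] if t0[-1] > 0 else 1.0

    def sse_for(log_k):
        k = math.exp(log_k)
        X = np.column_stack([np.exp(-k * t0), np.ones_like(t0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = X @ coef - y
        return float(r @ r), coef

    grid = np.log(np.geomspace(1e-2 / span, 1e3 / span, 40))
    sses = [sse_for(g)[0] for g in grid]
    k = int(np.argmin(sses))
    res = optimize.minimize_scalar(
        lambda g: sse_for(g)[0],
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
        method="bounded", options={"xatol": 1e-12})
    rate = math.exp(float(res.x))
    sse, coef = sse_for(float(res.x))
    amp, asym = float(coef[0]), float(coef[1])
    sigma = math.sqrt(sse / max(t.size - 3, 1))
    floor = 1e-9 * max(float(np.abs(y).max()), 1e-30)
    determined = abs(amp) > max(3 * sigma, floor) \
        and 1e-6 / span < rate < 1e4 / span and rate * t0[-1] > 0.05
    if not determined:
        return RacemizationFit(None, None, asym, amp, math.sqrt(sse), False,
                               "no resolvable first-order decay; half-life "
                               "not determined")
    return RacemizationFit(rate, math.log(2) / rate, asym, amp,
                           math.sqrt(sse), True)


def half_life_from_rate(rate_per_min: float) -> float:
    """Half-life (min) of a first-order process with the given rate (1/min)."""
    if rate_per_min <= 0:
        raise ValidationError("rate", "must be > 0")
    return math.log(2) / rate_per_min
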