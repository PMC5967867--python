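"""Hill-equation concentration-response analysis.

Two fixed functional forms are supported:

* modulator form — response as a ratio to the unmodulated control,
  ``I/I0 = 1 + Extent * [M]^h / ([M]^h + EC50^h)``, which starts at 1 and
  plateaus at ``1 + Extent`` (Extent < 0 for an inhibitor, with the plateau
  giving the residual response at saturation);
* agonist form — response as a fraction of the maximal response,
  ``I/Imax = [A]^h / ([A]^h + EC50^h)``.

Fitting is per replicate by nonlinear least squares, parameterised internally
in log10(EC50) with multi-start initialisation (EC50 seeded at the geometric
mean of the tested concentrations and at each tested concentration, Hill
slope at 0.8 / 1 / 1.5 when free).  Replicate-level EC50s are summarised as
the geometric mean with a t-based confidence interval computed on
log10(EC50) and back-transformed; the maximal-modulation Extent is
summarised as arithmetic mean ± SEM.

A screening rule familiar from oocyte panels is enforced before fitting a
modulator curve: if the response recorded at 30 µM of the compound differs
from control by less than 15%, the replicate is flagged "not fit" rather
than fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    AggregationError,
    FitRefusedError,
    PairingError,
    ValidationError,
)

#: canonical tidy CRC column names
CRC_COLUMNS = ("replicate_id", "condition", "concentration_um", "response")

#: concentration (µM) at which the "not fit" screening rule is evaluated
REFUSAL_CONCENTRATION_UM = 30.0
#: minimum fractional deviation from control required at that concentration
REFUSAL_MIN_CHANGE = 0.15

_LOG_EC50_BOUNDS = (-6.0, 6.0)
_H_BOUNDS = (0.2, 8.0)
_EXTENT_BOUNDS = (-1.0, 50.0)


def hill_modulator(m, ec50: float, h: float, extent: float):
    """Response ratio I/I0 of the modulator-form Hill equation."""
    _check_params(ec50, h)
    if 1.0 + extent < 0:
        raise ValidationError("extent", f"1 + Extent must be >= 0, got {extent!r}")
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValidationError("M", "concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        frac = np.where(m > 0, m ** h / (m ** h + ec50 ** h), 0.0)
    out = 1.0 + extent * frac
    return float(out) if out.ndim == 0 else out


def hill_agonist(a, ec50: float, h: float):
    """Response fraction I/Imax of the agonist-form Hill equation."""
    _check_params(ec50, h)
    a = np.asarray(a, dtype=float)
    if (a < 0).any():
        raise ValidationError("A", "concentrations must be >= 0")
    out = np.where(a > 0, a ** h / (a ** h + ec50 ** h), 0.0)
    return float(out) if out.ndim == 0 else out


def _check_params(ec50, h):
    if not (np.isfinite(ec50) and ec50 > 0):
        raise ValidationError("EC50", f"must be > 0, got {ec50!r}")
    if not (np.isfinite(h) and h > 0):
        raise ValidationError("h", f"must be > 0, got {h!r}")


@dataclass(frozen=True)
class HillFit:
    """Per-replicate fit result (modulator or agonist form)."""

    replicate_id: object
    form: str
    ec50: float | None
    h: float | None
    extent: float | None
    residual_norm: float | None
    converged: bool
    message: str = ""

    @property
    def log10_ec50(self) -> float:
        return math.log10(self.ec50)


@dataclass(frozen=True)
class HillSummary:
    """Log-space aggregate of replicate EC50s."""

    ec50: float
    ci_low: float
    ci_high: float
    extent_mean: float | None
    extent_sem: float | None
    n: int
    ci_level: float = 0.95


@dataclass(frozen=True)
class FoldShift:
    """Paired agonist-potency shift between control and treated fits."""

    fold: float
    per_pair: tuple
    non_overlapping: bool
    control: HillSummary
    treated: HillSummary


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _hill_model(form, conc, log_ec50, h, extent):
    ec50 = 10.0 ** log_ec50
    frac = np.where(conc > 0, conc ** h / (conc ** h + ec50 ** h), 0.0)
    if form == "modulator":
        return 1.0 + extent * frac
    return frac


def _fit_single(conc, resp, form, fix_hill):
    """Multi-start bounded least squares on one replicate; returns best params."""
    nz = conc[conc > 0]
    geo = float(np.exp(np.log(nz).mean()))
    ec50_starts = [geo] + sorted(set(nz.tolist()))
    h_starts = [fix_hill] if fix_hill is not None else [0.8, 1.0, 1.5]

    if form == "modulator":
        e0 = float(resp[np.argmax(conc)] - 1.0)
        e0 = float(np.clip(e0 if abs(e0) > 1e-3 else 0.5, *_EXTENT_BOUNDS))

    def residuals(p):
        if form == "modulator":
            if fix_hill is None:
                le, h, e = p
            else:
                le, e = p
                h = fix_hill
            return _hill_model(form, conc, le, h, e) - resp
        if fix_hill is None:
            le, h = p
        else:
            (le,) = p
            h = fix_hill
        return _hill_model(form, conc, le, h, 0.0) - resp

    lo, hi = [], []
    if form == "modulator":
        if fix_hill is None:
            lo = [_LOG_EC50_BOUNDS[0], _H_BOUNDS[0], _EXTENT_BOUNDS[0]]
            hi = [_LOG_EC50_BOUNDS[1], _H_BOUNDS[1], _EXTENT_BOUNDS[1]]
        else:
            lo = [_LOG_EC50_BOUNDS[0], _EXTENT_BOUNDS[0]]
            hi = [_LOG_EC50_BOUNDS[1], _EXTENT_BOUNDS[1]]
    else:
        if fix_hill is None:
            lo = [_LOG_EC50_BOUNDS[0], _H_BOUNDS[0]]
            hi = [_LOG_EC50_BOUNDS[1], _H_BOUNDS[1]]
        else:
            lo = [_LOG_EC50_BOUNDS[0]]
            hi = [_LOG_EC50_BOUNDS[1]]

    log_med = math.log10(float(np.median(nz)))
    candidates = []
    for ec0 in ec50_starts:
        for h0 in h_starts:
            p0 = [math.log10(ec0)]
            if fix_hill is None:
                p0.append(float(np.clip(h0, *_H_BOUNDS)))
            if form == "modulator":
                p0.append(e0)
            try:
                sol = optimize.least_squares(residuals, p0, bounds=(lo, hi),
                                             method="trf", xtol=1e-14,
                                             ftol=1e-14, gtol=1e-14)
            except Exception:  # numerical failure on this start only
                continue
            cost = float(np.linalg.norm(sol.fun))
            candidates.append((cost, abs(sol.x[0] - log_med), sol))
    if not candidates:
        return None
    # best residual wins; near-ties broken by EC50 closest to the tested range
    best_cost = min(c[0] for c in candidates)
    tol = 1e-9 * max(best_cost, 1e-12)
    cost, tie, sol = min((c for c in candidates if c[0] <= best_cost + tol),
                         key=lambda c: c[1])
    return cost, tie, sol


def fit_hill(crc: pd.DataFrame, form: str = "modulator",
             fix_hill: float | None = None,
             apply_refusal: bool | None = None,
             refusal_concentration_um: float = REFUSAL_CONCENTRATION_UM) -> list:
    """Fit the Hill equation to every replicate of a tidy CRC table.

    Parameters
    ----------
    crc:
        Tidy table with columns ``replicate_id, condition, concentration_um,
        response`` (``condition`` optional).
    form:
        ``"modulator"`` (ratio-to-control form with an Extent parameter) or
        ``"agonist"`` (fraction-of-max form).
    fix_hill:
        Fix the Hill slope at this value instead of fitting it.
    apply_refusal:
        Enforce the "<15% change at 30 µM means not fit" screening rule
        (defaults to True for the modulator form only).

    Returns one :class:`HillFit` per replicate; refused or unconverged
    replicates are flagged, never silently dropped.  Replicates with fewer
    than three distinct non-zero concentrations raise
    :class:`FitRefusedError`.
    """
    if form not in ("modulator", "agonist"):
        raise ValidationError("form", f"unknown form {form!r}")
    if apply_refusal is None:
        apply_refusal = form == "modulator"
    missing = {"replicate_id", "concentration_um", "response"} - set(crc.columns)
    if missing:
        raise ValidationError("crc", f"missing columns {sorted(missing)}")

    fits = []
    for rid, grp in crc.groupby("replicate_id", sort=False):
        conc = grp["concentration_um"].to_numpy(dtype=float)
        resp = grp["response"].to_numpy(dtype=float)
        if (conc < 0).any() or not np.isfinite(resp).all():
            raise ValidationError("crc", f"replicate {rid!r}: negative concentration "
                                  "or non-finite response")
        if len(np.unique(conc[conc > 0])) < 3:
            raise FitRefusedError(
                f"replicate {rid!r}: need >=3 distinct non-zero concentrations")

        if apply_refusal and form == "modulator":
            at30 = np.isclose(conc, refusal_concentration_um, rtol=1e-6)
            if at30.any():
                change = np.abs(resp[at30] - 1.0).max()
                if change <= REFUSAL_MIN_CHANGE:
                    fits.append(HillFit(rid, form, None, None, None, None, False,
                                        message=f"not fit: response at "
                                        f"{refusal_concentration_um:g} µM within "
                                        f"{REFUSAL_MIN_CHANGE:.0%} of control"))
                    continue

        best = _fit_single(conc, resp, form, fix_hill)
        if best is None:
            fits.append(HillFit(rid, form, None, None, None, None, False,
                                message="optimizer failed on all starts"))
            continue
        cost, _, sol = best
        x = list(sol.x)
        log_ec50 = x.pop(0)
        h = fix_hill if fix_hill is not None else x.pop(0)
        extent = x.pop(0) if form == "modulator" else None
        fits.append(HillFit(rid, form, 10.0 ** log_ec50, float(h),
                            None if extent is None else float(extent),
                            cost, bool(sol.success)))
    return fits


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_log_ec50(fits: list, ci_level: float = 0.95) -> HillSummary:
    """Geometric-mean EC50 with a t-based CI on log10(EC50).

    Requires at least two converged fits; Extent is summarised as arithmetic
    mean ± SEM when present.
    """
    good = [f for f in fits if f.converged and f.ec50 is not None]
    if len(good) < 2:
        raise AggregationError(
            f"need >=2 converged fits to aggregate, got {len(good)}")
    logs = np.array([f.log10_ec50 for f in good])
    n = len(logs)
    mean = logs.mean()
    sem = logs.std(ddof=1) / math.sqrt(n)
    half = stats.t.ppf(0.5 + ci_level / 2, df=n - 1) * sem
    extents = [f.extent for f in good if f.extent is not None]
    if extents:
        e = np.array(extents)
        e_mean = float(e.mean())
        e_sem = float(e.std(ddof=1) / math.sqrt(len(e))) if len(e) > 1 else 0.0
    else:
        e_mean = e_sem = None
    return HillSummary(
        ec50=10.0 ** mean, ci_low=10.0 ** (mean - half),
        ci_high=10.0 ** (mean + half),
        extent_mean=e_mean, extent_sem=e_sem, n=n, ci_level=ci_level,
    )


def fold_shift(control_fits: list, treated_fits: list,
               ci_level: float = 0.95) -> FoldShift:
    """Paired potency shift: geometric mean of per-replicate EC50 ratios.

    Fits are paired by ``replicate_id`` (an unpaired replicate raises
    :class:`PairingError`); the non-overlap flag compares the two groups'
    log-EC50 confidence intervals.
    """
    c = {f.replicate_id: f for f in control_fits if f.converged}
    t = {f.replicate_id: f for f in treated_fits if f.converged}
    if set(c) != set(t):
        odd = sorted(set(c) ^ set(t), key=repr)
        raise PairingError(f"unpaired replicates: {odd}")
    if len(c) < 2:
        raise PairingError(f"need >=2 pairs, got {len(c)}")
    ratios = tuple(c[k].ec50 / t[k].ec50 for k in sorted(c, key=repr))
    fold = float(np.exp(np.mean(np.log(ratios))))
    cs = aggregate_log_ec50(list(c.values()), ci_level)
    ts = aggregate_log_ec50(list(t.values()), ci_level)
    non_overlap = cs.ci_low > ts.ci_high or ts.ci_low > cs.ci_high
    return FoldShift(fold=fold, per_pair=ratios, non_overlapping=bool(non_overlap),
                     control=cs, treated=ts)
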