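"""Modulator-competition analysis: dose-ratio (Schild-type) diagnostics and
independent-action combination nulls.

The central question is whether a positive and a negative allosteric
modulator occupy one mutually exclusive site or two independent sites.  The
diagnostic mirrors classical competitive-antagonism analysis: inhibitor
concentration-response curves are simulated (or measured) in fixed
backgrounds of the potentiator, each normalised to its own zero-inhibitor
response, and the fold-shift of the inhibitor midpoint IC50' is regressed
against potentiator concentration.  Mutually exclusive binding produces
IC50' = IC50 * (1 + [P]/K_P) (the Gaddum relation), i.e. a straight line of
slope 1/K_P through dose ratio 1 at [P] = 0; independent sites leave the
normalised inhibitor curve essentially unshifted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import aggregate_log_ec50, fit_hill
from .exceptions import AnalysisError, ValidationError
from .receptor import ReceptorScheme, build_q_matrix, response_readout, \
    solve_equilibrium_nullspace

SHARED_SITE = "SHARED_SITE"
INDEPENDENT_SITES = "INDEPENDENT_SITES"
INDETERMINATE = "INDETERMINATE"

#: verdict thresholds (far from the boundary of the two phenotypes)
R2_THRESHOLD = 0.98
FLATNESS_THRESHOLD = 0.10


@dataclass(frozen=True)
class DoseRatioResult:
    pam_concentrations: tuple
    baseline_ic50: float
    ic50_prime: tuple
    dose_ratios: tuple
    slope: float           # 1/µM
    slope_ci: tuple        # 95% CI on the slope
    intercept: float
    r_squared: float
    verdict: str
    hill_slopes: tuple     # per-level fitted Hill slopes (parallelism diagnostic)
    thresholds: dict


@dataclass(frozen=True)
class CombinationComparison:
    mean_difference: float
    statistic: float | None
    p_value: float | None
    n: int
    note: str = ""


def simulate_crc_grid(scheme: ReceptorScheme, nam_concs, pam_concs,
                      agonist_um: float) -> pd.DataFrame:
    """Equilibrium NAM concentration-response curves across fixed PAM levels.

    For every (PAM, NAM) pair the stationary response is computed and
    normalised to the response at the same PAM level with NAM = 0, so each
    condition reads as a fraction of its own zero-inhibitor control.  Output
    is a tidy CRC table with one replicate per PAM level (deterministic).
    """
    nam_concs = np.asarray(list(nam_concs), dtype=float)
    pam_concs = np.asarray(list(pam_concs), dtype=float)
    if nam_concs.size == 0 or pam_concs.size == 0:
        raise ValidationError("concentrations", "concentration lists must be non-empty")
    records = []
    for pam in pam_concs:
        try:
            qm0 = build_q_matrix(scheme, agonist_um, pam_um=pam, nam_um=0.0)
            base = response_readout(solve_equilibrium_nullspace(qm0), scheme)
            grid = nam_concs if 0.0 in nam_concs else np.concatenate([[0.0], nam_concs])
            for nam in grid:
                qm = build_q_matrix(scheme, agonist_um, pam_um=pam, nam_um=nam)
                resp = response_readout(solve_equilibrium_nullspace(qm), scheme)
                records.append({
                    "replicate_id": f"pam={pam:g}",
                    "condition": f"pam={pam:g}",
                    "pam_um": pam,
                    "concentration_um": nam,
                    "response": resp / base,
                })
        except Exception as exc:
            raise AnalysisError(
                f"equilibrium solve failed at PAM={pam:g} µM: {exc}") from exc
    return pd.DataFrame.from_records(records)


def dose_ratio_analysis(crc: pd.DataFrame,
                        r2_threshold: float = R2_THRESHOLD,
                        flatness_threshold: float = FLATNESS_THRESHOLD,
                        fix_hill: float | None = None) -> DoseRatioResult:
    """Fit IC50' per PAM level and regress (dose ratio - 1) on [PAM].

    Requires a ``pam_um`` column with at least three levels including 0.
    The verdict is ``INDEPENDENT_SITES`` when the largest |ratio - 1| stays
    within the flatness threshold, ``SHARED_SITE`` when the regression is
    linear (R^2 above threshold) with a positive slope whose 95% CI excludes
    zero, and ``INDETERMINATE`` otherwise.  Hill slopes per level are
    reported as a parallel-shift diagnostic but do not gate the verdict.
    """
    if "pam_um" not in crc.columns:
        raise ValidationError("crc", "missing 'pam_um' column")
    levels = sorted(crc["pam_um"].unique())
    if len(levels) < 3 or 0.0 not in levels:
        raise AnalysisError("need >=3 PAM levels including 0")

    ic50, hills = {}, {}
    for pam in levels:
        sub = crc[crc["pam_um"] == pam].copy()
        # normalise the level to its own zero-inhibitor response, so dose
        # ratios are invariant to uniform rescaling of the response axis
        zero = sub["concentration_um"] == 0.0
        if zero.any():
            sub["response"] = sub["response"] / sub.loc[zero, "response"].mean()
        fits = [f for f in fit_hill(sub, form="modulator", fix_hill=fix_hill,
                                    apply_refusal=False) if f.converged]
        if not fits:
            raise AnalysisError(f"no fittable curve at PAM={pam:g} µM")
        if len(fits) == 1:
            ic50[pam] = fits[0].ec50
            hills[pam] = fits[0].h
        else:
            ic50[pam] = aggregate_log_ec50(fits).ec50
            hills[pam] = float(np.mean([f.h for f in fits]))

    baseline = ic50[0.0]
    ratios = {pam: (1.0 if pam == 0.0 else ic50[pam] / baseline) for pam in levels}

    x = np.array(levels)
    y = np.array([ratios[p] - 1.0 for p in levels])
    reg = stats.linregress(x, y)
    half = stats.t.ppf(0.975, df=len(levels) - 2) * reg.stderr
    slope_ci = (reg.slope - half, reg.slope + half)
    r2 = float(reg.rvalue ** 2)
    max_dev = float(np.abs(y).max())

    if max_dev <= flatness_threshold:
        verdict = INDEPENDENT_SITES
    elif r2 >= r2_threshold and reg.slope > 0 and slope_ci[0] > 0:
        verdict = SHARED_SITE
    else:
        verdict = INDETERMINATE

    return DoseRatioResult(
        pam_concentrations=tuple(levels),
        baseline_ic50=float(baseline),
        ic50_prime=tuple(float(ic50[p]) for p in levels),
        dose_ratios=tuple(float(ratios[p]) for p in levels),
        slope=float(reg.slope), slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        intercept=float(reg.intercept), r_squared=r2, verdict=verdict,
        hill_slopes=tuple(float(hills[p]) for p in levels),
        thresholds={"r2": r2_threshold, "flatness": flatness_threshold},
    )


def predict_independent_action(modulation_a, modulation_b):
    """Expected combined modulation (% of control) if two modulators act
    independently: the product of their individual percent effects.

    E.g. a NAM leaving 14% of control combined with a PAM producing 230%
    of control predicts 14 * 230 / 100 = 32.2% if the sites do not interact.
    Accepts scalars or per-replicate arrays; commutative and associative.
    """
    a = np.asarray(modulation_a, dtype=float)
    b = np.asarray(modulation_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("modulation", "percent-of-control values must be >= 0")
    out = a * b / 100.0
    return float(out) if out.ndim == 0 else out


def compare_combination(observed, predicted) -> CombinationComparison:
    """Paired comparison of observed co-application responses with the
    independent-action prediction.

    ``observed`` is per-replicate percent of control; ``predicted`` a scalar
    or matching per-replicate array.  Uses a paired (one-sample on the
    differences) t-test; identically zero differences are reported as "no
    detectable difference" rather than an ill-defined p-value.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.broadcast_to(np.asarray(predicted, dtype=float), obs.shape)
    if obs.size < 2:
        raise ValidationError("observed", "need >=2 replicates")
    diffs = obs - pred
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        note = ("no detectable difference" if mean == 0.0
                else "zero-variance differences; t undefined")
        return CombinationComparison(mean, None, None, obs.size, note)
    t = mean / (sd / math.sqrt(obs.size))
    p = float(2 * stats.t.sf(abs(t), df=obs.size - 1))
    return CombinationComparison(mean, float(t), p, obs.size)
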