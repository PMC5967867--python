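"""Mutant-panel normalisation and modulator-sensitivity classification.

Each construct's response in a fixed modulator concentration is expressed as
a percentage of that construct's own agonist-only response, paired per
replicate (per oocyte).  A mutant is then compared to wild type by
confidence-interval overlap at a stringent level (99% by default, suited to
screening dozens of constructs): overlapping intervals mean the mutation
left modulation UNCHANGED; otherwise the mutant mean's position relative to
the 100% line and the wild-type mean decides between apparent LOSS of
modulator activity (mutant pulled toward 100%), AUGMENTED activity (pushed
farther from 100% on the wild-type side) and INVERTED modulation (crossed to
the other side of 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

UNCHANGED = "UNCHANGED"
LOSS = "LOSS"
AUGMENTED = "AUGMENTED"
INVERTED = "INVERTED"

PANEL_COLUMNS = ("construct", "replicate_id", "percent_of_control")


@dataclass(frozen=True)
class MutantClassification:
    construct: str
    category: str
    mutant_mean: float
    mutant_ci: tuple
    wild_type_mean: float
    wild_type_ci: tuple
    ci_level: float
    n_mutant: int
    n_wild_type: int


def normalize_panel(raw: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-control normalisation of paired raw responses.

    ``raw`` must have columns ``construct, replicate_id,
    response_modulator, response_control``; each replicate's modulator
    response is divided by its own agonist-only control.  A non-positive
    control raises, naming the replicate.
    """
    missing = {"construct", "replicate_id", "response_modulator",
               "response_control"} - set(raw.columns)
    if missing:
        raise ValidationError("raw", f"missing columns {sorted(missing)}")
    bad = raw[raw["response_control"] <= 0]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValidationError(
            "response_control",
            f"non-positive agonist-only control for construct "
            f"{r['construct']!r}, replicate {r['replicate_id']!r}")
    out = raw[["construct", "replicate_id"]].copy()
    out["percent_of_control"] = 100.0 * raw["response_modulator"] \
        / raw["response_control"]
    return out


def _mean_ci(values: np.ndarray, level: float):
    n = values.size
    mean = float(values.mean())
    sem = float(values.std(ddof=1)) / math.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sem
    return mean, (mean - half, mean + half), n


def classify_mutant(panel: pd.DataFrame, construct: str,
                    wild_type: str = "WT",
                    level: float = 0.99) -> MutantClassification:
    """Classify one construct's modulator sensitivity against wild type.

    t-based confidence intervals at ``level`` are computed for both
    constructs from their per-replicate percent-of-control values; see the
    module docstring for the category rules.  Fewer than two replicates in
    either group refuses classification.
    """
    for name in (construct, wild_type):
        if name not in set(panel["construct"]):
            raise ValidationError("construct", f"{name!r} not present in panel")
    mut = panel.loc[panel["construct"] == construct,
                    "percent_of_control"].to_numpy(dtype=float)
    wt = panel.loc[panel["construct"] == wild_type,
                   "percent_of_control"].to_numpy(dtype=float)
    if (mut <= 0).any() or (wt <= 0).any():
        raise ValidationError("percent_of_control", "must be > 0")
    if mut.size < 2 or wt.size < 2:
        raise ValidationError(
            "n", f"need >=2 replicates per construct "
            f"(got {mut.size} mutant, {wt.size} wild type)")

    m_mean, m_ci, m_n = _mean_ci(mut, level)
    w_mean, w_ci, w_n = _mean_ci(wt, level)

    overlap = m_ci[0] <= w_ci[1] and w_ci[0] <= m_ci[1]
    if overlap:
        category = UNCHANGED
    else:
        d_wt = w_mean - 100.0
        d_mut = m_mean - 100.0
        if d_wt == 0.0:
            # wild type shows no modulation; any significant difference is a
            # gain of effect, direction-agnostic
            category = AUGMENTED
        elif d_mut * d_wt < 0:
            category = INVERTED
        elif abs(d_mut) < abs(d_wt):
            category = LOSS
        else:
            category = AUGMENTED
    return MutantClassification(
        construct=construct, category=category,
        mutant_mean=m_mean, mutant_ci=m_ci,
        wild_type_mean=w_mean, wild_type_ci=w_ci,
        ci_level=level, n_mutant=m_n, n_wild_type=w_n,
    )


def classify_panel(panel: pd.DataFrame, wild_type: str = "WT",
                   level: float = 0.99) -> list:
    """Classify every non-wild-type construct in the panel."""
    constructs = [c for c in panel["construct"].unique() if c != wild_type]
    return [classify_mutant(panel, c, wild_type, level) for c in constructs]
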