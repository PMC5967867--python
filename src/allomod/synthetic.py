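"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here under a fixed
seed, emulating the study designs of two-electrode voltage-clamp modulator
pharmacology: five-point concentration-response curves in half-log steps
with a handful of replicates (oocytes) and proportional scatter, whole-cell
relaxation traces with instrument-additive noise, first-order enantiomer
racemization time courses, and mutant-vs-wild-type response panels drawn
around specified means.

Noise models
------------
* ``multiplicative-lognormal`` (CRC default, 5% CV): responses are scaled by
  a mean-one lognormal factor, matching the proportional scatter of
  normalised oocyte responses.
* ``additive-gaussian`` (trace default): constant-variance instrument noise.
* ``none``: noiseless ground truth; every generator is a pure function of
  (truth, design, config), so the noiseless output is seed-independent and
  round-trips through the corresponding fitter to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import hill_agonist, hill_modulator
from .exceptions import ValidationError
from .receptor import RelaxationTrace, ReceptorScheme, simulate_relaxation

NOISE_MODELS = ("none", "multiplicative-lognormal", "additive-gaussian")

#: default five-point modulator design, half-log steps (µM)
DEFAULT_CRC_DESIGN = (0.3, 1.0, 3.0, 10.0, 30.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded design shared by all generators."""

    seed: int = 0
    noise: str = "multiplicative-lognormal"
    noise_scale: float = 0.05
    n_replicates: int = 8

    def __post_init__(self):
        if self.noise not in NOISE_MODELS:
            raise ValidationError("noise", f"must be one of {NOISE_MODELS}")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale", "must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates", "must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(values: np.ndarray, cfg: GeneratorConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if cfg.noise == "none" or cfg.noise_scale == 0:
        return values.copy()
    if cfg.noise == "multiplicative-lognormal":
        s = cfg.noise_scale
        # mean-one lognormal factor: E[exp(s*z - s^2/2)] = 1
        return values * np.exp(s * rng.standard_normal(values.shape) - s * s / 2)
    return values + cfg.noise_scale * rng.standard_normal(values.shape)


# ---------------------------------------------------------------------------
# concentration-response curves
# ---------------------------------------------------------------------------

def generate_crc(truth: dict, design=DEFAULT_CRC_DESIGN,
                 cfg: GeneratorConfig = GeneratorConfig(),
                 form: str = "modulator", condition: str = "synthetic") -> pd.DataFrame:
    """Tidy CRC table drawn around a Hill-equation truth.

    ``truth`` supplies ``ec50``, ``h`` and (for the modulator form)
    ``extent``.  One curve per replicate over the ``design`` concentrations;
    deterministic under ``cfg.seed``.
    """
    concs = np.asarray(list(design), dtype=float)
    if concs.size == 0:
        raise ValidationError("design", "must contain at least one concentration")
    if form == "modulator":
        clean = hill_modulator(concs, truth["ec50"], truth["h"], truth["extent"])
    elif form == "agonist":
        clean = hill_agonist(concs, truth["ec50"], truth["h"])
    else:
        raise ValidationError("form", f"unknown form {form!r}")
    clean = np.atleast_1d(np.asarray(clean, dtype=float))
    rng = cfg.rng()
    frames = []
    for rep in range(cfg.n_replicates):
        frames.append(pd.DataFrame({
            "replicate_id": f"rep{rep:03d}",
            "condition": condition,
            "concentration_um": concs,
            "response": _apply_noise(clean, cfg, rng),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# relaxation traces
# ---------------------------------------------------------------------------

def generate_two_state_traces(k_on: float, k_off: float, concentrations,
                              duration_s: float = 10.0, n_samples: int = 120,
                              amplitude: float = -0.8, baseline: float = 1.0,
                              cfg: GeneratorConfig = GeneratorConfig(
                                  noise="additive-gaussian", noise_scale=0.0)):
    """Mono-exponential onset/washout trace pairs from two-state truth.

    Onset at modulator concentration [M] relaxes with observed rate
    ``k_on*[M] + k_off`` toward a bound-fraction-scaled plateau; washout
    relaxes back at ``k_off``.  Returns ``(onset, washout)`` lists of
    ``(concentration_um, RelaxationTrace)`` pairs.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValidationError("rates", "k_on and k_off must be > 0")
    rng = cfg.rng()
    t = np.linspace(0.0, duration_s, n_samples)
    onset, washout = [], []
    for conc in concentrations:
        kobs = k_on * conc + k_off
        occ = conc * k_on / kobs  # equilibrium bound fraction
        y_on = baseline + amplitude * occ * (1 - np.exp(-kobs * t))
        y_off = baseline + amplitude * occ * np.exp(-k_off * t)
        onset.append((float(conc), RelaxationTrace(t, _apply_noise(y_on, cfg, rng))))
        washout.append((float(conc), RelaxationTrace(t, _apply_noise(y_off, cfg, rng))))
    return onset, washout


def generate_scheme_traces(scheme: ReceptorScheme, protocol, times,
                           cfg: GeneratorConfig = GeneratorConfig(
                               noise="additive-gaussian", noise_scale=0.0),
                           n_traces: int = 1) -> list:
    """Relaxation traces simulated from a full receptor scheme plus noise."""
    clean = simulate_relaxation(scheme, protocol, np.asarray(times, dtype=float))
    rng = cfg.rng()
    return [RelaxationTrace(clean.time, _apply_noise(clean.response, cfg, rng),
                            clean.protocol) for _ in range(n_traces)]


# ---------------------------------------------------------------------------
# racemization
# ---------------------------------------------------------------------------

def generate_racemization(half_life_min: float, times_min,
                          start: float = 1.0, asymptote: float = 0.5,
                          cfg: GeneratorConfig = GeneratorConfig(
                              noise="additive-gaussian", noise_scale=0.0)) -> pd.DataFrame:
    """First-order decay of enantiomeric activity toward the racemic level."""
    if half_life_min <= 0:
        raise ValidationError("half_life_min", "must be > 0")
    t = np.asarray(list(times_min), dtype=float)
    rate = math.log(2) / half_life_min
    clean = asymptote + (start - asymptote) * np.exp(-rate * t)
    rng = cfg.rng()
    return pd.DataFrame({"time_min": t,
                         "activity": _apply_noise(clean, cfg, rng)})


# ---------------------------------------------------------------------------
# mutant panels
# ---------------------------------------------------------------------------

def generate_mutant_panel(constructs: dict,
                          cfg: GeneratorConfig = GeneratorConfig(
                              noise="additive-gaussian")) -> pd.DataFrame:
    """Draw a per-construct percent-of-control panel around specified means.

    ``constructs`` maps construct label to ``(mean_percent, sd_percent, n)``.
    ``cfg.noise`` selects gaussian draws around the mean (sd from the
    construct tuple, not ``cfg.noise_scale``); ``"none"`` yields exact means.
    """
    rng = cfg.rng()
    rows = []
    for label, (mean, sd, n) in constructs.items():
        if n < 2:
            raise ValidationError("n", f"construct {label!r}: need n >= 2")
        if sd < 0:
            raise ValidationError("sd", f"construct {label!r}: must be >= 0")
        draws = (np.full(n, float(mean)) if cfg.noise == "none" or sd == 0
                 else mean + sd * rng.standard_normal(n))
        draws = np.clip(draws, 1e-6, None)  # percentages stay positive
        for i, v in enumerate(draws):
            rows.append({"construct": label, "replicate_id": f"{label}-{i:03d}",
                         "percent_of_control": float(v)})
    return pd.DataFrame(rows)
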