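"""Markov (Q-matrix) model of an agonist-gated receptor with allosteric
modulator layers.

The base scheme is a linear activation chain, by default

    R  <->  RA  <->  RA2  <->  O

with two sequential agonist-binding steps (statistical factors 2 and 1 on
association, 1 and 2 on dissociation) followed by a concerted gating step
(opening rate ``beta``, closing rate ``alpha``).  Each allosteric modulator
adds occupancy layers to this chain: under ``MODEL1`` the modulator site is
mutually exclusive (a receptor can carry at most one modulator at a time),
under ``MODEL2`` every combination of bound modulators is reachable, i.e.
the modulators occupy independent sites.

Modulator efficacy is expressed as a multiplicative factor on the opening
rate ``beta`` in modulator-bound layers (``gating_factor`` > 1 for a PAM,
< 1 for a NAM, 1 for a silent binder).  Agonist dependence is expressed as a
fold-increase in modulator affinity once both agonist molecules are bound
(``state_dependence_factor``).  Per-state modulator dissociation rates and
within-layer rate adjustments are *derived* from these factors by
thermodynamic cycle closure, never set independently, so every closed cycle
of the expanded state graph satisfies microscopic reversibility by
construction (and is re-checked numerically on every build).

Units are fixed: concentrations in µM, time in seconds, rates in 1/s or
1/(µM*s).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    StructureError,
    TopologyError,
    ValidationError,
)

MODEL1 = "MODEL1"
MODEL2 = "MODEL2"

#: relative tolerance for the microscopic-reversibility check on every cycle
CYCLE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ModulatorSpec:
    """Binding and efficacy parameters of one allosteric modulator.

    Parameters
    ----------
    name:
        Label used in state names and concentration maps.
    role:
        ``"PAM"`` or ``"NAM"``; used to route concentrations and for
        reporting only — the mechanics are fully determined by the rates.
    k_on:
        Association rate constant, 1/(µM*s), identical for all states.
    k_off_reference:
        Dissociation rate, 1/s, from the reference state: the fully
        agonist-bound *closed* state (``RA2`` in the default chain).
    gating_factor:
        Factor applied to the opening rate ``beta`` while the modulator is
        bound.  > 1 potentiates, < 1 inhibits (leaving a non-zero response
        plateau at saturation), 1 is binding-only.
    state_dependence_factor:
        Fold-increase of modulator affinity for fully agonist-bound states
        over apo / partially-bound states (use-dependence).  1 means the
        modulator binds all activation states equally.
    blocking:
        If True, states carrying this modulator conduct no current
        regardless of their gating state (full-block limit used for
        analytic cross-checks; the default, False, matches submaximal
        inhibition through ``gating_factor``).
    """

    name: str
    role: str
    k_on: float
    k_off_reference: float
    gating_factor: float = 1.0
    state_dependence_factor: float = 1.0
    blocking: bool = False

    def __post_init__(self):
        if self.role not in ("PAM", "NAM"):
            raise ValidationError("role", f"must be 'PAM' or 'NAM', got {self.role!r}")
        for fld in ("k_on", "k_off_reference", "gating_factor"):
            v = getattr(self, fld)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{self.name}.{fld}", f"must be > 0, got {v!r}")
        if not (np.isfinite(self.state_dependence_factor) and self.state_dependence_factor >= 1):
            raise ValidationError(
                f"{self.name}.state_dependence_factor",
                f"must be >= 1, got {self.state_dependence_factor!r}",
            )

    @property
    def kd_reference(self) -> float:
        """Equilibrium dissociation constant (µM) at the reference state."""
        return self.k_off_reference / self.k_on


@dataclass(frozen=True)
class ReceptorScheme:
    """A validated receptor state scheme with modulator occupancy layers."""

    base_states: tuple = ("R", "RA", "RA2", "O")
    agonist_on: float = 10.0
    agonist_off: float = 40.0
    beta: float = 50.0
    alpha: float = 5000.0
    topology: str = MODEL1
    modulators: tuple = ()
    open_states: frozenset = frozenset({"O"})
    statistical_factors: tuple = (2, 1)
    has_gating_step: bool = True

    # -- structural helpers -------------------------------------------------

    @property
    def n_binding_steps(self) -> int:
        return len(self.base_states) - 1 - (1 if self.has_gating_step else 0)

    def layers(self) -> list:
        """Modulator occupancy layers reachable under the topology."""
        names = [m.name for m in self.modulators]
        if self.topology == MODEL1:
            combos = [frozenset()] + [frozenset({n}) for n in names]
        else:
            combos = [
                frozenset(c)
                for k in range(len(names) + 1)
                for c in itertools.combinations(names, k)
            ]
        return sorted(combos, key=lambda s: (len(s), tuple(sorted(s))))

    def expanded_states(self) -> list:
        """Ordered list of (base_state, occupancy frozenset) pairs."""
        return [(b, layer) for layer in self.layers() for b in self.base_states]

    def state_labels(self) -> list:
        return [state_label(b, s) for b, s in self.expanded_states()]

    def modulator(self, name: str) -> ModulatorSpec:
        for m in self.modulators:
            if m.name == name:
                return m
        raise KeyError(name)

    # -- thermodynamics -----------------------------------------------------

    def phi(self, mod: ModulatorSpec, base_index: int) -> float:
        """Affinity weight of ``mod`` for a base state.

        ``k_off(state) = k_off_reference / phi(state)``; the reference
        (fully agonist-bound closed) state has phi = 1, apo and partially
        agonist-bound states phi = 1/state_dependence_factor, and the open
        state picks up an extra ``gating_factor`` so that the
        binding/gating cycle closes.
        """
        fully_bound = base_index >= self.n_binding_steps
        p = 1.0 if fully_bound else 1.0 / mod.state_dependence_factor
        if self.has_gating_step and base_index == len(self.base_states) - 1:
            p *= mod.gating_factor
        return p

    def base_edges(self) -> list:
        """Reversible base transitions as (i, j, kind, fwd_factor, bwd_factor).

        ``kind`` is ``"agonist"`` (forward rate fwd_factor * agonist_on * [A],
        backward bwd_factor * agonist_off) or ``"gating"`` (beta / alpha).
        """
        edges = []
        k = self.n_binding_steps
        for i in range(k):
            edges.append(
                (i, i + 1, "agonist", self.statistical_factors[i],
                 self.statistical_factors[k - 1 - i])
            )
        if self.has_gating_step:
            edges.append((len(self.base_states) - 2, len(self.base_states) - 1,
                          "gating", 1.0, 1.0))
        return edges


def state_label(base: str, occupancy: frozenset) -> str:
    if not occupancy:
        return base
    return base + "." + "+".join(sorted(occupancy))


# ---------------------------------------------------------------------------
# scheme construction
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Documented default configuration.

    Rate values emulate a low open-probability GluN2D-like receptor:
    glutamate binds with Kd 4 µM (k_on 10 /(µM*s), k_off 40 /s), gating is
    strongly biased closed (beta 50 /s, alpha 5000 /s, peak open probability
    about 0.01), the PAM potentiates maximal responses ~2.5-fold (Kd 2.4 µM
    at the fully-bound closed state) and the NAM inhibits to a ~15% residual
    plateau (Kd 0.20 µM), both binding ~100-fold more tightly once both
    agonist molecules are bound.
    """
    return {
        "schema_version": 1,
        "topology": MODEL1,
        "base_states": ["R", "RA", "RA2", "O"],
        "rates": {
            "agonist_on": 10.0,
            "agonist_off": 40.0,
            "beta": 50.0,
            "alpha": 5000.0,
        },
        "statistical_factors": [2, 1],
        "gating_step": True,
        "open_states": ["O"],
        "modulators": [
            {
                "name": "PAM",
                "role": "PAM",
                "k_on": 10.0,
                "k_off_reference": 24.0,
                "gating_factor": 2.5,
                "state_dependence_factor": 100.0,
            },
            {
                "name": "NAM",
                "role": "NAM",
                "k_on": 10.0,
                "k_off_reference": 2.0,
                "gating_factor": 0.15,
                "state_dependence_factor": 100.0,
            },
        ],
    }


def build_scheme(config: dict | None = None, **overrides) -> ReceptorScheme:
    """Build and validate a :class:`ReceptorScheme` from a configuration dict.

    ``config`` follows the shape of :func:`default_config`; omitted keys take
    the documented defaults.  Raises :class:`ValidationError` naming the
    offending field, or :class:`TopologyError` for MODEL1 configurations that
    request double-occupancy states.
    """
    cfg = default_config()
    if config:
        unknown = set(config) - set(cfg) - {"layers"}
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = {**cfg, **config}
        if config.get("rates"):
            cfg["rates"] = {**default_config()["rates"], **config["rates"]}
    cfg.update(overrides)

    topology = cfg["topology"]
    if topology not in (MODEL1, MODEL2):
        raise ValidationError("topology", f"must be MODEL1 or MODEL2, got {topology!r}")

    if "layers" in cfg and cfg["layers"] is not None:
        if topology == MODEL1 and any(len(layer) > 1 for layer in cfg["layers"]):
            raise TopologyError(
                "MODEL1 is mutually exclusive: a doubly-occupied (NP) state "
                "cannot be specified"
            )

    mods = tuple(
        m if isinstance(m, ModulatorSpec) else ModulatorSpec(**m)
        for m in cfg["modulators"]
    )
    names = [m.name for m in mods]
    if len(set(names)) != len(names):
        raise ValidationError("modulators", "modulator names must be unique")

    rates = cfg["rates"]
    base_states = tuple(cfg["base_states"])
    single_state = len(base_states) == 1
    gating = bool(cfg["gating_step"]) and not single_state
    factors = () if single_state else tuple(cfg["statistical_factors"])
    scheme = ReceptorScheme(
        base_states=base_states,
        agonist_on=float(rates["agonist_on"]),
        agonist_off=float(rates["agonist_off"]),
        beta=float(rates["beta"]),
        alpha=float(rates["alpha"]),
        topology=topology,
        modulators=mods,
        open_states=frozenset(cfg["open_states"]),
        statistical_factors=factors,
        has_gating_step=gating,
    )
    validate_scheme(scheme)
    return scheme


def validate_scheme(scheme: ReceptorScheme) -> None:
    """Check the structural and thermodynamic invariants of a scheme."""
    for fld in ("agonist_on", "agonist_off", "beta", "alpha"):
        v = getattr(scheme, fld)
        if not (np.isfinite(v) and v > 0):
            raise ValidationError(fld, f"must be > 0, got {v!r}")
    if not scheme.open_states:
        raise ConfigurationError("open_states must not be empty")
    if not scheme.open_states <= set(scheme.base_states):
        extra = scheme.open_states - set(scheme.base_states)
        raise ValidationError("open_states", f"unknown states {sorted(extra)}")
    if len(scheme.base_states) != len(set(scheme.base_states)):
        raise ValidationError("base_states", "labels must be unique")
    if scheme.n_binding_steps != len(scheme.statistical_factors):
        raise ValidationError(
            "statistical_factors",
            f"need {scheme.n_binding_steps} factors, got "
            f"{len(scheme.statistical_factors)}",
        )
    if any(f <= 0 for f in scheme.statistical_factors):
        raise ValidationError("statistical_factors", "must be > 0")
    if scheme.modulators:
        check_microscopic_reversibility(scheme)


def check_microscopic_reversibility(scheme: ReceptorScheme,
                                    rel_tol: float = CYCLE_TOLERANCE) -> None:
    """Verify every cycle of the expanded graph is thermodynamically closed.

    Builds the generator at unit concentrations, extracts a cycle basis of
    the underlying undirected graph and compares clockwise vs
    counter-clockwise rate products on each basis cycle.
    """
    qm = build_q_matrix(scheme, agonist_um=1.0,
                        modulator_um={m.name: 1.0 for m in scheme.modulators})
    q = qm.entries
    n = q.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if q[i, j] > 0 and q[j, i] > 0:
                g.add_edge(i, j)
            elif q[i, j] > 0 or q[j, i] > 0:
                raise StructureError(
                    f"one-way transition between states {qm.state_labels[i]!r} "
                    f"and {qm.state_labels[j]!r} breaks reversibility"
                )
    for cycle in nx.cycle_basis(g):
        log_ratio = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            log_ratio += math.log(q[a, b]) - math.log(q[b, a])
        if abs(math.expm1(log_ratio)) > rel_tol:
            labels = [qm.state_labels[i] for i in cycle]
            raise ValidationError(
                "cycle", f"microscopic reversibility violated on {labels}: "
                f"forward/backward product ratio deviates by {math.expm1(log_ratio):.3e}"
            )


# ---------------------------------------------------------------------------
# Q matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QMatrix:
    """Generator matrix of the expanded chain at fixed ligand concentrations."""

    state_labels: tuple
    entries: np.ndarray
    ligand_context: dict
    expanded: tuple  # ((base_state, occupancy frozenset), ...)

    def __post_init__(self):
        q = self.entries
        off = q - np.diag(np.diag(q))
        if (off < 0).any():
            raise ValidationError("entries", "off-diagonal entries must be >= 0")
        if np.abs(q.sum(axis=1)).max() > 1e-12 * max(1.0, np.abs(q).max()):
            raise ValidationError("entries", "rows must sum to zero")

    @property
    def n_states(self) -> int:
        return self.entries.shape[0]


def build_q_matrix(scheme: ReceptorScheme, agonist_um: float,
                   pam_um: float = 0.0, nam_um: float = 0.0,
                   modulator_um: dict | None = None) -> QMatrix:
    """Assemble the generator matrix at the given ligand concentrations.

    ``pam_um`` / ``nam_um`` are routed to modulators by their ``role``;
    ``modulator_um`` (name -> µM) overrides per modulator.
    """
    concs = {}
    for m in scheme.modulators:
        c = pam_um if m.role == "PAM" else nam_um
        if modulator_um is not None and m.name in modulator_um:
            c = modulator_um[m.name]
        concs[m.name] = float(c)
    for label, c in [("agonist_um", agonist_um)] + list(concs.items()):
        if not (np.isfinite(c) and c >= 0):
            raise ValidationError(label, f"concentration must be >= 0, got {c!r}")

    expanded = scheme.expanded_states()
    index = {st: k for k, st in enumerate(expanded)}
    n = len(expanded)
    nb = len(scheme.base_states)
    q = np.zeros((n, n))
    base_index = {b: i for i, b in enumerate(scheme.base_states)}
    edges = scheme.base_edges()
    layer_set = set(scheme.layers())

    for layer in scheme.layers():
        bound = [scheme.modulator(name) for name in layer]
        for (i, j, kind, ffac, bfac) in edges:
            # thermodynamic ratio contributed by bound modulators on this step
            r = 1.0
            for m in bound:
                r *= scheme.phi(m, j) / scheme.phi(m, i)
            if kind == "gating":
                fwd = scheme.beta * r
                bwd = scheme.alpha
            else:
                fwd = ffac * scheme.agonist_on * agonist_um
                bwd = bfac * scheme.agonist_off / r
            a = index[(scheme.base_states[i], layer)]
            b = index[(scheme.base_states[j], layer)]
            q[a, b] += fwd
            q[b, a] += bwd
        # modulator binding/unbinding out of this layer
        for m in scheme.modulators:
            if m.name in layer:
                continue
            target = layer | {m.name}
            if target not in layer_set:
                continue
            for bstate in scheme.base_states:
                a = index[(bstate, layer)]
                b = index[(bstate, target)]
                q[a, b] += m.k_on * concs[m.name]
                q[b, a] += m.k_off_reference / scheme.phi(m, base_index[bstate])

    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return QMatrix(
        state_labels=tuple(state_label(b, s) for b, s in expanded),
        entries=q,
        ligand_context={"agonist_um": float(agonist_um), **concs},
        expanded=tuple(expanded),
    )


# ---------------------------------------------------------------------------
# equilibrium solvers
# ---------------------------------------------------------------------------

def solve_equilibrium_nullspace(qm: QMatrix) -> np.ndarray:
    """Stationary distribution by direct linear algebra (pi Q = 0, sum = 1)."""
    ns = linalg.null_space(qm.entries.T)
    if ns.shape[1] != 1:
        raise StructureError(
            f"stationary distribution is not unique (null space dimension "
            f"{ns.shape[1]}); the state graph is disconnected"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if pi.min() < -1e-10:
        raise StructureError("stationary solve produced negative occupancy")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def solve_equilibrium_ode(qm: QMatrix, initial: np.ndarray | None = None,
                          tol: float = 1e-10, horizon: float = 1e4) -> np.ndarray:
    """Stationary distribution by stiff ODE relaxation of d(pi)/dt = pi Q.

    Integrates from ``initial`` (all mass in the first state by default) in
    growing time windows until the derivative max-norm drops below ``tol``.
    Raises :class:`ConvergenceError` (reporting the residual) if the horizon
    is exhausted.
    """
    if tol <= 0:
        raise ValidationError("tol", "must be > 0")
    q = qm.entries
    n = qm.n_states
    if initial is None:
        pi = np.zeros(n)
        pi[0] = 1.0
    else:
        pi = np.asarray(initial, dtype=float)
        if pi.shape != (n,) or abs(pi.sum() - 1.0) > 1e-8 or pi.min() < 0:
            raise ValidationError("initial", "must be a probability vector over states")
    jac = q.T

    t_end = 1e-3
    t_done = 0.0
    while t_done < horizon:
        t_span = min(t_end, horizon) - t_done
        sol = solve_ivp(
            lambda t, y: y @ q, (0.0, t_span), pi, method="BDF",
            jac=lambda t, y: jac, rtol=1e-10, atol=1e-14,
        )
        if not sol.success:
            raise ConvergenceError(f"stiff integrator failed: {sol.message}")
        pi = sol.y[:, -1]
        t_done = min(t_end, horizon)
        t_end *= 10.0
        residual = np.abs(pi @ q).max()
        if residual < tol:
            pi = np.clip(pi, 0.0, None)
            return pi / pi.sum()
    raise ConvergenceError(
        f"equilibrium not reached within {horizon:g} s of model time",
        residual=float(np.abs(pi @ q).max()),
    )


def response_readout(occupancy: np.ndarray, scheme: ReceptorScheme,
                     weights: dict | None = None) -> float:
    """Macroscopic response: occupancy summed over conducting states.

    A state conducts when its base state is in ``scheme.open_states`` and it
    carries no ``blocking`` modulator.  ``weights`` optionally maps base-state
    labels to relative conductances (unit weights by default).
    """
    if not scheme.open_states:
        raise ConfigurationError("open_states must not be empty")
    blocking = {m.name for m in scheme.modulators if m.blocking}
    total = 0.0
    for p, (bstate, layer) in zip(occupancy, scheme.expanded_states()):
        if bstate in scheme.open_states and not (layer & blocking):
            w = 1.0 if weights is None else weights.get(bstate, 1.0)
            total += w * p
    return float(total)


def equilibrium_response(scheme: ReceptorScheme, agonist_um: float,
                         pam_um: float = 0.0, nam_um: float = 0.0,
                         modulator_um: dict | None = None,
                         weights: dict | None = None) -> float:
    """Convenience: build the generator, solve the stationary state, read out."""
    qm = build_q_matrix(scheme, agonist_um, pam_um, nam_um, modulator_um)
    return response_readout(solve_equilibrium_nullspace(qm), scheme, weights)


# ---------------------------------------------------------------------------
# relaxations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationTrace:
    """A simulated (or measured) current relaxation.

    ``protocol`` is the ordered list of (switch_time_s, concentration dict)
    segments that produced the trace; concentration dicts use the key
    ``"agonist"`` plus modulator names, in µM.
    """

    time: np.ndarray
    response: np.ndarray
    protocol: tuple = ()

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.response, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValidationError("time", "time and response must be 1-D and equal length")
        if (np.diff(t) <= 0).any():
            raise ValidationError("time", "must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", y)


def _segment_q(scheme: ReceptorScheme, concs: dict) -> QMatrix:
    mod_um = {m.name: float(concs.get(m.name, 0.0)) for m in scheme.modulators}
    return build_q_matrix(scheme, float(concs.get("agonist", 0.0)),
                          modulator_um=mod_um)


def simulate_relaxation(scheme: ReceptorScheme, protocol: list,
                        times: np.ndarray,
                        weights: dict | None = None) -> RelaxationTrace:
    """Piecewise propagation of occupancy through a concentration-jump protocol.

    ``protocol`` is a list of ``(switch_time_s, concentrations)`` segments with
    strictly increasing switch times; the system starts at the equilibrium of
    the first segment.  The response is sampled at ``times`` (seconds), which
    must lie within the protocol span.
    """
    if not protocol:
        raise ValidationError("protocol", "must contain at least one segment")
    switch_times = [float(t) for t, _ in protocol]
    if any(b <= a for a, b in zip(switch_times, switch_times[1:])):
        raise ValidationError("protocol", "segment switch times must be increasing")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("times", "must contain at least one sample")
    if times.min() < switch_times[0]:
        raise ValidationError("times", "samples precede the first protocol segment")

    qms = [_segment_q(scheme, concs) for _, concs in protocol]
    pi = solve_equilibrium_nullspace(qms[0])
    t_end = float(times.max())
    bounds = switch_times + [t_end if t_end > switch_times[-1] else switch_times[-1]]

    out = np.empty_like(times)
    order = np.argsort(times)
    k = 0
    for seg, qm in enumerate(qms):
        t0, t1 = bounds[seg], bounds[seg + 1]
        q = qm.entries
        t_cursor = t0
        while k < times.size and (times[order[k]] <= t1 or seg == len(qms) - 1):
            ts = times[order[k]]
            if ts > t1 and seg < len(qms) - 1:
                break
            dt = ts - t_cursor
            if dt > 0:
                pi = pi @ linalg.expm(q * dt)
                t_cursor = ts
            out[order[k]] = response_readout(pi, scheme, weights)
            k += 1
        if seg < len(qms) - 1 and t1 > t_cursor:
            pi = pi @ linalg.expm(q * (t1 - t_cursor))
    return RelaxationTrace(time=times, response=out, protocol=tuple(
        (t, dict(c)) for t, c in protocol))
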