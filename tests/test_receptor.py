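"""State-graph construction, generator-matrix invariants and equilibrium
solvers of the Markov receptor model."""

import numpy as np
import pytest
from scipy.linalg import expm

from allomod import presets, receptor
from allomod.exceptions import (
    ConvergenceError,
    TopologyError,
    ValidationError,
)
from conftest import random_scheme


class TestSchemeConstruction:
    def test_model1_expanded_state_count(self, model1_scheme):
        # 4 base states x {free, P, N} layers
        assert len(model1_scheme.expanded_states()) == 12

    def test_model2_expanded_state_count(self, model2_scheme):
        # 4 base states x {free, P, N, PN} layers
        assert len(model2_scheme.expanded_states()) == 16

    def test_open_state_dissociation_derived_from_cycle_closure(self):
        """A PAM with gating factor g must leave the open state g-fold
        slower than the reference state for the binding/gating cycle to
        close; multiplying rates around the cycle must give exactly 1."""
        sch = receptor.build_scheme({"modulators": [
            {"name": "P", "role": "PAM", "k_on": 10.0, "k_off_reference": 20.0,
             "gating_factor": 5.0}]})
        i_ra2 = sch.base_states.index("RA2")
        i_o = sch.base_states.index("O")
        pam = sch.modulator("P")
        k_off_o = pam.k_off_reference / sch.phi(pam, i_o)
        assert k_off_o == pytest.approx(pam.k_off_reference / 5.0)
        # explicit cycle product: RA2 -> O -> O.P -> RA2.P -> RA2
        qm = receptor.build_q_matrix(sch, 100.0, pam_um=1.0)
        idx = {lbl: k for k, lbl in enumerate(qm.state_labels)}
        cycle = ["RA2", "O", "O.P", "RA2.P"]
        q = qm.entries
        fwd = np.prod([q[idx[a], idx[b]]
                       for a, b in zip(cycle, cycle[1:] + cycle[:1])])
        bwd = np.prod([q[idx[b], idx[a]]
                       for a, b in zip(cycle, cycle[1:] + cycle[:1])])
        assert fwd / bwd == pytest.approx(1.0, rel=1e-12)

    def test_model1_rejects_double_occupancy_layer(self):
        with pytest.raises(TopologyError):
            receptor.build_scheme({"topology": receptor.MODEL1,
                                   "layers": [[], ["PAM"], ["PAM", "NAM"]]})

    def test_nonpositive_rate_names_the_field(self):
        with pytest.raises(ValidationError, match="beta"):
            receptor.build_scheme({"rates": {"beta": -1.0}})

    def test_every_cycle_thermodynamically_closed(self, rng):
        for _ in range(20):
            sch = random_scheme(rng)
            receptor.check_microscopic_reversibility(sch)  # raises on failure


class TestQMatrix:
    def test_generator_property_on_random_schemes(self, rng):
        for _ in range(20):
            sch = random_scheme(rng)
            qm = receptor.build_q_matrix(sch, rng.uniform(0, 200),
                                         pam_um=rng.uniform(0, 30),
                                         nam_um=rng.uniform(0, 30))
            q = qm.entries
            off = q - np.diag(np.diag(q))
            assert (off >= 0).all()
            assert np.abs(q.sum(axis=1)).max() < 1e-12 * max(1, np.abs(q).max())

    def test_concentration_scaled_binding_entry(self):
        sch = presets.binding_only_modulator_scheme(k_on=0.3, k_off=1.2)
        qm = receptor.build_q_matrix(sch, 0.0, nam_um=10.0)
        idx = {lbl: k for k, lbl in enumerate(qm.state_labels)}
        assert qm.entries[idx["R"], idx["R.M"]] == pytest.approx(3.0)

    def test_zero_concentration_zeroes_binding_entries(self, model1_scheme):
        qm = receptor.build_q_matrix(model1_scheme, 100.0, pam_um=5.0, nam_um=0.0)
        idx = {lbl: k for k, lbl in enumerate(qm.state_labels)}
        for b in model1_scheme.base_states:
            assert qm.entries[idx[b], idx[f"{b}.NAM"]] == 0.0

    def test_negative_concentration_rejected(self, model1_scheme):
        with pytest.raises(ValidationError):
            receptor.build_q_matrix(model1_scheme, -1.0)


class TestEquilibrium:
    def test_symmetric_two_state_splits_evenly(self):
        sch = presets.binding_only_modulator_scheme(k_on=1.0, k_off=2.0)
        qm = receptor.build_q_matrix(sch, 0.0, nam_um=2.0)  # on = off = 2/s
        for solver in (receptor.solve_equilibrium_nullspace,
                       receptor.solve_equilibrium_ode):
            pi = solver(qm)
            assert pi == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_binding_isotherm_exact(self):
        """With gating removed, bound fraction must equal [M]/([M]+Kd)."""
        sch = presets.binding_only_modulator_scheme(k_on=0.3, k_off=1.2)  # Kd 4
        for m in (1.0, 4.0, 40.0):
            qm = receptor.build_q_matrix(sch, 0.0, nam_um=m)
            pi = receptor.solve_equilibrium_nullspace(qm)
            assert pi[1] == pytest.approx(m / (m + 4.0), rel=1e-12)

    def test_ode_matches_nullspace_over_random_schemes(self, rng):
        for _ in range(30):
            sch = random_scheme(rng)
            qm = receptor.build_q_matrix(sch, rng.uniform(1, 200),
                                         pam_um=rng.uniform(0, 20),
                                         nam_um=rng.uniform(0, 20))
            pi_ns = receptor.solve_equilibrium_nullspace(qm)
            pi_ode = receptor.solve_equilibrium_ode(qm)
            assert np.abs(pi_ns - pi_ode).max() < 1e-8
            assert pi_ode.sum() == pytest.approx(1.0, abs=1e-10)
            assert pi_ode.min() >= 0

    def test_equilibrium_independent_of_start(self, model1_scheme, rng):
        qm = receptor.build_q_matrix(model1_scheme, 100.0, pam_um=3.0, nam_um=1.0)
        n = qm.n_states
        results = []
        starts = [np.eye(n)[0], np.full(n, 1.0 / n)]
        x = rng.dirichlet(np.ones(n))
        starts.append(x)
        for s in starts:
            results.append(receptor.solve_equilibrium_ode(qm, initial=s))
        for r in results[1:]:
            assert np.abs(r - results[0]).max() < 1e-8

    def test_nullspace_matches_long_time_propagation(self):
        """Three-state chain: stationary vector equals brute-force
        propagation of the matrix exponential to long times."""
        sch = receptor.build_scheme({
            "base_states": ["R", "RA", "RA2"], "open_states": ["RA2"],
            "gating_step": False,
            "statistical_factors": [2, 1], "modulators": [],
            "rates": {"agonist_on": 3.0, "agonist_off": 7.0,
                      "beta": 1.0, "alpha": 1.0}})
        qm = receptor.build_q_matrix(sch, 5.0)
        pi = receptor.solve_equilibrium_nullspace(qm)
        p0 = np.array([1.0, 0.0, 0.0])
        brute = p0 @ expm(qm.entries * 1e4)
        assert np.abs(pi - brute).max() < 1e-10

    def test_state_relabeling_permutes_occupancy(self, model1_scheme):
        qm = receptor.build_q_matrix(model1_scheme, 100.0, pam_um=2.0, nam_um=1.0)
        pi = receptor.solve_equilibrium_nullspace(qm)
        perm = np.random.default_rng(7).permutation(qm.n_states)
        q_p = qm.entries[np.ix_(perm, perm)]
        qm_p = receptor.QMatrix(tuple(np.array(qm.state_labels)[perm]), q_p,
                                qm.ligand_context,
                                tuple(np.array(qm.expanded, dtype=object)[perm]))
        pi_p = receptor.solve_equilibrium_nullspace(qm_p)
        assert np.abs(pi_p - pi[perm]).max() < 1e-12

    def test_ode_reports_residual_on_tiny_horizon(self, model1_scheme):
        qm = receptor.build_q_matrix(model1_scheme, 100.0, nam_um=0.3)
        with pytest.raises(ConvergenceError):
            receptor.solve_equilibrium_ode(qm, tol=1e-14, horizon=1e-6)


class TestReadout:
    def test_zero_open_occupancy_reads_zero(self, model1_scheme):
        occ = np.zeros(len(model1_scheme.expanded_states()))
        assert receptor.response_readout(occ, model1_scheme) == 0.0

    def test_readout_sums_open_states_with_weights(self, model2_scheme):
        states = model2_scheme.expanded_states()
        occ = np.zeros(len(states))
        open_idx = [k for k, (b, s) in enumerate(states) if b == "O"][:2]
        occ[open_idx] = 0.2
        assert receptor.response_readout(occ, model2_scheme) == pytest.approx(0.4)

    def test_nam_saturating_plateau_submaximal_but_nonzero(self, model1_scheme):
        """A NAM acting through a reduced opening rate must leave a residual
        plateau strictly between zero and control at saturation."""
        control = receptor.equilibrium_response(model1_scheme, 100.0)
        sat = receptor.equilibrium_response(model1_scheme, 100.0, nam_um=1e3)
        assert 0 < sat < control
        # near the gating-factor bound but not identically zero
        assert sat / control > 0.1


class TestRelaxation:
    def test_constant_protocol_from_equilibrium_is_flat(self, model1_scheme):
        times = np.linspace(0, 2, 40)
        tr = receptor.simulate_relaxation(
            model1_scheme, [(0.0, {"agonist": 100.0, "NAM": 1.0})], times)
        assert np.ptp(tr.response) < 1e-10

    def test_two_state_jump_relaxes_at_kobs(self, two_state_scheme):
        """Concentration jump 0 -> [M] on a two-state binder relaxes
        mono-exponentially with observed rate k_on*[M] + k_off."""
        m = 10.0
        kobs = 0.3 * m + 1.2
        times = np.linspace(0, 3.0, 50)
        tr = receptor.simulate_relaxation(
            two_state_scheme,
            [(0.0, {"agonist": 0.0, "M": 0.0}), (0.0 + 1e-9, {"agonist": 0.0, "M": m})],
            times + 1e-9)
        # readout = unbound fraction; analytic relaxation toward kd/(m+kd)
        kd = 4.0
        expected = kd / (m + kd) + (1 - kd / (m + kd)) * np.exp(-kobs * times)
        assert np.abs(tr.response - expected).max() < 1e-8

    def test_segment_ends_reach_segment_equilibria(self, model1_scheme):
        protocol = [(0.0, {"agonist": 100.0}),
                    (5.0, {"agonist": 100.0, "NAM": 3.0}),
                    (60.0, {"agonist": 100.0})]
        times = np.array([4.999, 59.999, 200.0])
        tr = receptor.simulate_relaxation(model1_scheme, protocol, times)
        eq = [receptor.equilibrium_response(model1_scheme, 100.0),
              receptor.equilibrium_response(model1_scheme, 100.0, nam_um=3.0),
              receptor.equilibrium_response(model1_scheme, 100.0)]
        assert np.abs(tr.response - np.array(eq)).max() < 1e-6

    def test_empty_protocol_rejected(self, model1_scheme):
        with pytest.raises(ValidationError):
            receptor.simulate_relaxation(model1_scheme, [], np.array([0.0]))
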