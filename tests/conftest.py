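import numpy as np
import pytest

from allomod import presets, receptor


@pytest.fixture(scope="session")
def model1_scheme():
    return presets.demo_scheme(receptor.MODEL1)


@pytest.fixture(scope="session")
def model2_scheme():
    return presets.demo_scheme(receptor.MODEL2)


@pytest.fixture(scope="session")
def gaddum_scheme():
    return presets.gaddum_scheme(k_n_um=1.0, k_p_um=2.0)


@pytest.fixture(scope="session")
def two_state_scheme():
    return presets.binding_only_modulator_scheme(k_on=0.3, k_off=1.2)


def random_scheme(rng):
    """Random valid scheme for fuzzing (log-uniform rates, either topology)."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    mods = [
        {"name": "P", "role": "PAM", "k_on": lu(1, 30),
         "k_off_reference": lu(1, 100), "gating_factor": lu(2, 10),
         "state_dependence_factor": lu(1, 200)},
        {"name": "N", "role": "NAM", "k_on": lu(1, 30),
         "k_off_reference": lu(1, 100), "gating_factor": lu(0.05, 0.5),
         "state_dependence_factor": lu(1, 200)},
    ]
    topology = receptor.MODEL1 if rng.random() < 0.5 else receptor.MODEL2
    return receptor.build_scheme({
        "topology": topology,
        "rates": {"agonist_on": lu(1, 30), "agonist_off": lu(5, 200),
                  "beta": lu(10, 200), "alpha": lu(100, 8000)},
        "modulators": mods[: 1 + int(rng.random() < 0.7)],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
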