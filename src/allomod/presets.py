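"""Ready-made schemes for demonstrations, oracles and end-to-end runs."""

from __future__ import annotations

from .receptor import MODEL1, MODEL2, ReceptorScheme, build_scheme


def demo_scheme(topology: str = MODEL1) -> ReceptorScheme:
    """The default GluN2D-like demonstration scheme (see
    :func:`allomod.receptor.default_config`) under either binding topology."""
    return build_scheme({"topology": topology})


def gaddum_scheme(k_n_um: float = 1.0, k_p_um: float = 2.0,
                  k_on: float = 10.0) -> ReceptorScheme:
    """Binding-only one-site competition scheme with a closed-form oracle.

    A single conducting base state, a full-block NAM (dissociation constant
    ``k_n_um``) and a silent, binding-only PAM (``k_p_um``) competing under
    MODEL1.  The equilibrium response is then the classical two-ligand
    competition occupancy, and the shifted midpoint obeys
    IC50' = K_N * (1 + [P]/K_P) exactly.
    """
    return build_scheme({
        "base_states": ["R"],
        "open_states": ["R"],
        "modulators": [
            {"name": "P", "role": "PAM", "k_on": k_on,
             "k_off_reference": k_on * k_p_um},
            {"name": "N", "role": "NAM", "k_on": k_on,
             "k_off_reference": k_on * k_n_um, "blocking": True},
        ],
    })


def binding_only_modulator_scheme(k_on: float = 0.3, k_off: float = 1.2,
                                  blocking: bool = True) -> ReceptorScheme:
    """Two-state (free / modulator-bound) scheme for kinetics oracles.

    With a single base state and one modulator the occupancy relaxes
    mono-exponentially with observed rate ``k_on * [M] + k_off``.
    """
    return build_scheme({
        "base_states": ["R"],
        "open_states": ["R"],
        "modulators": [
            {"name": "M", "role": "NAM", "k_on": k_on,
             "k_off_reference": k_off, "blocking": blocking},
        ],
    })
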