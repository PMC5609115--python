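"""Named mechanism presets and the built-in channel library.

The paper-grade source models carry their kinetics in external parameter
sets; the presets here are free parameters of the reduced archetypes,
chosen to give each cell the qualitative behavior the protocols require
(thin high-density AIS, sparse dendritic Na+ conductance for the
pyramidal/purkinje cells, active dendrites for the mitral cell, a distal
Ca2+ hot zone, ...).  Pump distribution orders of magnitude (mol/cm^2:
soma 1e-11, axon 5e-12, dendrites 1e-15) and the distributed-input pump
variant (dendritic density 50e-15, equilibrium quartered) are fixed values;
kinetic rate constants are ported-style defaults, fully overridable.

Everything here is plain data; :func:`nadyn.solver.build_model` resolves a
preset onto a morphology.
"""

from __future__ import annotations

import copy
from dataclasses import replace

from .membrane import ChannelSpec, GateSpec, RateFn

__all__ = ["channel_spec", "get_preset", "merge_preset", "PRESET_NAMES"]

_Q = 3.0  # rate temperature factor applied to the fast spike channels


def _nat() -> ChannelSpec:
    """Transient Na+ channel, m^3 h, squid-derived rate forms."""
    return ChannelSpec(
        name="na_t",
        ion="Na",
        gbar=0.12,
        mode="nernst_dynamic",
        valence=1,
        gates=(
            GateSpec(
                "m", 3,
                alpha=RateFn("linoid", 0.1, -40.0, 10.0),
                beta=RateFn("expo", 4.0, -65.0, -18.0),
                q=_Q,
            ),
            GateSpec(
                "h", 1,
                alpha=RateFn("expo", 0.07, -65.0, -20.0),
                beta=RateFn("sigmoid", 1.0, -35.0, 10.0),
                q=_Q,
            ),
        ),
    )


def _nap() -> ChannelSpec:
    """Persistent Na+ channel (non-inactivating, low threshold)."""
    return ChannelSpec(
        name="na_p",
        ion="Na",
        gbar=1e-4,
        mode="nernst_dynamic",
        valence=1,
        gates=(
            GateSpec(
                "p", 1,
                inf=RateFn("sigmoid", 1.0, -52.0, 5.0),
                tau=RateFn("constant", 5.0),
            ),
        ),
    )


def _kdr(e_k: float = -90.0) -> ChannelSpec:
    """Delayed-rectifier K+ channel, n^4."""
    return ChannelSpec(
        name="k_dr",
        ion="K",
        gbar=0.036,
        mode="fixed_reversal",
        erev=e_k,
        gates=(
            GateSpec(
                "n", 4,
                alpha=RateFn("linoid", 0.01, -55.0, 10.0),
                beta=RateFn("expo", 0.125, -65.0, -80.0),
                q=_Q,
            ),
        ),
    )


def _cah() -> ChannelSpec:
    """High-threshold Ca2+ channel, q^2, GHK flux (gbar is cm/s)."""
    return ChannelSpec(
        name="ca_h",
        ion="Ca",
        gbar=1e-6,
        mode="ghk",
        valence=2,
        gates=(
            GateSpec(
                "q", 2,
                inf=RateFn("sigmoid", 1.0, -35.0, 4.5),
                tau=RateFn("constant", 2.0),
            ),
        ),
    )


def _leak(e_rev: float = -70.0) -> ChannelSpec:
    return ChannelSpec(
        name="leak", ion="nonspecific", gbar=1e-4, mode="fixed_reversal", erev=e_rev
    )


_CHANNEL_BUILDERS = {
    "na_t": _nat,
    "na_p": _nap,
    "k_dr": _kdr,
    "ca_h": _cah,
    "leak": _leak,
}


def channel_spec(name: str, e_k: float | None = None) -> ChannelSpec:
    """Instantiate a library channel; K+ channels adopt the model's E_K."""
    if name not in _CHANNEL_BUILDERS:
        raise KeyError(f"unknown channel {name!r}; known: {sorted(_CHANNEL_BUILDERS)}")
    spec = _CHANNEL_BUILDERS[name]()
    if e_k is not None and spec.ion == "K":
        spec = replace(spec, erev=e_k)
    return spec


# ---------------------------------------------------------------------------
# pump / exchanger / buffer parameter blocks (shared defaults)
# ---------------------------------------------------------------------------

# Na+-K+ pump kinetics: equilibrium [Na+]i = Na_o * (k2 k4 / k1 k3)^(1/3)
# = 10 mM at Na_o = 150; saturation and half-activation placed so the
# current rises steeply above ~20 mM.
NA_PUMP = {
    "k1": 1.0e-4,  # 1/(mM^3 ms)
    "k2": 1.4815e-3,  # 1/ms
    "k3": 0.03,  # 1/ms
    "k4": 6.0e-7,  # 1/(mM^3 ms)
    "density": {
        "soma": 1e-11,
        "AIS": 5e-12,
        "axon_node": 5e-12,
        "axon_myelin": 0.0,
        "dendrite_proximal": 1e-15,
        "dendrite_distal": 1e-15,
        "tuft": 1e-15,
    },
}

# Ca2+ pump (stoichiometry 1, two charges per cycle): equilibrium
# [Ca2+]i = Ca_o * k2 k4 / (k1 k3) = 20 nM at Ca_o = 2 mM.
CA_PUMP = {
    "k1": 1.0,  # 1/(mM ms)
    "k2": 0.01,  # 1/ms
    "k3": 0.02,  # 1/ms
    "k4": 2.0e-5,  # 1/(mM ms)
    "charge_per_cycle": 2.0,
    "density": {
        "soma": 1.2e-11,
        "AIS": 1.2e-11,
        "axon_node": 1.2e-11,
        "axon_myelin": 0.0,
        "dendrite_proximal": 2e-12,
        "dendrite_distal": 2e-12,
        "tuft": 2e-12,
    },
}

NCX = {
    "i_max": 2.6e-2,  # mA/cm^2
    "gamma": 0.35,
    "km_na": 87.5,
    "km_ca": 1.38,
    "k_sat": 0.1,
    "electrogenic": True,
}

BUFFER = {"total_buffer": 0.02, "k_on": 2.0, "k_off": 2e-3}  # Kd = 1 uM

IONS = {"na_o": 150.0, "na_i": 10.0, "ca_o": 2.0, "ca_i": 5e-5, "e_k": -90.0}

MEMBRANE = {"c_m": 1.0, "Ra": 150.0, "v_init": -70.0}


def _base_preset() -> dict:
    return {
        "membrane": copy.deepcopy(MEMBRANE),
        "ions": copy.deepcopy(IONS),
        "temperature": 310.15,
        "na_pump": copy.deepcopy(NA_PUMP),
        "ca_pump": copy.deepcopy(CA_PUMP),
        "ncx": copy.deepcopy(NCX),
        "buffer": copy.deepcopy(BUFFER),
        "diffusion": {"d_na": 0.3, "spine_correction": False},
        "channels": [],
    }


def _mitral() -> dict:
    p = _base_preset()
    # active Na+ conductance extends into the distal dendrites and tuft
    p["channels"] = [
        {"channel": "na_t", "gbar": {
            "AIS": 1.2, "soma": 0.08, "axon_node": 0.5,
            "dendrite_proximal": 0.01, "dendrite_distal": 0.06, "tuft": 0.06,
        }},
        {"channel": "na_p", "gbar": {"AIS": 1.5e-3, "soma": 3e-4}},
        {"channel": "k_dr", "gbar": {
            "AIS": 0.36, "soma": 0.07, "axon_node": 0.15,
            "dendrite_proximal": 0.01, "dendrite_distal": 0.03, "tuft": 0.03,
        }},
        {"channel": "ca_h", "gbar": {"tuft": 1e-5, "dendrite_distal": 2e-6,
                                     "soma": 1e-6}},
        {"channel": "leak", "gbar": {
            "AIS": 1e-4, "soma": 1e-4, "axon_node": 1e-4,
            "dendrite_proximal": 1e-4, "dendrite_distal": 1e-4, "tuft": 1e-4,
        }},
    ]
    return p


def _pyramidal() -> dict:
    p = _base_preset()
    # very low dendritic Na+ conductance; highest somatic Na+ of the three;
    # the exchanger's electrogenic effect is removed (it is assumed already
    # folded into the fitted membrane model)
    p["ncx"]["electrogenic"] = False
    p["channels"] = [
        {"channel": "na_t", "gbar": {
            "AIS": 1.0, "soma": 0.25, "axon_node": 0.5,
            "dendrite_proximal": 2e-3, "dendrite_distal": 2e-3, "tuft": 2e-3,
        }},
        {"channel": "k_dr", "gbar": {
            "AIS": 0.3, "soma": 0.1, "axon_node": 0.15,
            "dendrite_proximal": 5e-3, "dendrite_distal": 5e-3, "tuft": 5e-3,
        }},
        {"channel": "na_p", "gbar": {"dendrite_proximal": 1e-4,
                                     "dendrite_distal": 1e-4}},
        {"channel": "ca_h", "gbar": {"soma": 1e-6, "dendrite_proximal": 4e-6,
                                     "dendrite_distal": 1e-6, "tuft": 5e-7}},
        {"channel": "leak", "gbar": {
            "AIS": 1e-4, "soma": 1e-4, "axon_node": 1e-4,
            "dendrite_proximal": 1e-4, "dendrite_distal": 1e-4, "tuft": 1e-4,
        }},
    ]
    # distal apical Ca2+ conductance hot zone (path distance from soma, um)
    p["ca_hot_zone"] = {"distance": 430.0, "width": 40.0, "permeability": 4e-5}
    return p


def _pyramidal_distributed() -> dict:
    """Pyramidal variant for the distributed-input protocol: spine-corrected
    diffusion, higher dendritic pump density and a quartered pump set point
    (prevents run-away Na+ build-up under continuous background input)."""
    p = _pyramidal()
    p["diffusion"]["spine_correction"] = True
    p["na_pump"]["density"]["dendrite_proximal"] = 50e-15
    p["na_pump"]["density"]["dendrite_distal"] = 50e-15
    p["na_pump"]["density"]["tuft"] = 50e-15
    p["na_pump"]["equilibrium_scale"] = 0.25
    return p


def _purkinje() -> dict:
    p = _base_preset()
    p["membrane"]["c_m_per_region"] = {"axon_myelin": 0.05}
    p["channels"] = [
        {"channel": "na_t", "gbar": {
            "AIS": 1.5, "soma": 0.12, "axon_node": 1.0,
            "dendrite_proximal": 1e-3, "dendrite_distal": 1e-3,
        }},
        {"channel": "k_dr", "gbar": {
            "AIS": 0.45, "soma": 0.15, "axon_node": 0.3,
            "dendrite_proximal": 5e-3, "dendrite_distal": 5e-3,
        }},
        {"channel": "ca_h", "gbar": {"soma": 1e-6, "dendrite_proximal": 5e-6,
                                     "dendrite_distal": 5e-6}},
        {"channel": "leak", "gbar": {
            "AIS": 1.2e-4, "soma": 1.2e-4, "axon_node": 1.2e-4,
            "axon_myelin": 1e-5,
            "dendrite_proximal": 1.2e-4, "dendrite_distal": 1.2e-4,
        }},
    ]
    # replace most Ca2+ pumping with Na+-Ca2+ exchange (density transform)
    p["ncx_substitution"] = True
    return p


_PRESETS = {
    "mitral_like": _mitral,
    "pyramidal_like": _pyramidal,
    "pyramidal_distributed": _pyramidal_distributed,
    "purkinje_like": _purkinje,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def get_preset(name: str) -> dict:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    return _PRESETS[name]()


def merge_preset(base: dict, overrides: dict) -> dict:
    """Recursively merge *overrides* into a deep copy of *base*."""
    out = copy.deepcopy(base)

    def _merge(dst, src):
        for key, val in src.items():
            if isinstance(val, dict) and isinstance(dst.get(key), dict):
                _merge(dst[key], val)
            else:
                dst[key] = copy.deepcopy(val)

    _merge(out, overrides)
    return out
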