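"""Shared fixtures: tiny morphologies and minimal mechanism presets."""

import numpy as np
import pytest

from nadyn.morphology import Morphology, RegionTag, Segment
from nadyn.presets import CA_PUMP, NA_PUMP
from nadyn.solver import Model


def passive_preset(g_leak=1e-4, e_leak=-70.0, pumps=False):
    """A minimal preset: leak only, optionally the standard Na+-K+ pump."""
    return {
        "membrane": {"c_m": 1.0, "Ra": 150.0, "v_init": -70.0},
        "ions": {"na_o": 150.0, "na_i": 10.0, "ca_o": 2.0, "ca_i": 5e-5,
                 "e_k": -90.0},
        "temperature": 310.15,
        "channels": [{"channel": "leak", "gbar": {"soma": g_leak}}],
        "na_pump": {
            **{k: NA_PUMP[k] for k in ("k1", "k2", "k3", "k4")},
            "density": {"soma": 1e-11 if pumps else 0.0},
        },
        "ca_pump": {
            **{k: CA_PUMP[k] for k in ("k1", "k2", "k3", "k4")},
            "density": {"soma": 0.0},
        },
        "ncx": {"i_max": 0.0},
        "buffer": {"total_buffer": 0.0},
        "diffusion": {"d_na": 0.3},
    }


def hh_preset(gna=0.12, gk=0.036, gl=3e-4):
    """Classic squid-type excitable single-compartment preset."""
    p = passive_preset(g_leak=gl)
    p["channels"] = [
        {"channel": "na_t", "gbar": {"soma": gna}},
        {"channel": "k_dr", "gbar": {"soma": gk}},
        {"channel": "leak", "gbar": {"soma": gl}},
    ]
    return p


@pytest.fixture
def soma_segment():
    return Segment(0, None, 50.0, 20.0, RegionTag.SOMA, "soma")


@pytest.fixture
def soma_morph(soma_segment):
    return Morphology([soma_segment])


@pytest.fixture
def passive_soma(soma_morph):
    return Model(soma_morph, passive_preset())


@pytest.fixture
def hh_soma(soma_morph):
    return Model(soma_morph, hh_preset())


@pytest.fixture
def chain_morph():
    """Unbranched 5-segment dendrite chain hanging off a soma."""
    segs = [Segment(0, None, 20.0, 20.0, RegionTag.SOMA, "soma")]
    for k in range(5):
        segs.append(
            Segment(
                k + 1, k, 50.0, 2.0, RegionTag.DENDRITE_DISTAL, f"dend{k}"
            )
        )
    return Morphology(segs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
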