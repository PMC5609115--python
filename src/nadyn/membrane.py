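"""Voltage-gated conductances, driving forces and gating kinetics.

Channels are described declaratively (:class:`ChannelSpec`) so parameter sets
can be loaded from configuration without code changes.  Three driving-force
modes are supported:

``nernst_dynamic``
    ohmic current with the reversal potential recomputed every step from the
    current intracellular concentration (used for Na+ channels),
``fixed_reversal``
    ohmic current with a constant reversal potential (K+, leak),
``ghk``
    constant-field flux (required for Ca2+ channels, where the inside/outside
    concentration ratio is far too large for the Nernst form to be useful).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import FARADAY, thermal_voltage

__all__ = [
    "RateFn",
    "GateSpec",
    "ChannelSpec",
    "nernst",
    "ghk_current",
    "channel_current",
    "update_gates",
    "gate_inf_tau",
]


def nernst(c_in: float, c_out: float, valence: int, temperature: float) -> float:
    """Nernst equilibrium potential in mV.

    ``(RT / zF) * ln(c_out / c_in)``, concentrations in mM, temperature in K.
    """
    c_in = np.asarray(c_in, dtype=float)
    if np.any(c_in <= 0) or np.any(np.asarray(c_out, dtype=float) <= 0):
        raise ValueError("Nernst potential requires positive concentrations")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    out = thermal_voltage(temperature) / valence * np.log(c_out / c_in)
    return float(out) if out.ndim == 0 else out


def ghk_current(
    permeability: float,
    valence: int,
    c_in,
    c_out,
    v,
    temperature: float,
):
    """Goldman-Hodgkin-Katz current density (mA/cm^2, outward positive).

    *permeability* in cm/s, concentrations in mM, *v* in mV.  The removable
    singularity at v = 0 is evaluated by its analytic limit
    ``P * z * F * (c_in - c_out)`` (times the mM -> mol/cm^3 factor).
    """
    c_in = np.asarray(c_in, dtype=float)
    c_out_a = np.asarray(c_out, dtype=float)
    if np.any((c_in <= 0) & (c_out_a <= 0)):
        raise ValueError("GHK flux undefined with zero concentration on both sides")
    v = np.asarray(v, dtype=float)
    xi = valence * v / thermal_voltage(temperature)
    # mM = 1e-6 mol/cm^3; P[cm/s] * F * c[mol/cm^3] = A/cm^2 = 1e3 mA/cm^2
    scale = permeability * valence * FARADAY * 1e-6 * 1e3
    small = np.abs(xi) < 1e-6
    xi_safe = np.where(small, 1.0, xi)
    full = scale * xi_safe * (c_in - c_out_a * np.exp(-xi_safe)) / (1.0 - np.exp(-xi_safe))
    # first-order expansion around xi = 0
    lim = scale * (c_in - c_out_a + xi * (c_in + c_out_a) / 2.0)
    out = np.where(small, lim, full)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateFn:
    """A parametric voltage-dependent rate/steady-state function.

    kinds:
      - ``linoid``:   a * (v - vhalf) / (1 - exp(-(v - vhalf) / k))
      - ``expo``:     a * exp((v - vhalf) / k)
      - ``sigmoid``:  a / (1 + exp(-(v - vhalf) / k))
      - ``constant``: a
    """

    kind: str
    a: float
    vhalf: float = 0.0
    k: float = 1.0

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "constant":
            out = np.full_like(v, self.a)
        elif self.kind == "expo":
            out = self.a * np.exp((v - self.vhalf) / self.k)
        elif self.kind == "sigmoid":
            out = self.a / (1.0 + np.exp(-(v - self.vhalf) / self.k))
        elif self.kind == "linoid":
            x = (v - self.vhalf) / self.k
            small = np.abs(x) < 1e-7
            x_safe = np.where(small, 1.0, x)
            out = self.a * self.k * np.where(
                small, 1.0 + x / 2.0, x_safe / (1.0 - np.exp(-x_safe))
            )
        else:
            raise ValueError(f"unknown rate function kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley style gating variable.

    Either (alpha, beta) or (inf, tau) descriptors must be given.  ``q``
    scales both rates (temperature factor).
    """

    name: str
    exponent: int
    alpha: RateFn | None = None
    beta: RateFn | None = None
    inf: RateFn | None = None
    tau: RateFn | None = None
    q: float = 1.0
    tau_min: float = 1e-3  # ms, numerical floor

    def __post_init__(self):
        if self.exponent < 0:
            raise ValueError("gate exponent must be >= 0")
        has_ab = self.alpha is not None and self.beta is not None
        has_it = self.inf is not None and self.tau is not None
        if not (has_ab or has_it):
            raise ValueError(f"gate {self.name}: need alpha/beta or inf/tau")

    def inf_tau(self, v):
        if self.alpha is not None and self.beta is not None:
            a, b = self.alpha(v), self.beta(v)
            tau = 1.0 / (self.q * (np.asarray(a) + np.asarray(b)))
            inf = np.asarray(a) / (np.asarray(a) + np.asarray(b))
        else:
            inf = np.asarray(self.inf(v))  # type: ignore[misc]
            tau = np.asarray(self.tau(v)) / self.q  # type: ignore[misc]
        tau = np.maximum(tau, self.tau_min)
        return inf, tau


def gate_inf_tau(gate: GateSpec, v):
    """Convenience wrapper returning (x_inf(v), tau(v))."""
    return gate.inf_tau(v)


def update_gates(x, gate: GateSpec, v, dt: float):
    """Advance a gating variable by the exact exponential solution at frozen v.

    ``x(t + dt) = x_inf + (x - x_inf) * exp(-dt / tau)``; the result stays in
    [0, 1] for any dt > 0 whenever x_inf does.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    inf, tau = gate.inf_tau(v)
    return inf + (np.asarray(x, dtype=float) - inf) * np.exp(-dt / tau)


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

DRIVING_FORCE_MODES = ("nernst_dynamic", "fixed_reversal", "ghk")


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance (or GHK permeability) with its gating scheme.

    *gbar* is a conductance density (S/cm^2) for ohmic modes or a
    permeability (cm/s) for ``ghk`` mode; per-region densities are resolved
    by the model builder, this is the reference value.
    """

    name: str
    ion: str  # 'Na' | 'K' | 'Ca' | 'nonspecific'
    gbar: float
    gates: tuple[GateSpec, ...] = ()
    mode: str = "fixed_reversal"
    erev: float | None = None  # mV, fixed_reversal mode
    valence: int = 1

    def __post_init__(self):
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")
        if self.mode not in DRIVING_FORCE_MODES:
            raise ValueError(f"unknown driving-force mode {self.mode!r}")
        if self.ion == "Ca" and self.mode != "ghk":
            raise ValueError("Ca channels must use the GHK driving-force mode")
        if self.mode == "fixed_reversal" and self.erev is None:
            raise ValueError("fixed_reversal mode requires erev")

    def open_fraction(self, gate_values: dict[str, float]):
        g = 1.0
        for gate in self.gates:
            g = g * np.asarray(gate_values[gate.name], dtype=float) ** gate.exponent
        return g


def channel_current(
    spec: ChannelSpec,
    gate_values: dict[str, float],
    v,
    c_in=None,
    c_out=None,
    temperature: float = 310.15,
    gbar=None,
):
    """Membrane current density (mA/cm^2, outward positive) of one channel.

    For ``nernst_dynamic`` the reversal potential is recomputed from the
    supplied concentrations; for ``ghk`` the constant-field flux is used.
    *gbar* overrides the spec's density (used for per-segment arrays).
    """
    gb = spec.gbar if gbar is None else gbar
    popen = spec.open_fraction(gate_values)
    if spec.mode == "ghk":
        return popen * ghk_current(gb, spec.valence, c_in, c_out, v, temperature)
    if spec.mode == "nernst_dynamic":
        erev = nernst(c_in, c_out, spec.valence, temperature)
    else:
        erev = spec.erev
    out = gb * popen * (np.asarray(v, dtype=float) - erev)
    return float(out) if np.ndim(out) == 0 else out
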