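"""Intracellular ion dynamics: accumulation, diffusion, pumps and exchange.

This module implements the slow subsystem of the simulator:

* ion accumulation from membrane currents (``d[ion]/dt = I / (zFV)``),
* conservative longitudinal diffusion of Na+ on the compartmental tree,
* the Na+-K+ pump, both as a two-reaction kinetic scheme and as its
  closed-form steady-state current (the default; the closed form is the
  occupancy-equilibrium limit of the kinetic scheme),
* the Na+-Ca2+ exchanger (Courtemanche-form), whose rate depends on the
  trans-membrane Na+ gradient and therefore couples Na+ loading to the
  stable-state Ca2+ level,
* Ca2+ balance with kinetic buffering and a plasma-membrane Ca2+ pump
  modeled like the Na+-K+ pump with different stoichiometry.

All current densities are in mA/cm^2 with *outward positive* sign; fluxes
into concentrations convert via the factors in :mod:`nadyn.constants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    CHARGE_FLUX_TO_CURRENT,
    CHARGE_TO_CONC,
    FARADAY,
    SURFACE_FLUX_TO_CONC,
    thermal_voltage,
)
from .morphology import Morphology, segment_geometry

__all__ = [
    "PumpSpec",
    "NCXSpec",
    "BufferSpec",
    "DiffusionSpec",
    "IonState",
    "accumulation_rate",
    "DiffusionOperator",
    "diffusion_step",
    "pump_current_steady_state",
    "pump_flux_steady_state",
    "pump_current_kinetic",
    "pump_occupancy_equilibrium",
    "ncx_current",
    "ca_balance_rate",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PumpSpec:
    """Two-reaction kinetic pump:

    ``pump + n ion_i <=>(k1, k2) pump.ion <=>(k3, k4) pump + n ion_o``

    *stoichiometry* n is the number of transported ions per cycle (3 for the
    Na+ leg of the Na+-K+ pump, 1 for the Ca2+ pump) and *charge_per_cycle*
    the net elementary charges moved outward per cycle (1 for Na+-K+ with its
    2 K+ countertransport, 2 for the Ca2+ pump).
    """

    k1: float  # 1/(mM^n ms)
    k2: float  # 1/ms
    k3: float  # 1/ms
    k4: float  # 1/(mM^n ms)
    total_density: float = 0.0  # mol/cm^2 (reference; may be overridden per segment)
    stoichiometry: int = 3
    charge_per_cycle: float = 1.0

    def __post_init__(self):
        if min(self.k1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("pump rate constants must be >= 0")
        if self.total_density < 0:
            raise ValueError("pump density must be >= 0")

    @property
    def equilibrium_ratio(self) -> float:
        """c_in/c_out ratio at which the steady-state current vanishes."""
        return (self.k2 * self.k4 / (self.k1 * self.k3)) ** (1.0 / self.stoichiometry)

    def with_equilibrium_scaled(self, factor: float) -> "PumpSpec":
        """Return a spec whose zero-current c_in is scaled by *factor*.

        Implemented by scaling k2*k4 (the reverse pathway); used for the
        distributed-input pump variant where the pump set point is lowered.
        """
        return replace(self, k2=self.k2 * factor**self.stoichiometry)


@dataclass(frozen=True)
class NCXSpec:
    """Na+-Ca2+ exchanger (3 Na+ : 1 Ca2+, Courtemanche formulation)."""

    i_max: float  # mA/cm^2
    gamma: float = 0.35
    km_na: float = 87.5  # mM
    km_ca: float = 1.38  # mM
    k_sat: float = 0.1
    electrogenic: bool = True

    def __post_init__(self):
        if self.i_max < 0:
            raise ValueError("i_max must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.k_sat < 0:
            raise ValueError("k_sat must be >= 0")


@dataclass(frozen=True)
class BufferSpec:
    """First-order Ca2+ buffer: Ca + B <=>(k_on, k_off) CaB."""

    total_buffer: float = 0.0  # mM
    k_on: float = 0.1  # 1/(mM ms)
    k_off: float = 0.01  # 1/ms

    def __post_init__(self):
        if min(self.total_buffer, self.k_on, self.k_off) < 0:
            raise ValueError("buffer parameters must be >= 0")


@dataclass(frozen=True)
class DiffusionSpec:
    """Longitudinal Na+ diffusion parameters.

    *spine_correction* applies a 10-fold reduction of D in dendritic regions,
    linearly approximating the hindrance of dendritic spines.
    """

    d_na: float = 0.3  # um^2/ms
    spine_correction: bool = False
    ca_diffusible: bool = False

    def __post_init__(self):
        if self.d_na <= 0:
            raise ValueError("D_Na must be positive")


@dataclass
class IonState:
    """Per-segment concentration state."""

    na_i: np.ndarray  # mM
    ca_i: np.ndarray  # mM
    bound_buffer: np.ndarray  # mM
    pump_na_occupancy: np.ndarray | None = None  # mol/cm^2 (kinetic mode)
    pump_ca_occupancy: np.ndarray | None = None

    def copy(self) -> "IonState":
        return IonState(
            self.na_i.copy(),
            self.ca_i.copy(),
            self.bound_buffer.copy(),
            None if self.pump_na_occupancy is None else self.pump_na_occupancy.copy(),
            None if self.pump_ca_occupancy is None else self.pump_ca_occupancy.copy(),
        )


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------


def accumulation_rate(i_ion: float, valence: int, volume: float):
    """Concentration rate (mM/ms) from an influx-positive point current.

    *i_ion* in nA (positive = ions entering), *volume* in um^3.  One nA of
    inward monovalent current into 1000 um^3 for 1 ms raises the
    concentration by ~1.0364e-2 mM.
    """
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("volume must be positive")
    out = np.asarray(i_ion, dtype=float) / (valence * FARADAY * volume) * CHARGE_TO_CONC
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


class DiffusionOperator:
    """Precomputed conservative flux-form diffusion on a morphology.

    Fluxes between adjacent segments j, k follow
    ``J = D_edge * (C_k - C_j) * A_cross / dx`` with dx the center-to-center
    distance and A_cross the smaller of the two cross sections.  Amounts
    (mM * um^3), not concentrations, are exchanged, so total ion content is
    conserved to machine precision.  The explicit update is automatically
    sub-stepped to stay within the stability bound.
    """

    def __init__(self, morph: Morphology, d_coeff: np.ndarray | float):
        n = len(morph)
        index = {s.id: i for i, s in enumerate(morph.segments)}
        self.volume = np.array([segment_geometry(s)[1] for s in morph.segments])
        d_arr = np.broadcast_to(np.asarray(d_coeff, dtype=float), (n,)).copy()
        src, dst, coef = [], [], []
        for s in morph.segments:
            if s.parent_id is None:
                continue
            p = morph[s.parent_id]
            j, k = index[s.id], index[p.id]
            a_cross = min(segment_geometry(s)[2], segment_geometry(p)[2])
            dx = 0.5 * (s.length + p.length)
            # series (harmonic) combination of the two segment coefficients
            dj, dk = d_arr[j], d_arr[k]
            d_edge = 2.0 * dj * dk / (dj + dk) if (dj + dk) > 0 else 0.0
            src.append(j)
            dst.append(k)
            coef.append(d_edge * a_cross / dx)  # um^3/ms
        self.src = np.array(src, dtype=int)
        self.dst = np.array(dst, dtype=int)
        self.coef = np.array(coef)
        if n > 1 and len(self.src) != n - 1:
            raise ValueError("morphology is disconnected")
        # stability: per-segment total rate (1/ms)
        rate = np.zeros(n)
        np.add.at(rate, self.src, self.coef / self.volume[self.src])
        np.add.at(rate, self.dst, self.coef / self.volume[self.dst])
        self.max_rate = float(rate.max()) if n > 1 else 0.0

    def step(self, conc: np.ndarray, dt: float) -> np.ndarray:
        """Advance concentrations by dt (ms); returns a new array."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self.src.size == 0:
            return conc.copy()
        nsub = max(1, int(math.ceil(dt * self.max_rate / 0.5)))
        h = dt / nsub
        c = conc.astype(float).copy()
        for _ in range(nsub):
            flux = self.coef * (c[self.dst] - c[self.src])  # mM um^3 / ms
            dm = flux * h
            np.subtract.at(c, self.dst, dm / self.volume[self.dst])
            np.add.at(c, self.src, dm / self.volume[self.src])
        return c


def diffusion_step(
    conc: np.ndarray, morph: Morphology, spec: DiffusionSpec, dt: float
) -> np.ndarray:
    """One-shot conservative diffusion update (see :class:`DiffusionOperator`)."""
    from .morphology import RegionTag

    d = np.full(len(morph), spec.d_na)
    if spec.spine_correction:
        dendritic = {
            RegionTag.DENDRITE_PROXIMAL,
            RegionTag.DENDRITE_DISTAL,
            RegionTag.TUFT,
        }
        mask = np.array([s.region in dendritic for s in morph.segments])
        d[mask] *= 0.1
    return DiffusionOperator(morph, d).step(np.asarray(conc, dtype=float), dt)


# ---------------------------------------------------------------------------
# pumps
# ---------------------------------------------------------------------------


def pump_flux_steady_state(c_in, c_out, spec: PumpSpec, density=None):
    """Outward molar ion flux (mol/cm^2/ms) at occupancy equilibrium."""
    dens = spec.total_density if density is None else density
    n = spec.stoichiometry
    ci = np.asarray(c_in, dtype=float) ** n
    co = float(c_out) ** n
    num = spec.k1 * spec.k3 * ci - spec.k2 * spec.k4 * co
    den = spec.k1 * ci + spec.k4 * co + spec.k2 + spec.k3
    return dens * num / den


def pump_current_steady_state(c_in, c_out, spec: PumpSpec, density=None):
    """Steady-state pump current density (mA/cm^2, outward positive).

    Closed form obtained by setting the occupancy derivative to zero:
    ``I = (F q / n) * [total] * (k1 k3 c_in^n - k2 k4 c_out^n) /
    (k1 c_in^n + k4 c_out^n + k2 + k3)`` with q the charge per cycle and n
    the stoichiometry; monotonically non-decreasing in c_in.
    """
    flux = pump_flux_steady_state(c_in, c_out, spec, density)
    out = (
        FARADAY
        * spec.charge_per_cycle
        / spec.stoichiometry
        * flux
        * CHARGE_FLUX_TO_CURRENT
    )
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def pump_occupancy_equilibrium(c_in, c_out, spec: PumpSpec, density=None):
    """Equilibrium loaded-state density (mol/cm^2) at fixed concentrations."""
    dens = spec.total_density if density is None else density
    n = spec.stoichiometry
    fwd = spec.k1 * np.asarray(c_in, dtype=float) ** n + spec.k4 * float(c_out) ** n
    return dens * fwd / (fwd + spec.k2 + spec.k3)


def pump_current_kinetic(
    occupancy, c_in, c_out, spec: PumpSpec, dt: float, density=None
):
    """Advance the loaded-state occupancy over dt and return (current, occupancy).

    The occupancy ODE is linear at frozen concentrations, so the exact
    exponential update is used.  The instantaneous current follows the
    forward/backward loading imbalance of the first reaction (times the
    charge factor), which equals the closed-form current at equilibrium.
    """
    dens = spec.total_density if density is None else density
    dens = np.asarray(dens, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    if np.any(occ < -1e-15) or np.any(occ - dens > 1e-12 * np.maximum(dens, 1e-30)):
        raise ValueError("pump occupancy out of [0, total_density]")
    n = spec.stoichiometry
    ci = np.asarray(c_in, dtype=float) ** n
    co = float(c_out) ** n
    fwd = spec.k1 * ci + spec.k4 * co  # loading rate (from free pump)
    rel = spec.k2 + spec.k3  # unloading rate
    occ_inf = dens * fwd / (fwd + rel)
    occ_new = occ_inf + (occ - occ_inf) * np.exp(-(fwd + rel) * dt)
    free = dens - occ_new
    # I = (F q / n) * (k1 [pump] c_in^n - k2 [pumpNa]) per unit area
    flux = spec.k1 * free * ci - spec.k2 * occ_new
    current = (
        FARADAY * spec.charge_per_cycle / n * flux * CHARGE_FLUX_TO_CURRENT
    )
    current = np.asarray(current)
    if current.ndim == 0:
        return float(current), float(occ_new)
    return current, occ_new


# ---------------------------------------------------------------------------
# Na+-Ca2+ exchanger
# ---------------------------------------------------------------------------


def ncx_current(na_i, na_o, ca_i, ca_o, v, temperature, spec: NCXSpec):
    """Na+-Ca2+ exchanger current density (mA/cm^2).

    Positive sign corresponds to Ca2+ influx / Na+ efflux (reverse mode);
    the exchanger reverses at ``V = 3 E_Na - 2 E_Ca``.  The same signed value
    is the outward-positive charge current when the exchanger is electrogenic
    (net one charge per cycle, moving with the 3 Na+).
    """
    na_i = np.asarray(na_i, dtype=float)
    ca_i = np.asarray(ca_i, dtype=float)
    if np.any(na_i < 0) or np.any(ca_i < 0):
        raise ValueError("concentrations must be non-negative")
    vt = thermal_voltage(temperature)
    v = np.asarray(v, dtype=float)
    e_g = np.exp(spec.gamma * v / vt)
    e_g1 = np.exp((spec.gamma - 1.0) * v / vt)
    num = na_i**3 * ca_o * e_g - na_o**3 * ca_i * e_g1
    den = (spec.km_na**3 + na_o**3) * (spec.km_ca + ca_o) * (1.0 + spec.k_sat * e_g1)
    out = spec.i_max * num / den
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Ca2+ balance
# ---------------------------------------------------------------------------


def ca_balance_rate(
    ca_i,
    na_i,
    v,
    *,
    na_o: float,
    ca_o: float,
    temperature: float,
    ncx: NCXSpec,
    ca_pump: PumpSpec,
    buffer: BufferSpec | None = None,
    bound_buffer=0.0,
    i_ca_channel=0.0,
    area_over_volume=1.0,
    ncx_density_scale=1.0,
    ca_pump_density=None,
):
    """Total d[Ca2+]/dt (mM/ms) for one compartment.

    Terms: NCX flux (entering as ``+I_NCX / F`` per the exchanger balance,
    converted by the membrane area / volume ratio, 1/um), minus the Ca2+
    pump flux, minus net buffering, minus the (outward-positive) voltage-
    gated Ca2+ channel current *i_ca_channel* (mA/cm^2) divided by 2F.
    """
    i_ncx = ncx_current(na_i, na_o, ca_i, ca_o, v, temperature, ncx) * ncx_density_scale
    rate = (i_ncx / FARADAY) * 1e-6 * area_over_volume * SURFACE_FLUX_TO_CONC
    pump_flux = pump_flux_steady_state(ca_i, ca_o, ca_pump, ca_pump_density)
    rate = rate - pump_flux * area_over_volume * SURFACE_FLUX_TO_CONC
    rate = rate - (
        np.asarray(i_ca_channel, dtype=float)
        / (2.0 * FARADAY)
        * 1e-6
        * area_over_volume
        * SURFACE_FLUX_TO_CONC
    )
    if buffer is not None and buffer.total_buffer > 0:
        free = buffer.total_buffer - np.asarray(bound_buffer, dtype=float)
        rate = rate - (
            buffer.k_on * np.asarray(ca_i, dtype=float) * free
            - buffer.k_off * np.asarray(bound_buffer, dtype=float)
        )
    out = np.asarray(rate)
    return float(out) if out.ndim == 0 else out
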