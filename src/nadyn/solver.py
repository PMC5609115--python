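"""Time integration of the coupled voltage / gating / concentration system.

The membrane potential is advanced with an implicit (backward Euler) solve of
the cable equation on the compartmental tree; gating variables use their
exact exponential update at frozen voltage; concentrations (Na+, Ca2+) are
advanced by first-order operator splitting after the voltage solve.  The
split is accurate because concentration time scales are seconds while the
voltage step is tens of microseconds.

The model assembly (:func:`build_model`) resolves a mechanism preset —
channel densities, pump/exchanger/buffer parameters, diffusion — onto a
morphology, producing per-segment parameter arrays.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets as presets_mod
from .constants import (
    CHARGE_FLUX_TO_CURRENT,
    DENSITY_TO_POINT,
    FARADAY,
    SURFACE_FLUX_TO_CONC,
    thermal_voltage,
)
from .ion_dynamics import (
    BufferSpec,
    DiffusionOperator,
    DiffusionSpec,
    IonState,
    NCXSpec,
    PumpSpec,
    ncx_current,
    pump_current_kinetic,
    pump_flux_steady_state,
    pump_occupancy_equilibrium,
)
from .membrane import ChannelSpec, nernst
from .morphology import Morphology, RegionTag, build_archetype, segment_geometry
from .stimuli import EventSchedule

__all__ = [
    "SolverConfig",
    "CellState",
    "Pulse",
    "VClamp",
    "Protocol",
    "Trace",
    "Model",
    "build_model",
    "step",
    "run_protocol",
    "NumericalError",
]

_DENDRITIC = (RegionTag.DENDRITE_PROXIMAL, RegionTag.DENDRITE_DISTAL, RegionTag.TUFT)


class NumericalError(RuntimeError):
    """Raised when the solver produces a non-finite state."""


@dataclass
class SolverConfig:
    dt: float = 0.025  # ms
    method: str = "backward_euler"
    record_every: int = 8
    check_charge_balance: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.method not in ("backward_euler", "crank_nicolson"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class Pulse:
    """A rectangular current pulse injected into one segment (nA)."""

    seg_id: int
    t_start: float
    width: float
    amplitude: float


@dataclass
class VClamp:
    """Piecewise-constant somatic voltage clamp."""

    seg_id: int
    times: np.ndarray  # step onset times, ms (first should be <= 0)
    levels: np.ndarray  # mV

    def level_at(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.levels[max(i, 0)])


@dataclass
class Protocol:
    """Everything delivered to the cell during a run."""

    duration: float  # ms
    pulses: list[Pulse] = field(default_factory=list)
    holding: dict[int, float] = field(default_factory=dict)  # seg_id -> nA
    events: EventSchedule | None = None
    vclamp: VClamp | None = None
    freeze_na: bool = False
    freeze_ca: bool = False


@dataclass
class CellState:
    """Full per-segment state: potential, gates, concentrations."""

    v: np.ndarray  # mV
    gates: dict[str, np.ndarray]  # "<channel>:<gate>" -> values in [0, 1]
    ions: IonState
    t: float = 0.0

    def copy(self) -> "CellState":
        return CellState(
            self.v.copy(),
            {k: g.copy() for k, g in self.gates.items()},
            self.ions.copy(),
            self.t,
        )


class Trace:
    """Recorded simulation output: time stamps x per-segment variables.

    Per-segment variables are (n_times, n_segments) arrays; global variables
    (e.g. the summed Na+ current) are 1-D.  The long-format table produced by
    :meth:`to_frame` has columns (time, segment, variable, value).
    """

    def __init__(self, t: np.ndarray, data: dict[str, np.ndarray], seg_ids, meta=None):
        self.t = t
        self.data = data
        self.seg_ids = np.asarray(seg_ids)
        self.meta = meta or {}
        self._col = {int(s): i for i, s in enumerate(self.seg_ids)}

    def get(self, var: str, seg_id: int | None = None) -> np.ndarray:
        arr = self.data[var]
        if arr.ndim == 1:
            return arr
        if seg_id is None:
            return arr
        if seg_id not in self._col:
            raise KeyError(f"segment {seg_id} was not recorded")
        return arr[:, self._col[seg_id]]

    def variables(self) -> list[str]:
        return sorted(self.data)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, arr in self.data.items():
            if arr.ndim == 1:
                rows.append(
                    pd.DataFrame(
                        {"time": self.t, "segment": -1, "variable": var, "value": arr}
                    )
                )
            else:
                for i, sid in enumerate(self.seg_ids):
                    rows.append(
                        pd.DataFrame(
                            {
                                "time": self.t,
                                "segment": int(sid),
                                "variable": var,
                                "value": arr[:, i],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# nadyn-trace meta={json.dumps(self.meta, sort_keys=True)}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        with open(path) as fh:
            header = fh.readline()
            meta = {}
            if header.startswith("# nadyn-trace"):
                meta = json.loads(header.split("meta=", 1)[1])
                frame = pd.read_csv(fh)
            else:
                fh.seek(0)
                frame = pd.read_csv(fh)
        t = np.array(sorted(frame["time"].unique()))
        seg_ids = sorted(s for s in frame["segment"].unique() if s >= 0)
        data: dict[str, np.ndarray] = {}
        for var, sub in frame.groupby("variable"):
            if (sub["segment"] < 0).all():
                data[var] = sub.sort_values("time")["value"].to_numpy()
            else:
                arr = np.empty((len(t), len(seg_ids)))
                for i, sid in enumerate(seg_ids):
                    arr[:, i] = (
                        sub[sub["segment"] == sid].sort_values("time")["value"].to_numpy()
                    )
                data[var] = arr
        return cls(t, data, np.array(seg_ids), meta)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


@dataclass
class _ChannelInstance:
    spec: ChannelSpec
    density: np.ndarray  # S/cm^2 (or cm/s for GHK channels)


class Model:
    """A morphology with resolved mechanism arrays, ready to simulate."""

    def __init__(self, morph: Morphology, preset: dict):
        self.morph = morph
        self.preset = preset
        n = len(morph)
        self.n = n
        segs = morph.segments
        self.seg_ids = np.array([s.id for s in segs])
        self.index = {s.id: i for i, s in enumerate(segs)}
        geom = [segment_geometry(s) for s in segs]
        self.area = np.array([g[0] for g in geom])  # um^2
        self.volume = np.array([g[1] for g in geom])  # um^3
        self.area_over_volume = self.area / self.volume  # 1/um
        self.parent = np.array(
            [self.index[s.parent_id] if s.parent_id is not None else -1 for s in segs]
        )
        self.regions = [s.region for s in segs]

        mem = preset["membrane"]
        cm_region = mem.get("c_m_per_region", {})
        cm = np.array(
            [float(cm_region.get(s.region.value, mem["c_m"])) for s in segs]
        )
        self.c_nF = cm * self.area * 1e-5
        self.ra = float(mem["Ra"])  # Ohm cm
        self.v_init = float(mem["v_init"])

        ions = preset["ions"]
        self.na_o = float(ions["na_o"])
        self.na_init = float(ions["na_i"])
        self.ca_o = float(ions["ca_o"])
        self.ca_init = float(ions.get("ca_i", 5e-5))
        self.e_k = float(ions["e_k"])
        self.temperature = float(preset.get("temperature", 310.15))

        # channels
        self.channels: list[_ChannelInstance] = []
        for entry in preset["channels"]:
            spec = presets_mod.channel_spec(entry["channel"], e_k=self.e_k)
            dens = np.zeros(n)
            for region, value in entry["gbar"].items():
                mask = [s.region.value == region for s in segs]
                dens[np.array(mask)] = float(value)
            self.channels.append(_ChannelInstance(spec, dens))
        hot = preset.get("ca_hot_zone")
        if hot:
            self._apply_hot_zone(hot)

        # pumps / exchanger / buffer / diffusion
        npump = preset["na_pump"]
        self.na_pump = PumpSpec(
            k1=npump["k1"], k2=npump["k2"], k3=npump["k3"], k4=npump["k4"],
            stoichiometry=3, charge_per_cycle=1.0,
        )
        if npump.get("equilibrium_scale"):
            self.na_pump = self.na_pump.with_equilibrium_scaled(
                float(npump["equilibrium_scale"])
            )
        self.na_pump_density = self._region_array(npump["density"])
        self.na_pump_mode = npump.get("mode", "steady_state")

        cpump = preset["ca_pump"]
        self.ca_pump = PumpSpec(
            k1=cpump["k1"], k2=cpump["k2"], k3=cpump["k3"], k4=cpump["k4"],
            stoichiometry=1, charge_per_cycle=float(cpump.get("charge_per_cycle", 2.0)),
        )
        self.ca_pump_density = self._region_array(cpump["density"])

        ncx = dict(preset["ncx"])
        scale = ncx.pop("density_scale", None)
        self.ncx = NCXSpec(**ncx)
        self.ncx_scale = (
            self._region_array(scale) if scale is not None else np.ones(n)
        )
        if preset.get("ncx_substitution"):
            # replace most Ca2+ pumping with exchange: I_max per segment is
            # the local Ca2+ pump density times 1e8 mA/mol, pump density /1e5
            self.ncx_scale = self.ca_pump_density * 1e8 / max(self.ncx.i_max, 1e-30)
            self.ca_pump_density = self.ca_pump_density / 1e5

        buf = preset.get("buffer", {})
        self.buffer = BufferSpec(**buf) if buf else BufferSpec(0.0)

        diff = preset.get("diffusion", {})
        self.diffusion_spec = DiffusionSpec(
            d_na=float(diff.get("d_na", 0.3)),
            spine_correction=bool(diff.get("spine_correction", False)),
        )
        d = np.full(n, self.diffusion_spec.d_na)
        if self.diffusion_spec.spine_correction:
            mask = np.array([s.region in _DENDRITIC for s in segs])
            d[mask] *= 0.1
        self.diffusion = DiffusionOperator(morph, d)
        self._rest_cache: dict[float, CellState] = {}

    # -- helpers -----------------------------------------------------------
    def _region_array(self, mapping: dict) -> np.ndarray:
        out = np.zeros(self.n)
        for region, value in mapping.items():
            mask = np.array([r.value == region for r in self.regions])
            out[mask] = float(value)
        return out

    def _apply_hot_zone(self, hot: dict):
        dist = float(hot["distance"])
        width = float(hot.get("width", 50.0))
        perm = float(hot["permeability"])
        for chan in self.channels:
            if chan.spec.ion != "Ca":
                continue
            for i, s in enumerate(self.morph.segments):
                if s.region in _DENDRITIC and abs(
                    self.morph.path_distance(s.id) - dist
                ) <= width:
                    chan.density[i] = perm

    def hot_zone_segments(self) -> list[int]:
        hot = self.preset.get("ca_hot_zone")
        if not hot:
            return []
        dist, width = float(hot["distance"]), float(hot.get("width", 50.0))
        return [
            s.id
            for s in self.morph.segments
            if s.region in _DENDRITIC
            and abs(self.morph.path_distance(s.id) - dist) <= width
        ]

    def e_na_rest(self) -> float:
        return nernst(self.na_init, self.na_o, 1, self.temperature)

    def stable_ca(self, na_i: float, v: float) -> float:
        """Baseline stable-state [Ca2+]i (pump/NCX balance; buffer neutral)."""
        from scipy.optimize import brentq

        if (
            self.ncx.i_max <= 0
            or not np.any(self.ncx_scale > 0)
            or not np.any(self.ca_pump_density > 0)
        ):
            return self.ca_init

        def balance(ca):
            i_ncx = ncx_current(
                na_i, self.na_o, ca, self.ca_o, v, self.temperature, self.ncx
            )
            flux_in = i_ncx * 1e-6 / FARADAY
            flux_out = pump_flux_steady_state(ca, self.ca_o, self.ca_pump, 1.0)
            # per-unit-density balance scaled by the (uniform) density ratio
            return flux_in * float(np.median(self.ncx_scale[self.ncx_scale > 0])) \
                - flux_out * float(np.median(self.ca_pump_density[self.ca_pump_density > 0]))

        lo, hi = 1e-9, self.ca_o
        try:
            return float(brentq(balance, lo, hi, xtol=1e-12, rtol=1e-12))
        except ValueError:
            return self.ca_init

    def initial_state(self, settle: float = 200.0) -> CellState:
        """Resting state: gates at steady state, then a settling run with
        frozen concentrations so the voltage relaxes to its fixed point."""
        key = round(settle, 6)
        if key in self._rest_cache:
            return self._rest_cache[key].copy()
        v = np.full(self.n, self.v_init)
        gates = {}
        for chan in self.channels:
            for gate in chan.spec.gates:
                inf, _ = gate.inf_tau(v)
                gates[f"{chan.spec.name}:{gate.name}"] = np.asarray(inf, dtype=float).copy()
        ca0 = self.stable_ca(self.na_init, self.v_init)
        kd = self.buffer.k_off / max(self.buffer.k_on, 1e-30)
        bound = self.buffer.total_buffer * ca0 / (ca0 + kd) if self.buffer.total_buffer else 0.0
        ions = IonState(
            na_i=np.full(self.n, self.na_init),
            ca_i=np.full(self.n, ca0),
            bound_buffer=np.full(self.n, bound),
        )
        if self.na_pump_mode == "kinetic":
            ions.pump_na_occupancy = np.asarray(
                pump_occupancy_equilibrium(
                    ions.na_i, self.na_o, self.na_pump, self.na_pump_density
                )
            )
        state = CellState(v, gates, ions, 0.0)
        if settle > 0:
            proto = Protocol(duration=settle, freeze_na=True, freeze_ca=True)
            engine = _Engine(self, proto, SolverConfig(dt=0.05, record_every=10**9))
            engine.bind(state)
            nsteps = int(round(settle / 0.05))
            for _ in range(nsteps):
                engine.advance(state)
            engine.sync(state)
            state.t = 0.0
        self._rest_cache[key] = state.copy()
        return state


def build_model(
    cell: str | Morphology,
    preset: str | dict | None = None,
    overrides: dict | None = None,
) -> Model:
    """Build a :class:`Model` from an archetype kind (or morphology) + preset.

    *preset* defaults to the archetype's standard preset name; *overrides*
    is a nested dict merged over the preset.
    """
    if isinstance(cell, Morphology):
        morph = cell
        if preset is None:
            raise ValueError("a preset is required when passing a raw morphology")
    else:
        morph = build_archetype(cell)
        if preset is None:
            preset = cell
    pdict = presets_mod.get_preset(preset) if isinstance(preset, str) else copy.deepcopy(preset)
    if overrides:
        pdict = presets_mod.merge_preset(pdict, overrides)
    return Model(morph, pdict)


# ---------------------------------------------------------------------------
# integration engine
# ---------------------------------------------------------------------------


class _Engine:
    """Per-run precomputation and the inner step loop.

    The engine trades generality for speed in the hot path: gate steady
    states and per-step decay factors are tabulated on a voltage grid, and
    the pump / exchanger / GHK expressions are inlined with precomputed unit
    factors.  The module-level operations in :mod:`nadyn.ion_dynamics` and
    :mod:`nadyn.membrane` remain the reference implementations; equivalence
    is covered by tests.
    """

    V_GRID = (-150.0, 100.0, 0.02)  # mV: lo, hi, step

    def __init__(self, model: Model, protocol: Protocol, cfg: SolverConfig):
        self.model = model
        self.protocol = protocol
        self.cfg = cfg
        n = model.n
        self.dt = dt = cfg.dt

        # --- axial conductances and constant matrix part -------------------
        g_ax = np.zeros(n)
        for i in range(n):
            p = model.parent[i]
            if p < 0:
                continue
            seg = model.morph.segments[i]
            par = model.morph.segments[p]
            a_i = math.pi * seg.diameter**2 / 4.0
            a_p = math.pi * par.diameter**2 / 4.0
            r_mohm = model.ra * 1e-2 * (
                seg.length / (2 * a_i) + par.length / (2 * a_p)
            )
            g_ax[i] = 1.0 / r_mohm  # uS
        self.g_ax = g_ax
        base = np.zeros((n, n))
        for i in range(n):
            p = model.parent[i]
            if p < 0:
                continue
            base[i, i] += g_ax[i]
            base[p, p] += g_ax[i]
            base[i, p] -= g_ax[i]
            base[p, i] -= g_ax[i]
        self.base_matrix = base
        self.diag = np.arange(n)
        self.c_over_dt = model.c_nF / dt  # nF/ms == nA/mV

        # --- gating tables -------------------------------------------------
        lo, hi, dv = self.V_GRID
        grid = np.arange(lo, hi + dv, dv)
        self.grid_lo, self.grid_dv, self.grid_n = lo, dv, grid.size
        self.gate_keys: list[str] = []
        gate_rows: dict[str, int] = {}
        tabs_inf, tabs_decay = [], []
        for chan in model.channels:
            for gate in chan.spec.gates:
                key = f"{chan.spec.name}:{gate.name}"
                if key not in gate_rows:
                    gate_rows[key] = len(self.gate_keys)
                    self.gate_keys.append(key)
                    inf, tau = gate.inf_tau(grid)
                    tabs_inf.append(np.asarray(inf, dtype=float))
                    tabs_decay.append(np.exp(-dt / np.asarray(tau, dtype=float)))
        self.tab_inf = np.array(tabs_inf) if tabs_inf else np.empty((0, grid.size))
        self.tab_decay = np.array(tabs_decay) if tabs_decay else np.empty((0, grid.size))

        # --- channel data --------------------------------------------------
        # ohmic channels: (g_full uS, gate rows+exponents, erev or None(=Na))
        self.ohmic: list[tuple[np.ndarray, list[tuple[int, int]], float | None]] = []
        # ghk channels: (permeability cm/s, gate rows+exponents)
        self.ghk: list[tuple[np.ndarray, list[tuple[int, int]]]] = []
        for chan in model.channels:
            spec = chan.spec
            rows = [
                (gate_rows[f"{spec.name}:{g.name}"], g.exponent) for g in spec.gates
            ]
            if spec.mode == "ghk":
                self.ghk.append((chan.density.copy(), rows))
            elif spec.mode == "nernst_dynamic":
                self.ohmic.append((chan.density * model.area * 1e-2, rows, None))
            else:
                self.ohmic.append((chan.density * model.area * 1e-2, rows, spec.erev))

        # --- precomputed unit factors --------------------------------------
        self.vt = thermal_voltage(model.temperature)
        self.area_pt = model.area * DENSITY_TO_POINT  # mA/cm^2 -> nA
        self.na_rate = 1e6 / (FARADAY * model.volume)  # nA -> mM/ms (z=1)
        self.ca_rate = 1e6 / (2.0 * FARADAY * model.volume)
        self.ghk_scale = 2.0 * FARADAY * 1e-3  # ghk prefactor (z=2, mM units)

        np_spec = model.na_pump
        self.np_dens = model.na_pump_density
        self.np_c_num1 = np_spec.k1 * np_spec.k3
        self.np_c_num2 = np_spec.k2 * np_spec.k4 * model.na_o**3
        self.np_c_den0 = np_spec.k4 * model.na_o**3 + np_spec.k2 + np_spec.k3
        self.np_k1 = np_spec.k1
        self.np_curr = FARADAY / 3.0 * CHARGE_FLUX_TO_CURRENT  # flux -> mA/cm^2

        cp = model.ca_pump
        self.cp_dens = model.ca_pump_density
        self.cp_num1 = cp.k1 * cp.k3
        self.cp_num2 = cp.k2 * cp.k4 * model.ca_o
        self.cp_den0 = cp.k4 * model.ca_o + cp.k2 + cp.k3
        self.cp_k1 = cp.k1
        self.cp_curr = FARADAY * cp.charge_per_cycle * CHARGE_FLUX_TO_CURRENT
        self.cp_conc = model.area_over_volume * SURFACE_FLUX_TO_CONC

        ncx = model.ncx
        self.ncx_pref = ncx.i_max * model.ncx_scale / (
            (ncx.km_na**3 + model.na_o**3) * (ncx.km_ca + model.ca_o)
        )
        self.ncx_gamma = ncx.gamma
        self.ncx_ksat = ncx.k_sat
        self.ncx_nao3 = model.na_o**3
        self.ncx_cao = model.ca_o
        self.ncx_electro = ncx.electrogenic

        buf = model.buffer
        self.buf_on = buf.k_on
        self.buf_off = buf.k_off
        self.buf_total = buf.total_buffer

        diff = model.diffusion
        self.dif_src, self.dif_dst, self.dif_coef = diff.src, diff.dst, diff.coef
        self.dif_vol = diff.volume
        self.dif_nsub = max(1, int(math.ceil(dt * diff.max_rate / 0.5)))

        # --- stimulus bookkeeping ------------------------------------------
        self.holding = np.zeros(n)
        for sid, amp in protocol.holding.items():
            self.holding[model.index[sid]] += amp
        pulses = protocol.pulses
        self.pulse_seg = np.array([model.index[p.seg_id] for p in pulses], dtype=int)
        self.pulse_t0 = np.array([p.t_start for p in pulses])
        self.pulse_t1 = np.array([p.t_start + p.width for p in pulses])
        self.pulse_amp = np.array([p.amplitude for p in pulses])

        ev = protocol.events
        if ev is not None and len(ev):
            self.ev_t = ev.times
            self.ev_seg = np.array([model.index[s] for s in ev.seg_ids], dtype=int)
            self.ev_gmax = ev.g_max * 1e-3  # nS -> uS
            self.ev_tau_on = ev.tau_onset
            self.ev_tau_off = ev.tau_offset
            self.ev_na_frac = ev.na_fraction
            tp = (
                np.log(self.ev_tau_off / self.ev_tau_on)
                * self.ev_tau_on
                * self.ev_tau_off
                / (self.ev_tau_off - self.ev_tau_on)
            )
            self.ev_norm = 1.0 / (
                np.exp(-tp / self.ev_tau_off) - np.exp(-tp / self.ev_tau_on)
            )
            self.ev_window = 12.0 * float(self.ev_tau_off.max())
        else:
            self.ev_t = np.empty(0)

        self.vclamp = protocol.vclamp
        self.clamp_idx = (
            model.index[self.vclamp.seg_id] if self.vclamp is not None else None
        )
        self.last_clamp_current = 0.0
        self.max_residual = 0.0
        self.integral_ina = 0.0  # nA ms, summed over segments
        self.integral_ipump = 0.0
        self.last_ina = np.zeros(n)
        self.last_ipump_nA = np.zeros(n)
        self.gmat: np.ndarray | None = None
        self._finite_check = 0

    # -- gate matrix binding ----------------------------------------------
    def bind(self, state: CellState) -> None:
        if self.gate_keys:
            self.gmat = np.array([state.gates[k] for k in self.gate_keys])
        else:
            self.gmat = np.empty((0, self.model.n))

    def sync(self, state: CellState) -> None:
        for row, key in enumerate(self.gate_keys):
            state.gates[key] = self.gmat[row].copy()

    # -- one step ----------------------------------------------------------
    def advance(self, state: CellState) -> None:
        model = self.model
        dt = self.dt
        t_new = state.t + dt
        v_old = state.v
        ions = state.ions
        na_i = ions.na_i
        ca_i = ions.ca_i

        e_na = self.vt * np.log(model.na_o / na_i)

        # 1. gating update at frozen (old) voltage, via tables
        if self.gate_keys:
            pos = (v_old - self.grid_lo) / self.grid_dv
            np.clip(pos, 0, self.grid_n - 2, out=pos)
            i0 = pos.astype(int)
            w = pos - i0
            inf = self.tab_inf[:, i0] * (1.0 - w) + self.tab_inf[:, i0 + 1] * w
            dec = self.tab_decay[:, i0] * (1.0 - w) + self.tab_decay[:, i0 + 1] * w
            self.gmat = inf + (self.gmat - inf) * dec
        gmat = self.gmat

        # 2. membrane conductances / constant currents
        g_diag = np.zeros(model.n)
        rhs_ge = np.zeros(model.n)
        i_const = np.zeros(model.n)  # nA, outward positive
        g_na_chan = np.zeros(model.n)
        for g_full, rows, erev in self.ohmic:
            g = g_full
            for row, expo in rows:
                g = g * gmat[row] ** expo
            g_diag += g
            if erev is None:
                rhs_ge += g * e_na
                g_na_chan += g
            else:
                rhs_ge += g * erev

        i_ca_ghk = np.zeros(model.n)  # nA, outward positive, at old voltage
        for dens, rows in self.ghk:
            popen = dens
            for row, expo in rows:
                popen = popen * gmat[row] ** expo
            xi = 2.0 * v_old / self.vt
            # GHK with z=2, concentrations in mM (1e-6 mol/cm^3)
            exi = np.exp(-xi)
            denom = 1.0 - exi
            small = np.abs(xi) < 1e-6
            safe = np.where(small, 1.0, denom)
            flux = np.where(
                small,
                ca_i - model.ca_o + xi * (ca_i + model.ca_o) / 2.0,
                xi * (ca_i - model.ca_o * exi) / safe,
            )
            i_ca_ghk += popen * self.ghk_scale * flux * self.area_pt

        i_const += i_ca_ghk

        # Na+-K+ pump (steady-state closed form, or kinetic occupancy mode)
        if model.na_pump_mode == "kinetic" and ions.pump_na_occupancy is not None:
            i_pump_dens, occ = pump_current_kinetic(
                ions.pump_na_occupancy, na_i, model.na_o, model.na_pump, dt,
                self.np_dens,
            )
            ions.pump_na_occupancy = np.asarray(occ)
            i_pump_dens = np.asarray(i_pump_dens)
        else:
            na3 = na_i**3
            flux = self.np_dens * (self.np_c_num1 * na3 - self.np_c_num2) / (
                self.np_k1 * na3 + self.np_c_den0
            )
            i_pump_dens = self.np_curr * flux
        i_pump_nA = i_pump_dens * self.area_pt
        i_const += i_pump_nA

        # Ca2+ pump (same scheme, stoichiometry 1, 2 charges/cycle)
        cp_flux = self.cp_dens * (self.cp_num1 * ca_i - self.cp_num2) / (
            self.cp_k1 * ca_i + self.cp_den0
        )
        i_const += self.cp_curr * cp_flux * self.area_pt

        # Na+-Ca2+ exchanger
        e_g = np.exp(self.ncx_gamma * v_old / self.vt)
        e_g1 = np.exp((self.ncx_gamma - 1.0) * v_old / self.vt)
        na3 = na_i**3
        i_ncx_dens = self.ncx_pref * (
            na3 * self.ncx_cao * e_g - self.ncx_nao3 * ca_i * e_g1
        ) / (1.0 + self.ncx_ksat * e_g1)
        i_ncx_nA = i_ncx_dens * self.area_pt
        if self.ncx_electro:
            i_const += i_ncx_nA

        # 3. synaptic conductances at t_new
        g_na_syn = np.zeros(model.n)
        g_k_syn = np.zeros(model.n)
        if self.ev_t.size:
            lo = int(np.searchsorted(self.ev_t, t_new - self.ev_window))
            hi = int(np.searchsorted(self.ev_t, t_new, side="right"))
            if hi > lo:
                dt_ev = t_new - self.ev_t[lo:hi]
                g_ev = (
                    self.ev_gmax[lo:hi]
                    * self.ev_norm[lo:hi]
                    * (
                        np.exp(-dt_ev / self.ev_tau_off[lo:hi])
                        - np.exp(-dt_ev / self.ev_tau_on[lo:hi])
                    )
                )
                segs = self.ev_seg[lo:hi]
                frac = self.ev_na_frac[lo:hi]
                np.add.at(g_na_syn, segs, g_ev * frac)
                np.add.at(g_k_syn, segs, g_ev * (1.0 - frac))
        g_diag_total = g_diag + g_na_syn + g_k_syn
        rhs_ge_total = rhs_ge + g_na_syn * e_na + g_k_syn * model.e_k

        # 4. injected currents at t_new
        i_inj = self.holding.copy()
        if self.pulse_seg.size:
            active = (self.pulse_t0 < t_new) & (t_new <= self.pulse_t1)
            if active.any():
                np.add.at(i_inj, self.pulse_seg[active], self.pulse_amp[active])

        # 5. implicit voltage solve on the tree
        mat = self.base_matrix.copy()
        mat[self.diag, self.diag] += self.c_over_dt + g_diag_total
        rhs = self.c_over_dt * v_old + rhs_ge_total - i_const + i_inj
        if self.clamp_idx is not None:
            c = self.clamp_idx
            mat[c, :] = 0.0
            mat[c, c] = 1.0
            rhs[c] = self.vclamp.level_at(t_new)
        v_new = np.linalg.solve(mat, rhs)
        self._finite_check += 1
        if self._finite_check >= 40 or self.clamp_idx is not None:
            self._finite_check = 0
            if not np.all(np.isfinite(v_new)):
                raise NumericalError(
                    f"solver diverged (non-finite voltage) at t={t_new} ms"
                )

        if self.cfg.check_charge_balance or self.clamp_idx is not None:
            i_mem = g_diag_total * v_new - rhs_ge_total + i_const  # nA outward
            i_ax = self.base_matrix @ v_new  # nA leaving each segment axially
            resid = self.c_over_dt * (v_new - v_old) + i_mem + i_ax - i_inj
            if self.clamp_idx is not None:
                self.last_clamp_current = float(resid[self.clamp_idx])
                resid = np.delete(resid, self.clamp_idx)
            if self.cfg.check_charge_balance and resid.size:
                scale = (
                    np.abs(self.c_over_dt * (v_new - v_old)).max()
                    + np.abs(i_mem).max()
                    + 1.0
                )
                self.max_residual = max(
                    self.max_residual, float(np.abs(resid).max() / scale)
                )

        # 6. concentration updates (first-order split after the voltage solve)
        i_na_nA = (g_na_chan + g_na_syn) * (v_new - e_na)  # nA outward
        self.last_ina = i_na_nA
        self.last_ipump_nA = i_pump_nA
        self.integral_ina += float(i_na_nA.sum()) * dt
        self.integral_ipump += float(i_pump_nA.sum()) * dt
        if not self.protocol.freeze_na:
            # influx (inward channel current) and 3 Na+ out per pump charge
            na = na_i - (i_na_nA + 3.0 * i_pump_nA) * self.na_rate * dt
            if self.dif_src.size:
                h = dt / self.dif_nsub
                for _ in range(self.dif_nsub):
                    dm = self.dif_coef * (na[self.dif_dst] - na[self.dif_src]) * h
                    np.subtract.at(na, self.dif_dst, dm / self.dif_vol[self.dif_dst])
                    np.add.at(na, self.dif_src, dm / self.dif_vol[self.dif_src])
            ions.na_i = np.maximum(na, 1e-3)

        if not self.protocol.freeze_ca:
            dca = (-i_ca_ghk * self.ca_rate + i_ncx_nA * self.na_rate) * dt
            dca -= cp_flux * self.cp_conc * dt
            if self.buf_total > 0:
                free = self.buf_total - ions.bound_buffer
                dbound = (
                    self.buf_on * ca_i * free - self.buf_off * ions.bound_buffer
                ) * dt
                np.clip(dbound, -ions.bound_buffer, free, out=dbound)
                ions.bound_buffer = ions.bound_buffer + dbound
                dca -= dbound
            ions.ca_i = np.maximum(ca_i + dca, 1e-9)

        state.v = v_new
        state.t = t_new


def step(state: CellState, model: Model, protocol: Protocol, t: float, dt: float) -> CellState:
    """Advance a copy of *state* by one step of size dt (public single-step op)."""
    new = state.copy()
    new.t = t
    engine = _Engine(model, protocol, SolverConfig(dt=dt))
    engine.bind(new)
    engine.advance(new)
    engine.sync(new)
    return new


_DEFAULT_RECORD = ("v", "na_i", "ca_i", "e_na", "i_pump", "ina_total")


def run_protocol(
    model: Model,
    protocol: Protocol,
    cfg: SolverConfig | None = None,
    record: tuple[str, ...] = _DEFAULT_RECORD,
    record_segments=None,
    seed: int = 0,
    initial_state: CellState | None = None,
    settle: float = 200.0,
) -> Trace:
    """Run a protocol and return a :class:`Trace`.

    Deterministic: all stochasticity lives in the stimulus generators, which
    take explicit seeds; two runs with identical model/protocol/config are
    bit-identical.
    """
    cfg = cfg or SolverConfig()
    state = initial_state.copy() if initial_state is not None else model.initial_state(settle)
    engine = _Engine(model, protocol, cfg)
    engine.bind(state)

    if record_segments is None:
        rec_idx = np.arange(model.n)
    else:
        missing = [s for s in record_segments if s not in model.index]
        if missing:
            raise KeyError(f"recording site(s) absent from morphology: {missing}")
        rec_idx = np.array([model.index[s] for s in record_segments], dtype=int)
    rec_ids = model.seg_ids[rec_idx]

    nsteps = int(round(protocol.duration / cfg.dt))
    nrec = nsteps // cfg.record_every + 1
    t_out = np.empty(nrec)
    bufs: dict[str, np.ndarray] = {}
    for var in record:
        if var in ("ina_total", "i_clamp"):
            bufs[var] = np.empty(nrec)
        else:
            bufs[var] = np.empty((nrec, rec_idx.size))

    def snapshot(k: int):
        t_out[k] = state.t
        for var in record:
            if var == "v":
                bufs[var][k] = state.v[rec_idx]
            elif var == "na_i":
                bufs[var][k] = state.ions.na_i[rec_idx]
            elif var == "ca_i":
                bufs[var][k] = state.ions.ca_i[rec_idx]
            elif var == "e_na":
                bufs[var][k] = nernst(
                    state.ions.na_i[rec_idx], model.na_o, 1, model.temperature
                )
            elif var == "i_pump":
                bufs[var][k] = engine.last_ipump_nA[rec_idx]
            elif var == "i_na":
                bufs[var][k] = engine.last_ina[rec_idx]
            elif var == "ina_total":
                bufs[var][k] = float(engine.last_ina.sum())
            elif var == "i_clamp":
                bufs[var][k] = engine.last_clamp_current
            else:
                raise KeyError(f"unknown recordable variable {var!r}")

    snapshot(0)
    k = 1
    for istep in range(1, nsteps + 1):
        engine.advance(state)
        if istep % cfg.record_every == 0:
            snapshot(k)
            k += 1
    meta = {
        "seed": seed,
        "dt": cfg.dt,
        "duration": protocol.duration,
        "freeze_na": protocol.freeze_na,
        "integral_ina": engine.integral_ina,
        "integral_ipump": engine.integral_ipump,
        "max_charge_residual": engine.max_residual,
    }
    meta["config_hash"] = hashlib.sha256(
        json.dumps(
            {k2: v for k2, v in meta.items() if k2 != "config_hash"}, sort_keys=True
        ).encode()
    ).hexdigest()[:16]
    return Trace(t_out[:k], {v: b[:k] for v, b in bufs.items()}, rec_ids, meta)
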