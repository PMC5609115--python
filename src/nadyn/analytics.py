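"""Derived quantities: spike metrics, sodium entry ratio, effective
capacitance, the E_Na / pump-current curves and the stable-state
[Ca2+]i([Na+]i) relationship.

The stable-state Ca2+ solver deliberately exposes two independent routes —
a symbolic closed form (generated once with sympy from the flux-balance
equation) and a bracketed numerical root-finder — that must agree; tests
exercise both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .constants import FARADAY, thermal_voltage
from .ion_dynamics import NCXSpec, PumpSpec, ncx_current, pump_flux_steady_state
from .membrane import nernst

__all__ = [
    "SpikeMetrics",
    "StableStateCurve",
    "detect_spikes",
    "spike_metrics",
    "effective_capacitance",
    "sodium_entry_ratio",
    "stable_state_ca",
    "stable_state_curve",
    "ena_curve",
    "pump_curve",
    "amplitude_series",
    "rate_histogram",
]


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


@dataclass
class SpikeMetrics:
    peak_times: np.ndarray  # ms
    peak_amplitudes: np.ndarray  # mV, baseline-to-peak
    peak_values: np.ndarray  # mV, absolute


def detect_spikes(
    t: np.ndarray, v: np.ndarray, threshold: float = 0.0, refractory: float = 1.0
) -> np.ndarray:
    """Indices of upward threshold crossings with a refractory period (ms)."""
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return crossings
    keep = [crossings[0]]
    for c in crossings[1:]:
        if t[c] - t[keep[-1]] >= refractory:
            keep.append(c)
    return np.array(keep)


def spike_metrics(
    t: np.ndarray,
    v: np.ndarray,
    threshold: float = 0.0,
    refractory: float = 1.0,
    baseline_window: float = 5.0,
) -> SpikeMetrics:
    """Per-spike peak time and baseline-to-peak amplitude.

    The baseline is the minimum of v over *baseline_window* ms preceding the
    threshold crossing; the peak is the maximum up to the next crossing.
    """
    idx = detect_spikes(t, v, threshold, refractory)
    if idx.size == 0:
        raise ValueError("no spikes detected in trace")
    bounds = list(idx) + [len(t)]
    times, amps, peaks = [], [], []
    for k, i0 in enumerate(idx):
        i1 = bounds[k + 1]
        seg = slice(i0, i1)
        ipk = i0 + int(np.argmax(v[seg]))
        pre = (t >= t[i0] - baseline_window) & (t < t[i0])
        baseline = float(v[pre].min()) if pre.any() else float(v[0])
        times.append(t[ipk])
        peaks.append(float(v[ipk]))
        amps.append(float(v[ipk]) - baseline)
    return SpikeMetrics(np.array(times), np.array(amps), np.array(peaks))


# ---------------------------------------------------------------------------
# effective capacitance and the sodium entry ratio
# ---------------------------------------------------------------------------


def effective_capacitance(
    model,
    v_hold_1: float = -80.0,
    v_hold_2: float = -75.0,
    settle_ms: float = 150.0,
    transient_ms: float = 150.0,
    dt: float = 0.01,
    remove_dendrites: bool = False,
) -> float:
    """Effective membrane capacitance (nF) by two-level somatic voltage clamp.

    The soma is clamped at the first holding potential until steady, stepped
    to the second, and the capacitance is the integral of the clamp-current
    transient (relative to its new steady level) divided by the voltage step.
    *remove_dendrites* drops all dendritic subtrees first (used for the
    purkinje-like cell whose dendritic load inflates the apparent value).
    """
    from .morphology import RegionTag
    from .solver import Model, Protocol, SolverConfig, VClamp, run_protocol

    if v_hold_1 == v_hold_2:
        raise ValueError("the two holding potentials must differ")
    if remove_dendrites:
        morph = model.morph.remove_regions(
            (RegionTag.DENDRITE_PROXIMAL, RegionTag.DENDRITE_DISTAL, RegionTag.TUFT)
        )
        model = Model(morph, model.preset)
    soma = model.morph.by_region(RegionTag.SOMA)[0].id
    clamp = VClamp(
        seg_id=soma,
        times=np.array([0.0, settle_ms]),
        levels=np.array([v_hold_1, v_hold_2]),
    )
    proto = Protocol(
        duration=settle_ms + transient_ms,
        vclamp=clamp,
        freeze_na=True,
        freeze_ca=True,
    )
    cfg = SolverConfig(dt=dt, record_every=1)
    trace = run_protocol(model, proto, cfg, record=("v", "i_clamp"))
    t, i_clamp = trace.t, trace.get("i_clamp")
    after = t > settle_ms
    tail = i_clamp[after]
    if tail.size < 10:
        raise RuntimeError("voltage clamp failed to converge (no post-step samples)")
    i_ss = float(np.mean(tail[-max(int(10.0 / dt), 1):]))
    if not np.isfinite(i_ss):
        raise RuntimeError("voltage clamp failed to converge")
    dq = float(np.sum((tail - i_ss)) * dt)  # nA ms = pC
    return abs(dq / (v_hold_2 - v_hold_1))  # pC/mV = nF


def sodium_entry_ratio(
    t: np.ndarray,
    v: np.ndarray,
    ina_total: np.ndarray,
    capacitance_nF: float,
    threshold: float = 0.0,
    tail_ms: float = 2.0,
    spike_index: int = 0,
) -> float:
    """Sodium entry ratio of one spike.

    Integral of |summed Na+ current| (nA) over the spike window — from the
    threshold crossing until the voltage falls back below threshold, plus a
    fixed 2 ms tail — divided by the minimal charge needed for the spike
    amplitude (amplitude x capacitance).  Equals 1 for a spike whose Na+
    influx exactly charges the capacitance with no overlapping K+ flux.
    """
    idx = detect_spikes(t, v, threshold)
    if idx.size == 0:
        raise ValueError("no spike found in the trace")
    if spike_index >= idx.size:
        raise ValueError(f"spike {spike_index} not found ({idx.size} detected)")
    i0 = idx[spike_index]
    after = np.flatnonzero(v[i0:] < threshold)
    i1 = i0 + (int(after[0]) if after.size else len(v) - i0 - 1)
    t_end = t[i1] + tail_ms
    window = (t >= t[i0]) & (t <= t_end)
    charge = float(np.trapezoid(np.abs(ina_total[window]), t[window]))  # nA ms = pC
    metrics = spike_metrics(t, v, threshold)
    amplitude = float(metrics.peak_amplitudes[spike_index])
    minimal = amplitude * capacitance_nF  # mV * nF = pC
    return charge / minimal


# ---------------------------------------------------------------------------
# stable-state calcium
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _stable_ca_closed_form():
    """Sympy-derived closed form of the flux balance, cached as a lambda.

    Balance (per unit area; the area/volume factor cancels):
    ``a_ncx * (c1 - c2*Ca) / d - T * (p1*Ca - p2) / (k1*Ca + q) = 0``
    which is quadratic in Ca; sympy picks the roots, we select the positive
    one inside (0, Ca_o).
    """
    import sympy as sp

    ca, a_ncx, c1, c2, d, tt, p1, p2, k1, q = sp.symbols(
        "ca a_ncx c1 c2 d tt p1 p2 k1 q", positive=True, real=True
    )
    expr = a_ncx * (c1 - c2 * ca) / d - tt * (p1 * ca - p2) / (k1 * ca + q)
    roots = sp.solve(sp.Eq(expr, 0), ca)
    fns = [
        sp.lambdify((a_ncx, c1, c2, d, tt, p1, p2, k1, q), r, "numpy") for r in roots
    ]
    return fns


def _balance_terms(na_i, v, temperature, na_o, ca_o, ncx: NCXSpec, ca_pump: PumpSpec,
                   ncx_scale, ca_pump_density):
    vt = thermal_voltage(temperature)
    e_g = math.exp(ncx.gamma * v / vt)
    e_g1 = math.exp((ncx.gamma - 1.0) * v / vt)
    c1 = na_i**3 * ca_o * e_g
    c2 = na_o**3 * e_g1
    d = (ncx.km_na**3 + na_o**3) * (ncx.km_ca + ca_o) * (1.0 + ncx.k_sat * e_g1)
    a_ncx = ncx.i_max * ncx_scale * 1e-6 / FARADAY  # current -> molar flux
    n = ca_pump.stoichiometry
    if n != 1:
        raise ValueError("closed form assumes a stoichiometry-1 Ca2+ pump")
    p1 = ca_pump.k1 * ca_pump.k3
    p2 = ca_pump.k2 * ca_pump.k4 * ca_o**n
    q = ca_pump.k4 * ca_o**n + ca_pump.k2 + ca_pump.k3
    tt = ca_pump.total_density if ca_pump_density is None else ca_pump_density
    return a_ncx, c1, c2, d, tt, p1, p2, ca_pump.k1, q


def stable_state_ca(
    na_i: float,
    v: float,
    temperature: float,
    ca_o: float,
    ncx: NCXSpec,
    ca_pump: PumpSpec,
    na_o: float = 150.0,
    ncx_scale: float = 1.0,
    ca_pump_density: float | None = None,
    method: str = "closed_form",
) -> float:
    """Stable-state [Ca2+]i (mM) at fixed [Na+]i: the root of the balance
    between Na+-Ca2+ exchange influx and Ca2+ pump extrusion.

    ``method='closed_form'`` evaluates the sympy-derived expression,
    ``method='brentq'`` brackets the root in [1e-9, Ca_o] mM.
    """
    args = _balance_terms(
        na_i, v, temperature, na_o, ca_o, ncx, ca_pump, ncx_scale, ca_pump_density
    )
    if method == "closed_form":
        candidates = []
        for fn in _stable_ca_closed_form():
            try:
                root = float(fn(*args))
            except (ZeroDivisionError, FloatingPointError):
                continue
            if np.isfinite(root) and 0.0 < root <= ca_o:
                candidates.append(root)
        if not candidates:
            raise ValueError("no positive stable-state root in (0, Ca_o]")
        return min(candidates)
    if method == "brentq":
        a_ncx, c1, c2, d, tt, p1, p2, k1, q = args

        def balance(ca):
            return a_ncx * (c1 - c2 * ca) / d - tt * (p1 * ca - p2) / (k1 * ca + q)

        lo, hi = 1e-9, ca_o
        if balance(lo) * balance(hi) > 0:
            raise ValueError(
                f"no positive root bracketed in [{lo}, {hi}] mM"
            )
        return float(brentq(balance, lo, hi, xtol=1e-15, rtol=1e-14))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class StableStateCurve:
    na_grid: np.ndarray  # mM
    ca_stable: np.ndarray  # mM
    params: dict


def stable_state_curve(
    na_grid,
    v: float,
    temperature: float,
    ca_o: float,
    ncx: NCXSpec,
    ca_pump: PumpSpec,
    na_o: float = 150.0,
    ncx_scale: float = 1.0,
    ca_pump_density: float | None = None,
    method: str = "closed_form",
) -> StableStateCurve:
    na_grid = np.asarray(na_grid, dtype=float)
    ca = np.array(
        [
            stable_state_ca(
                na, v, temperature, ca_o, ncx, ca_pump, na_o,
                ncx_scale, ca_pump_density, method,
            )
            for na in na_grid
        ]
    )
    return StableStateCurve(
        na_grid, ca,
        {"v": v, "temperature": temperature, "ca_o": ca_o, "na_o": na_o,
         "ncx_scale": ncx_scale},
    )


# ---------------------------------------------------------------------------
# curves and histograms
# ---------------------------------------------------------------------------


def ena_curve(na_grid, na_o: float = 150.0, temperature: float = 310.15):
    """E_Na (mV) over a grid of [Na+]i values (strictly decreasing, convex)."""
    na_grid = np.asarray(na_grid, dtype=float)
    return nernst(na_grid, na_o, 1, temperature)


def pump_curve(na_grid, spec: PumpSpec, na_o: float = 150.0, density=None):
    """Steady-state pump current density (mA/cm^2) over a [Na+]i grid."""
    from .ion_dynamics import pump_current_steady_state

    na_grid = np.asarray(na_grid, dtype=float)
    return pump_current_steady_state(na_grid, na_o, spec, density)


def amplitude_series(
    t: np.ndarray,
    v: np.ndarray,
    kind: str = "spike",
    event_times=None,
    baseline_ms: float = 5.0,
    threshold: float = 0.0,
) -> np.ndarray:
    """Event amplitudes normalized to the first event.

    ``kind='spike'`` detects spikes by threshold crossing; ``kind='epsp'``
    requires *event_times* and measures peak minus the mean voltage over the
    *baseline_ms* window preceding each event.
    """
    if kind == "spike":
        amps = spike_metrics(t, v, threshold).peak_amplitudes
    elif kind == "epsp":
        if event_times is None or len(event_times) == 0:
            raise ValueError("EPSP amplitude series requires event times")
        event_times = np.asarray(event_times, dtype=float)
        bounds = list(event_times) + [np.inf]
        amps = []
        for k, te in enumerate(event_times):
            pre = (t >= te - baseline_ms) & (t < te)
            win = (t >= te) & (t < min(bounds[k + 1], te + 200.0))
            if not pre.any() or not win.any():
                raise ValueError(f"event at t={te} ms outside the trace")
            amps.append(float(v[win].max() - v[pre].mean()))
        amps = np.array(amps)
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    if amps.size == 0:
        raise ValueError("no events found")
    return amps / amps[0]


def rate_histogram(
    spike_times, bin_width: float, t_max: float, n_runs: int = 1
):
    """Averaged firing-rate histogram in Hz.

    *spike_times*: flat array (ms) pooling all runs, or list of per-run
    arrays.  Returns (bin_edges_ms, rates_hz); rate = spikes per bin /
    bin width / n_runs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(spike_times, (list, tuple)):
        pooled = np.concatenate([np.asarray(s, dtype=float) for s in spike_times]) \
            if spike_times else np.empty(0)
        n_runs = len(spike_times) if spike_times else n_runs
    else:
        pooled = np.asarray(spike_times, dtype=float)
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    counts, _ = np.histogram(pooled, bins=edges)
    rates = counts / (bin_width / 1000.0) / max(n_runs, 1)
    return edges, rates
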