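"""Stimulus generation: current pulse trains, synaptic events and the
stochastic distributed ("cortical"/"thalamic") input generator.

Synaptic conductances are dual exponentials normalized so that the peak
equals ``g_max``.  Because the synapse reverses at +10 mV, between the K+
and Na+ equilibria, its conductance is split into a Na+ and a K+ component
at event creation (from the resting concentrations); the Na+ component is
what feeds intracellular Na+ accumulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import Morphology, RegionTag, segment_geometry

__all__ = [
    "SynapseSpec",
    "PulseTrainSpec",
    "DistributedInputSpec",
    "SynapticEvent",
    "EventSchedule",
    "dual_exp_conductance",
    "dual_exp_peak_time",
    "na_conductance_fraction",
    "split_synaptic_current",
    "make_synaptic_train",
    "make_climbing_fiber_event",
    "make_pulse_times",
    "make_distributed_input",
]

_DENDRITIC = (RegionTag.DENDRITE_PROXIMAL, RegionTag.DENDRITE_DISTAL, RegionTag.TUFT)


@dataclass(frozen=True)
class SynapseSpec:
    """Dual-exponential synapse parameters (defaults: AMPA/NMDA compromise)."""

    tau_onset: float = 0.5  # ms
    tau_offset: float = 10.0  # ms
    g_max: float = 5.0  # nS (peak)
    e_rev: float = 10.0  # mV
    target_segment: int | None = None

    def __post_init__(self):
        if not self.tau_onset < self.tau_offset:
            raise ValueError("tau_onset must be smaller than tau_offset")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")


@dataclass(frozen=True)
class PulseTrainSpec:
    """Repeated rectangular current pulses (amplitudes in nA, times in ms)."""

    frequency: float  # Hz
    duration: float  # ms (train length)
    pulse_amplitude: float  # nA
    pulse_width: float = 3.0  # ms
    holding_current: float = 0.0  # nA

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class DistributedInputSpec:
    """Stochastic distributed input: Poisson trains contacting the dendrites.

    "Cortical" trains are homogeneous Poisson at *rate_background*; "thalamic"
    trains add epochs at *rate_epoch* (piecewise-homogeneous Poisson) and
    place their contacts by a gamma(k, theta) path-distance distribution
    (denser proximally), optionally clustered (all contacts of a train on a
    single segment).
    """

    n_trains_cortical: int = 1000
    n_trains_thalamic: int = 1000
    rate_background: float = 1.0  # Hz
    rate_epoch: float = 5.0  # Hz
    epoch_windows: tuple = ()  # ((start_ms, duration_ms), ...)
    contacts_per_train: int = 5
    placement_k: float = 2.0
    placement_theta: float = 60.0  # um
    clustered: bool = True
    g_max: float = 0.5  # nS
    tau_onset: float = 0.5
    tau_offset: float = 15.0
    e_rev: float = 10.0

    def __post_init__(self):
        if self.rate_background < 0 or self.rate_epoch < 0:
            raise ValueError("rates must be >= 0")
        if self.contacts_per_train < 1:
            raise ValueError("contacts_per_train must be >= 1")


@dataclass(frozen=True)
class SynapticEvent:
    time: float  # ms
    seg_id: int
    g_max: float  # nS
    tau_onset: float
    tau_offset: float
    e_rev: float


def dual_exp_peak_time(tau_onset: float, tau_offset: float) -> float:
    """Time to peak of the dual exponential."""
    return (
        math.log(tau_offset / tau_onset)
        * tau_onset
        * tau_offset
        / (tau_offset - tau_onset)
    )


def dual_exp_conductance(t_since_event, spec: SynapseSpec):
    """Conductance (nS) at time *t_since_event* (ms) after the event.

    ``g(t) = g_max * N * (exp(-t/tau_off) - exp(-t/tau_on))`` for t >= 0 and
    zero before, with N chosen so the peak equals g_max.
    """
    tp = dual_exp_peak_time(spec.tau_onset, spec.tau_offset)
    norm = 1.0 / (math.exp(-tp / spec.tau_offset) - math.exp(-tp / spec.tau_onset))
    t = np.asarray(t_since_event, dtype=float)
    g = np.where(
        t < 0,
        0.0,
        spec.g_max
        * norm
        * (np.exp(-np.maximum(t, 0) / spec.tau_offset)
           - np.exp(-np.maximum(t, 0) / spec.tau_onset)),
    )
    return float(g) if g.ndim == 0 else g


def na_conductance_fraction(e_rev: float, e_na: float, e_k: float) -> float:
    """Fraction of a mixed Na+/K+ conductance carried by Na+.

    Solves ``g_Na (E_rev - E_Na) + g_K (E_rev - E_K) = 0`` for g_Na/g:
    ``(E_rev - E_K) / (E_Na - E_K)``.
    """
    if not (e_k < e_rev < e_na):
        raise ValueError("E_rev must lie strictly between E_K and E_Na")
    return (e_rev - e_k) / (e_na - e_k)


def split_synaptic_current(g: float, v: float, e_rev: float, e_na: float, e_k: float):
    """Split a synaptic conductance *g* (nS) into its Na+ and K+ currents (pA-scale
    consistent: returns nS*mV = pA*1e... with g in uS the result is nA).

    Returns (I_Na, I_K), each ``g_x * (V - E_x)`` with the conductance split
    fixed by the reversal condition at resting concentrations.
    """
    frac = na_conductance_fraction(e_rev, e_na, e_k)
    g_na = frac * g
    g_k = g - g_na
    return g_na * (v - e_na), g_k * (v - e_k)


class EventSchedule:
    """A flat, time-sorted collection of synaptic events with a fixed Na+
    conductance split (computed once from resting potentials)."""

    def __init__(self, events: list[SynapticEvent], e_na_rest: float, e_k: float):
        events = sorted(events, key=lambda e: e.time)
        self.times = np.array([e.time for e in events])
        self.seg_ids = np.array([e.seg_id for e in events], dtype=int)
        self.g_max = np.array([e.g_max for e in events])
        self.tau_onset = np.array([e.tau_onset for e in events])
        self.tau_offset = np.array([e.tau_offset for e in events])
        self.e_rev = np.array([e.e_rev for e in events])
        self.e_na_rest = e_na_rest
        self.e_k = e_k
        self.na_fraction = np.array(
            [na_conductance_fraction(e.e_rev, e_na_rest, e_k) for e in events]
        )

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "segment": self.seg_ids,
                "g_max": self.g_max,
                "tau_onset": self.tau_onset,
                "tau_offset": self.tau_offset,
                "e_rev": self.e_rev,
            }
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# nadyn-events e_na_rest={self.e_na_rest!r} e_k={self.e_k!r}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventSchedule":
        with open(path) as fh:
            header = fh.readline()
            parts = dict(
                kv.split("=") for kv in header.replace("# nadyn-events", "").split()
            )
            frame = pd.read_csv(fh)
        events = [
            SynapticEvent(
                float(r.time), int(r.segment), float(r.g_max),
                float(r.tau_onset), float(r.tau_offset), float(r.e_rev),
            )
            for r in frame.itertuples()
        ]
        return cls(events, float(parts["e_na_rest"]), float(parts["e_k"]))

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for arr in (self.times, self.seg_ids, self.g_max):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# deterministic generators
# ---------------------------------------------------------------------------


def make_pulse_times(frequency: float, duration: float, t_start: float = 0.0):
    """Pulse onset times (ms) of a regular train: *frequency* Hz for *duration* ms."""
    period = 1000.0 / frequency
    n = int(round(duration / period))
    return t_start + np.arange(n) * period


def make_synaptic_train(
    seg_id: int,
    rate: float,
    duration: float,
    spec: SynapseSpec,
    t_start: float = 0.0,
    probe_offsets: tuple = (),
) -> list[SynapticEvent]:
    """Regular synaptic train at *rate* Hz plus optional isolated probe events
    at the given offsets (ms) after the end of the train."""
    times = make_pulse_times(rate, duration, t_start)
    t_end = t_start + duration
    all_times = list(times) + [t_end + off for off in probe_offsets]
    return [
        SynapticEvent(
            float(t), seg_id, spec.g_max, spec.tau_onset, spec.tau_offset, spec.e_rev
        )
        for t in all_times
    ]


def make_climbing_fiber_event(
    morph: Morphology,
    t: float,
    total_g_max: float = 250.0,  # nS, summed over all target segments
    tau_onset: float = 0.5,
    tau_offset: float = 5.0,
    e_rev: float = 10.0,
    diameter_threshold: float = 2.2,  # um
) -> list[SynapticEvent]:
    """Concurrent input to every dendritic segment thicker than the threshold,
    with per-segment peaks distributed proportionally to membrane area and
    summing to *total_g_max*."""
    targets = [
        s
        for s in morph.segments
        if s.region in _DENDRITIC and s.diameter > diameter_threshold
    ]
    if not targets:
        warnings.warn(
            f"no dendritic segment thicker than {diameter_threshold} um; "
            "climbing-fiber event is empty",
            stacklevel=2,
        )
        return []
    areas = np.array([segment_geometry(s)[0] for s in targets])
    weights = areas / areas.sum()
    return [
        SynapticEvent(t, s.id, total_g_max * w, tau_onset, tau_offset, e_rev)
        for s, w in zip(targets, weights)
    ]


# ---------------------------------------------------------------------------
# stochastic distributed input
# ---------------------------------------------------------------------------


def _poisson_train(rng, rate_hz: float, duration_ms: float) -> np.ndarray:
    if rate_hz <= 0 or duration_ms <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def _piecewise_poisson(rng, spec: DistributedInputSpec, duration: float) -> np.ndarray:
    """Background rate everywhere, epoch rate inside the epoch windows."""
    pieces = []
    cursor = 0.0
    windows = sorted((float(a), float(b)) for a, b in spec.epoch_windows)
    for start, width in windows:
        if start < cursor or start + width > duration:
            raise ValueError(
                f"epoch window ({start}, {width}) outside the simulation span"
            )
        pieces.append(cursor + _poisson_train(rng, spec.rate_background, start - cursor))
        pieces.append(start + _poisson_train(rng, spec.rate_epoch, width))
        cursor = start + width
    pieces.append(cursor + _poisson_train(rng, spec.rate_background, duration - cursor))
    return np.sort(np.concatenate(pieces)) if pieces else np.empty(0)


def _dendrite_pool(morph: Morphology):
    segs = [s for s in morph.segments if s.region in _DENDRITIC]
    if not segs:
        raise ValueError("morphology has no dendritic segments")
    lengths = np.array([s.length for s in segs])
    dists = np.array([morph.path_distance(s.id) for s in segs])
    return segs, lengths, dists


def _gamma_site(rng, spec, dists, max_dist) -> int:
    """Index into the dendrite pool drawn by gamma path distance, truncated
    to the dendritic extent by resampling."""
    for _ in range(1000):
        x = rng.gamma(spec.placement_k, spec.placement_theta)
        if x <= max_dist:
            return int(np.argmin(np.abs(dists - x)))
    return int(np.argmin(dists))  # pathological spec; fall back to most proximal


def make_distributed_input(
    spec: DistributedInputSpec,
    morph: Morphology,
    duration: float,
    seed: int,
    e_na_rest: float = 70.0,
    e_k: float = -90.0,
) -> EventSchedule:
    """Build the full event schedule for the distributed-input protocol.

    Deterministic for a fixed (spec, morphology, seed).  Returns a schedule
    whose ``meta`` columns can be exported/imported as CSV for exact replay.
    """
    rng = np.random.default_rng(seed)
    segs, lengths, dists = _dendrite_pool(morph)
    max_dist = float(dists.max())
    p_uniform = lengths / lengths.sum()
    events: list[SynapticEvent] = []

    for _ in range(spec.n_trains_cortical):
        times = _poisson_train(rng, spec.rate_background, duration)
        sites = rng.choice(len(segs), size=spec.contacts_per_train, p=p_uniform)
        for t in times:
            for si in sites:
                events.append(
                    SynapticEvent(
                        float(t), segs[si].id, spec.g_max,
                        spec.tau_onset, spec.tau_offset, spec.e_rev,
                    )
                )

    for _ in range(spec.n_trains_thalamic):
        times = _piecewise_poisson(rng, spec, duration)
        if spec.clustered:
            site = _gamma_site(rng, spec, dists, max_dist)
            sites = [site] * spec.contacts_per_train
        else:
            sites = [
                _gamma_site(rng, spec, dists, max_dist)
                for _ in range(spec.contacts_per_train)
            ]
        for t in times:
            for si in sites:
                events.append(
                    SynapticEvent(
                        float(t), segs[si].id, spec.g_max,
                        spec.tau_onset, spec.tau_offset, spec.e_rev,
                    )
                )

    return EventSchedule(events, e_na_rest, e_k)
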