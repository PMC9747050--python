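"""Fixed-step network integrator with delayed synaptic delivery.

Forward Euler throughout, matching the single-neuron integrator.  Each
presynaptic spike schedules a conductance onset at t_spike + delta (rounded
up to the next step), scaled by the presynaptic depression state at spike
time.  Gap-junction currents use same-step (pre-update) voltages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .coupling import ChemicalSynapse, GapJunction, ThetaDrive
from .neuron import NeuronParams, NeuronState, BlowupError, rest_state, steady_state_gates

__all__ = [
    "NetworkSpec", "SpikeRaster", "run_network", "init_states",
    "limit_cycle_states", "population_spike_times", "population_frequency",
    "first_synchronous_event", "cycles_to_synchrony",
]


@dataclass
class NetworkSpec:
    population: list[NeuronParams]
    chem: list[ChemicalSynapse] = field(default_factory=list)
    gaps: list[GapJunction] = field(default_factory=list)
    drive: ThetaDrive = field(default_factory=ThetaDrive)
    std_enabled: bool = True
    i_app: float = 0.0

    def __post_init__(self):
        n = len(self.population)
        for s in self.chem:
            if not (0 <= s.pre < n and 0 <= s.post < n):
                raise ValueError("chemical synapse index out of range")
        for g in self.gaps:
            if not (0 <= g.i < n and 0 <= g.j < n):
                raise ValueError("gap junction index out of range")

    @property
    def n(self) -> int:
        return len(self.population)


@dataclass
class SpikeRaster:
    """Spike times and neuron ids for one simulation run."""
    times: np.ndarray      # ms, sorted
    neurons: np.ndarray    # int ids aligned with times
    n_neurons: int
    duration: float
    dt: float

    def __post_init__(self):
        order = np.argsort(self.times, kind="stable")
        self.times = np.asarray(self.times)[order]
        self.neurons = np.asarray(self.neurons)[order]

    def per_neuron(self) -> list[np.ndarray]:
        out = [self.times[self.neurons == i] for i in range(self.n_neurons)]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neurons, "t_ms": self.times})

    def write_csv(self, path, meta: dict | None = None):
        self.to_frame().to_csv(path, index=False)
        side = dict(n_neurons=self.n_neurons, duration_ms=self.duration, dt_ms=self.dt)
        side.update(meta or {})
        with open(str(path) + ".json", "w") as f:
            json.dump(side, f, indent=1)

    @classmethod
    def read_csv(cls, path, n_neurons, duration, dt):
        df = pd.read_csv(path)
        return cls(df["t_ms"].to_numpy(), df["neuron_id"].to_numpy(),
                   n_neurons, duration, dt)


def _pack_population(pop):
    n = len(pop)
    C = np.array([p.C_M for p in pop])
    gL = np.array([p.g_L for p in pop])
    EL = np.array([p.E_L for p in pop])
    gNa = np.array([p.g_Na for p in pop])
    gKv1 = np.array([p.g_Kv1 for p in pop])
    gKv3 = np.array([p.g_Kv3 for p in pop])
    kin = np.stack([p.kinetics_array() for p in pop])
    return C, gL, EL, gNa, gKv1, gKv3, kin


def _pack_chem(chem, n, dt):
    S = len(chem)
    post = np.zeros(S, np.int64)
    pre = np.zeros(S, np.int64)
    w = np.zeros(S)
    dsteps = np.ones(S, np.int64)
    for e, s in enumerate(chem):
        pre[e] = s.pre
        post[e] = s.post
        w[e] = s.g_syn
        dsteps[e] = max(1, int(np.ceil(s.delta / dt - 1e-9)))
    order = np.argsort(pre, kind="stable")
    pre, post, w, dsteps = pre[order], post[order], w[order], dsteps[order]
    out_ptr = np.zeros(n + 1, np.int64)
    np.add.at(out_ptr, pre + 1, 1)
    out_ptr = np.cumsum(out_ptr)
    out_idx = np.arange(S)
    return post, w, dsteps, out_ptr, out_idx


def _pack_gaps(gaps, n):
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for g in gaps:
        adj[g.i].append((g.j, g.g_gap))
        adj[g.j].append((g.i, g.g_gap))
    ptr = np.zeros(n + 1, np.int64)
    for i in range(n):
        ptr[i + 1] = ptr[i] + len(adj[i])
    idx = np.zeros(ptr[-1], np.int64)
    gv = np.zeros(ptr[-1])
    k = 0
    for i in range(n):
        for j, g in adj[i]:
            idx[k] = j
            gv[k] = g
            k += 1
    return ptr, idx, gv


def limit_cycle_states(params: NeuronParams, g_const: float, *, dt: float = 0.01,
                       settle: float = 200.0) -> np.ndarray:
    """States over one free-running cycle, starting at the -30 mV crossing.

    Settles from rest for `settle` ms at a constant ChR conductance, then
    records (V, m, h, n, a) at every step of one period.  Raises if the
    neuron is not firing repetitively at g_const.
    """
    from ._kernels import integrate_single
    y0 = rest_state(params).as_array()
    kin = params.kinetics_array()
    args = (kin, params.C_M, params.g_L, params.E_L, params.g_Na,
            params.g_Kv1, params.g_Kv3, 0.0, 0, g_const, 0.0, 0.0,
            -1.0, 0.0, -75.0, 2.0, 0.3)
    spikes, _, _, yf, status, step = integrate_single(
        y0, *args, settle, dt, 0, 1.0, 0, False)
    if status != _kernels.OK:
        raise BlowupError(step, dt)
    if len(spikes) < 5:
        raise ValueError("neuron does not fire repetitively at this drive")
    period = float(np.diff(spikes)[-3:].mean())
    # re-run a short stretch recording full state, then cut one cycle at a crossing
    spikes2, _, states, _, status, step = integrate_single(
        yf, *args, 3.0 * period, dt, 0, 1.0, 1, True)
    if status != _kernels.OK or len(spikes2) < 2:
        raise ValueError("failed to capture a full cycle")
    k0 = int(np.ceil(spikes2[0] / dt))
    k1 = k0 + int(round(period / dt))
    if k1 > states.shape[0]:
        raise ValueError("cycle capture window too short")
    return states[k0:k1]


def init_states(spec: NetworkSpec, mode: str = "random", seed=None,
                *, phase_offsets=None, custom=None) -> np.ndarray:
    """Initial (n, 5) state array.

    random: independent uniform phases on the free-running limit cycle at
    the drive's constant value (or its midpoint for a sinusoidal drive).
    on_cycle: all neurons at the threshold crossing, with optional
    per-neuron phase offsets (fractions of the period).
    custom: caller-supplied (n, 5) array.
    rest: every neuron at its own resting state.
    """
    n = spec.n
    if mode == "custom":
        if custom is None or np.shape(custom) != (n, 5):
            raise ValueError("custom init requires an (n, 5) state array")
        return np.array(custom, dtype=float)
    if mode == "rest":
        states = []
        for p in spec.population:
            try:
                states.append(rest_state(p).as_array())
            except ValueError:
                # gap-compensated cells can lack an isolated subthreshold
                # rest (their E_L absorbs the gap-current correction); any
                # subthreshold start works since transients are discarded
                g = steady_state_gates(-65.0, p)
                states.append(np.array([-65.0, *g]))
        return np.stack(states)
    g_const = (spec.drive.g_const if spec.drive.mode == "constant"
               else 0.5 * spec.drive.g_max)
    cycle = limit_cycle_states(spec.population[0], g_const)
    nper = cycle.shape[0]
    if mode == "random":
        rng = np.random.default_rng(seed)
        ph = rng.integers(0, nper, size=n)
        return cycle[ph].copy()
    if mode == "on_cycle":
        if phase_offsets is None:
            phase_offsets = np.zeros(n)
        idx = (np.asarray(phase_offsets) * nper).astype(int) % nper
        return cycle[idx].copy()
    raise ValueError(f"unknown init mode {mode!r}")


def run_network(spec: NetworkSpec, duration: float, dt: float, *,
                init: np.ndarray, record_traces=None, trace_stride: int = 1,
                lockout: float = 1.0):
    """Simulate the network; returns (SpikeRaster, traces or None).

    init is an (n, 5) state array (see init_states).  record_traces is an
    optional sequence of neuron indices whose V is recorded every
    trace_stride steps.
    """
    n = spec.n
    C, gL, EL, gNa, gKv1, gKv3, kin = _pack_population(spec.population)
    if spec.chem:
        post, w, dsteps, out_ptr, out_idx = _pack_chem(spec.chem, n, dt)
        esyn = spec.chem[0].E_syn
        tau1, tau2 = spec.chem[0].tau1, spec.chem[0].tau2
        tau_r, u_se = spec.chem[0].tau_r, spec.chem[0].U_SE
    else:
        post = np.zeros(0, np.int64)
        w = np.zeros(0)
        dsteps = np.ones(0, np.int64)
        out_ptr = np.zeros(n + 1, np.int64)
        out_idx = np.zeros(0, np.int64)
        esyn, tau1, tau2, tau_r, u_se = -75.0, 2.0, 0.3, 100.0, 0.3
    gap_ptr, gap_idx, gap_g = _pack_gaps(spec.gaps, n)
    drive = spec.drive
    mode = 0 if drive.mode == "constant" else 1
    init = np.asarray(init, dtype=float)
    if init.shape != (n, 5):
        raise ValueError("init must be an (n, 5) state array")
    V = init[:, 0].copy()
    m = init[:, 1].copy()
    h = init[:, 2].copy()
    ngate = init[:, 3].copy()
    agate = init[:, 4].copy()
    rec_idx = (np.asarray(record_traces, np.int64)
               if record_traces is not None else np.zeros(0, np.int64))
    iapp = np.full(n, spec.i_app)
    sp_t, sp_i, traces, x_final, status, step = _kernels.integrate_network(
        V, m, h, ngate, agate, kin, C, gL, EL, gNa, gKv1, gKv3,
        post, w, dsteps, out_ptr, out_idx,
        esyn, tau1, tau2,
        spec.std_enabled, 1.0, tau_r, u_se,
        gap_ptr, gap_idx, gap_g,
        mode, drive.g_const, drive.g_max, drive.f, iapp,
        duration, dt, lockout,
        rec_idx, trace_stride if rec_idx.size else 0)
    if status == _kernels.BLOWUP:
        raise BlowupError(step, dt)
    if status == _kernels.SPIKE_OVERFLOW:
        raise RuntimeError(f"spike buffer overflow at step {step}")
    raster = SpikeRaster(sp_t, sp_i, n, duration, dt)
    return raster, (traces if rec_idx.size else None)


def population_spike_times(raster: SpikeRaster, *, bin_ms: float = 0.1,
                           frac: float = 0.5) -> np.ndarray:
    """Times of population spikes: peaks of the 0.1 ms-binned spike histogram
    exceeding frac * n_neurons."""
    edges = np.arange(0.0, raster.duration + bin_ms, bin_ms)
    counts, _ = np.histogram(raster.times, edges)
    thr = frac * raster.n_neurons
    pk = []
    for k in range(1, len(counts) - 1):
        if counts[k] >= thr and counts[k] >= counts[k - 1] and counts[k] > counts[k + 1]:
            pk.append(edges[k] + 0.5 * bin_ms)
    return np.array(pk)


def population_frequency(raster: SpikeRaster, *, skip: float = 50.0,
                         bin_ms: float = 0.1, frac: float = 0.5) -> float:
    """Median inverse interval between successive population spikes (Hz).

    Transients before `skip` ms are excluded.  Returns nan when fewer than
    three population spikes remain (no sustained population rhythm).
    """
    pk = population_spike_times(raster, bin_ms=bin_ms, frac=frac)
    pk = pk[pk >= skip]
    if pk.size < 3:
        return float("nan")
    return float(np.median(1000.0 / np.diff(pk)))


def first_synchronous_event(raster: SpikeRaster, *, window: float = 1.0,
                            min_neurons: int | None = None) -> float | None:
    """Time of the first window containing spikes of >= min_neurons distinct
    neurons (default n-1, the '99 of 100' criterion), or None."""
    if min_neurons is None:
        min_neurons = raster.n_neurons - 1
    t = raster.times
    ids = raster.neurons
    j0 = 0
    for j in range(t.size):
        while t[j] - t[j0] > window:
            j0 += 1
        if j - j0 + 1 >= min_neurons and np.unique(ids[j0:j + 1]).size >= min_neurons:
            return float(t[j])
    return None


def max_coincident(raster: SpikeRaster, *, t_start: float = 0.0,
                   t_stop: float | None = None, window: float = 1.0) -> int:
    """Largest number of distinct neurons spiking within any `window` ms
    interval between t_start and t_stop."""
    t_stop = raster.duration if t_stop is None else t_stop
    sel = (raster.times >= t_start) & (raster.times < t_stop)
    t = raster.times[sel]
    ids = raster.neurons[sel]
    best = 0
    j0 = 0
    for j in range(t.size):
        while t[j] - t[j0] > window:
            j0 += 1
        if j - j0 + 1 > best:
            best = max(best, int(np.unique(ids[j0:j + 1]).size))
    return best


def cycles_to_synchrony(raster: SpikeRaster, *, window: float = 1.0,
                        min_neurons: int | None = None) -> int | None:
    """Population spikes elapsed before the first synchronous event.

    Returns None when the network never reaches the synchrony criterion
    (>= min_neurons distinct neurons within `window` ms).
    """
    t_sync = first_synchronous_event(raster, window=window, min_neurons=min_neurons)
    if t_sync is None:
        return None
    pk = population_spike_times(raster, frac=0.2)
    return int(np.sum(pk < t_sync - 0.5 * window))
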