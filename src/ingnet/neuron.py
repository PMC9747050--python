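"""Single-compartment fast-spiking interneuron model.

The cell carries a transient sodium current (m^3 h), a slowly activating
Kv1-type delayed rectifier (a^4), a fast Kv3-type delayed rectifier (n^4)
and an ohmic leak:

    C_M dV/dt = I_app + g_Na m^3 h (E_Na - V) + g_Kv1 a^4 (E_K - V)
              + g_Kv3 n^4 (E_K - V) + g_L (E_L - V) + (synaptic/drive terms)

with E_Na = 50 mV and E_K = -90 mV; every conductance drives V toward its
own reversal potential.  Activation gates follow dx/dt = a(V)(1-x) - b(V)x
with a(V) = k1(th-V)/(exp((th-V)/s1)-1) and b(V) = k2 exp(V/s2).  The
inactivation gate h follows dh/dt = b(V)(1-h) - a(V)h where the (k, sigma)
pairs attach to the opposite functional forms: opening b_h = k1 exp(V/s1)
and closing a_h = k2(th_h-V)/(exp((th_h-V)/s2)-1), which is positive for
all V.  This is the only role assignment under which both h rates are
admissible (positive), h is high at rest and low during the spike, and the
model fires tonically rather than latching into depolarization block; it
reproduces the anchored free-running behavior (168 Hz / 5.97 ms period at
a constant 7 nS channelrhodopsin conductance) to printed precision.

Units: mV, ms, nS, pA, pF throughout (nS*mV = pA, pA/pF = mV/ms).

This neuron is type 2 excitable: below an abrupt cutoff frequency it cannot
sustain repetitive firing, and near rheobase it may emit a few spikes and
then fall silent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from ._kernels import integrate_single

__all__ = [
    "GateKinetics", "NeuronParams", "NeuronState", "APFeatures",
    "TABLE_KINETICS", "FIG3_NEURON", "SPIKE_THRESHOLD",
    "gate_rates", "state_derivatives", "steady_state_gates",
    "resting_potential", "simulate_neuron", "spike_features", "fI_curve",
]

SPIKE_THRESHOLD = -30.0  # mV; phase zero / spike detection threshold
SPIKE_LOCKOUT = 1.0      # ms; minimum inter-event interval
E_NA = _kernels.ENA
E_K = _kernels.EK


@dataclass(frozen=True)
class GateKinetics:
    """Voltage-dependent rate parameters for one gating variable."""
    theta: float   # half-point voltage of the singular rate branch (mV)
    sigma1: float  # slope factor of the alpha branch (mV)
    sigma2: float  # slope factor of the beta branch (mV)
    k1: float      # alpha rate scale (1/ms)
    k2: float      # beta rate scale (1/ms)
    role: str = "activation"  # "activation" | "inactivation"

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("rate scales k1, k2 must be positive")
        if self.sigma1 == 0 or self.sigma2 == 0:
            raise ValueError("slope factors must be nonzero")

    def as_row(self) -> np.ndarray:
        return np.array([self.theta, self.sigma1, self.sigma2, self.k1, self.k2])


# Kinetic constants shared by all model neurons; the theta values are the
# homogeneous-network reference and are varied per neuron when building
# heterogeneous populations.
TABLE_KINETICS = {
    "m": GateKinetics(-53.0, 4.0, -13.0, 0.25, 0.1),
    "h": GateKinetics(-55.71, -20.0, 3.5, 0.012, 0.2, role="inactivation"),
    "n": GateKinetics(5.9, 12.0, -8.5, 1.0, 0.001),
    "a": GateKinetics(51.36, 12.0, -80.0, 1.0, 0.02),
}

_GATES = ("m", "h", "n", "a")


@dataclass(frozen=True)
class NeuronParams:
    """Complete passive + active parameter vector for one model cell."""
    C_M: float    # capacitance (pF)
    g_L: float    # leak conductance (nS)
    E_L: float    # leak reversal (mV)
    g_Na: float   # peak Na conductance (nS)
    g_Kv1: float  # peak Kv1 conductance (nS)
    g_Kv3: float  # peak Kv3 conductance (nS)
    kinetics_m: GateKinetics = TABLE_KINETICS["m"]
    kinetics_h: GateKinetics = TABLE_KINETICS["h"]
    kinetics_n: GateKinetics = TABLE_KINETICS["n"]
    kinetics_a: GateKinetics = TABLE_KINETICS["a"]
    E_Na: float = E_NA
    E_K: float = E_K

    def __post_init__(self):
        if self.C_M <= 0:
            raise ValueError("C_M must be positive")
        for name in ("g_L", "g_Na", "g_Kv1", "g_Kv3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def kinetics_array(self) -> np.ndarray:
        """(4, 5) array in gate order m, h, n, a."""
        return np.vstack([
            self.kinetics_m.as_row(), self.kinetics_h.as_row(),
            self.kinetics_n.as_row(), self.kinetics_a.as_row(),
        ])

    def with_thetas(self, theta_m, theta_h, theta_n, theta_a) -> "NeuronParams":
        from dataclasses import replace
        return NeuronParams(
            self.C_M, self.g_L, self.E_L, self.g_Na, self.g_Kv1, self.g_Kv3,
            replace(self.kinetics_m, theta=theta_m),
            replace(self.kinetics_h, theta=theta_h),
            replace(self.kinetics_n, theta=theta_n),
            replace(self.kinetics_a, theta=theta_a),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))


# Representative neuron (homogeneous-network reference): input resistance
# 68 MOhm, membrane time constant 5.22 ms, table kinetics.
FIG3_NEURON = NeuronParams(
    C_M=76.8, g_L=14.7, E_L=-72.0,
    g_Na=16805.0, g_Kv1=59.0, g_Kv3=631.7,
)


@dataclass
class NeuronState:
    """Dynamical state (V, m, h, n, a)."""
    V: float
    m: float
    h: float
    n: float
    a: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n, self.a])

    @classmethod
    def from_array(cls, y) -> "NeuronState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class APFeatures:
    """Threshold-referenced action-potential features.

    amplitude_above_threshold: peak V minus the -30 mV threshold (mV)
    half_width: time spent above the threshold/peak midpoint (ms)
    ahp_depth: threshold minus the post-spike minimum (mV)
    """
    amplitude_above_threshold: float
    half_width: float
    ahp_depth: float
    threshold_voltage: float = SPIKE_THRESHOLD


def gate_rates(V: float, kin: GateKinetics) -> tuple[float, float]:
    """Voltage-dependent (opening, closing) rates in 1/ms.

    For activation gates the opening rate is the singular-form alpha and the
    closing rate the exponential beta.  For the inactivation gate the pairs
    swap functional forms (see module docstring); both returned rates are
    admissible (positive).  At the removable singularity u = 0 the limit
    k*sigma is used.
    """
    if not math.isfinite(V):
        raise ValueError("membrane potential must be finite")
    if kin.role == "inactivation":
        opening = kin.k1 * math.exp(V / kin.sigma1)
        closing = _singular(kin.theta - V, kin.sigma2, kin.k2)
    else:
        opening = _singular(kin.theta - V, kin.sigma1, kin.k1)
        closing = kin.k2 * math.exp(V / kin.sigma2)
    return opening, closing


def _singular(u: float, sigma: float, k: float) -> float:
    x = u / sigma
    if abs(x) < 1e-12:
        return k * sigma
    return k * u / (math.expm1(x))


def state_derivatives(state: NeuronState, params: NeuronParams,
                      extra_current: float = 0.0) -> np.ndarray:
    """Time derivatives (dV, dm, dh, dn, da) of the five state variables.

    extra_current is the total non-intrinsic current in pA (applied current
    plus any synaptic/gap/drive current already evaluated at this state).
    """
    V = state.V
    I = extra_current
    I += params.g_Na * state.m ** 3 * state.h * (params.E_Na - V)
    I += params.g_Kv1 * state.a ** 4 * (params.E_K - V)
    I += params.g_Kv3 * state.n ** 4 * (params.E_K - V)
    I += params.g_L * (params.E_L - V)
    d = np.empty(5)
    d[0] = I / params.C_M
    for j, name in enumerate(_GATES):
        kin = getattr(params, f"kinetics_{name}")
        x = getattr(state, name)
        op, cl = gate_rates(V, kin)
        d[1 + j] = op * (1.0 - x) - cl * x
    return d


def steady_state_gates(V: float, params: NeuronParams) -> np.ndarray:
    """Equilibrium gate values (m, h, n, a) at a clamped voltage."""
    out = np.empty(4)
    for j, name in enumerate(_GATES):
        op, cl = gate_rates(V, getattr(params, f"kinetics_{name}"))
        out[j] = op / (op + cl)
    return out


def rest_state(params: NeuronParams, V: float | None = None) -> NeuronState:
    """State with gates at equilibrium; V defaults to the resting potential."""
    if V is None:
        V = resting_potential(params)
    g = steady_state_gates(V, params)
    return NeuronState(V, *g)


def resting_potential(params: NeuronParams, extra_g: float = 0.0,
                      extra_E: float = 0.0) -> float:
    """Resting potential from the steady-state current balance.

    Optionally includes a constant extra conductance (e.g. a ChR drive or
    gap-junction load) with reversal extra_E.  Solved by bisection (brentq).
    """
    from scipy.optimize import brentq

    def f(V):
        g = steady_state_gates(V, params)
        s = NeuronState(V, *g)
        return state_derivatives(s, params, extra_g * (extra_E - V))[0]

    lo, hi = -95.0, SPIKE_THRESHOLD - 5.0
    if f(lo) * f(hi) > 0:  # no subthreshold rest (neuron fires tonically)
        raise ValueError("no subthreshold resting potential in [-95, -35] mV")
    return float(brentq(f, lo, hi, xtol=1e-6))


class BlowupError(RuntimeError):
    """Numerical blow-up (|V| > 200 mV) naming the offending step."""

    def __init__(self, step: int, dt: float):
        super().__init__(f"membrane potential diverged at step {step} (t = {step * dt:.4f} ms)")
        self.step = step


def simulate_neuron(params: NeuronParams, *, duration: float, dt: float = 0.01,
                    i_app: float = 0.0, g_chr: float = 0.0,
                    drive=None, method: str = "euler",
                    init: NeuronState | None = None,
                    record: bool = True,
                    pert_t: float = -1.0, pert_g: float = 0.0,
                    pert_E: float = -75.0, pert_tau1: float = 2.0,
                    pert_tau2: float = 0.3):
    """Integrate a single neuron and detect spikes.

    drive may be a ThetaDrive (sinusoidally modulated ChR conductance); if
    None, a constant conductance g_chr and/or applied current i_app is used.
    Spikes are logged at upward crossings of -30 mV with a 1 ms lockout; the
    crossing time is linearly interpolated inside the step.

    Returns (t, V, spike_times, final_state); t and V are None when
    record=False.
    """
    if dt <= 0 or duration <= dt:
        raise ValueError("need dt > 0 and duration > dt")
    if method not in ("euler", "rk4"):
        raise ValueError("method must be 'euler' or 'rk4'")
    if drive is not None:
        mode, g0, gmax, freq = 1, 0.0, drive.g_max, drive.f
        if getattr(drive, "mode", "sinusoidal") == "constant":
            mode, g0 = 0, drive.g_const
    else:
        mode, g0, gmax, freq = 0, g_chr, 0.0, 0.0
    y0 = (init or rest_state(params)).as_array()
    spikes, trace, _, yf, status, step = integrate_single(
        y0, params.kinetics_array(), params.C_M, params.g_L, params.E_L,
        params.g_Na, params.g_Kv1, params.g_Kv3,
        i_app, mode, g0, gmax, freq,
        pert_t, pert_g, pert_E, pert_tau1, pert_tau2,
        duration, dt, 0 if method == "euler" else 1, SPIKE_LOCKOUT,
        1 if record else 0, False)
    if status == _kernels.BLOWUP:
        raise BlowupError(step, dt)
    if record:
        t = (np.arange(trace.shape[0]) + 1) * dt
        return t, trace, spikes, NeuronState.from_array(yf)
    return None, None, spikes, NeuronState.from_array(yf)


def spike_features(t: np.ndarray, V: np.ndarray,
                   threshold: float = SPIKE_THRESHOLD) -> list[APFeatures]:
    """Per-spike AP features from a voltage trace.

    For each upward threshold crossing: amplitude = peak - threshold,
    half-width = time above the midpoint between threshold and peak,
    AHP depth = threshold - minimum before the next crossing (or trace end).
    A trace with no spike yields an empty list.
    """
    V = np.asarray(V)
    t = np.asarray(t)
    up = np.flatnonzero((V[1:] >= threshold) & (V[:-1] < threshold)) + 1
    out = []
    for j, k0 in enumerate(up):
        k1 = up[j + 1] if j + 1 < len(up) else len(V)
        seg = V[k0:k1]
        if seg.size < 3:
            continue
        peak = float(seg.max())
        mid = 0.5 * (peak + threshold)
        dtv = float(t[1] - t[0])
        half_width = float((seg > mid).sum()) * dtv
        kpk = int(seg.argmax())
        ahp_min = float(seg[kpk:].min())
        out.append(APFeatures(
            amplitude_above_threshold=peak - threshold,
            half_width=half_width,
            ahp_depth=threshold - ahp_min,
        ))
    return out


@dataclass
class FICurve:
    """Steady-state frequency/current relationship of one neuron."""
    currents: np.ndarray          # pA, levels sustaining repetitive firing
    frequencies: np.ndarray       # Hz
    rheobase: float | None        # smallest sustaining current on the grid (pA)
    cutoff_frequency: float | None  # frequency at rheobase (Hz)

    @property
    def fires(self) -> bool:
        return self.rheobase is not None


def _steady_frequency(spikes: np.ndarray, duration: float) -> float | None:
    """Steady frequency over the last 50% of a current step, or None.

    Firing counts as sustained when at least 3 spikes fall in the second
    half of the step and firing continues to the end of the step (gap from
    the last spike to the step end below twice the local mean ISI).
    """
    half = duration / 2.0
    late = spikes[spikes >= half]
    if late.size < 3:
        return None
    isis = np.diff(late)
    if duration - late[-1] > 2.0 * isis.mean():
        return None
    return float(1000.0 / isis.mean())


def fI_curve(params: NeuronParams, i_min: float = 0.0, i_max: float = 1000.0,
             step: float = 25.0, *, step_duration: float = 500.0,
             dt: float = 0.01, g_chr: float = 0.0) -> FICurve:
    """f/I curve from depolarizing current steps.

    Each level runs step_duration ms from rest; the stabilized frequency is
    the inverse mean ISI over the last half of the step.  Levels that do not
    sustain repetitive firing to the end of the step are excluded.  Rheobase
    is the smallest sustaining level on the grid; the cutoff frequency is
    the frequency at rheobase (type-2: strictly positive).
    """
    if i_min >= i_max:
        raise ValueError("need i_min < i_max")
    init = rest_state(params)
    currents, freqs = [], []
    for I in np.arange(i_min, i_max + 0.5 * step, step):
        _, _, spikes, _ = simulate_neuron(
            params, duration=step_duration, dt=dt, i_app=float(I),
            g_chr=g_chr, init=init, record=False)
        f = _steady_frequency(spikes, step_duration)
        if f is not None:
            currents.append(float(I))
            freqs.append(f)
    if not currents:
        return FICurve(np.array([]), np.array([]), None, None)
    return FICurve(np.array(currents), np.array(freqs), currents[0], freqs[0])


def rheobase_bisect(params: NeuronParams, lo: float = 0.0, hi: float = 1000.0,
                    tol: float = 5.0, *, step_duration: float = 500.0,
                    dt: float = 0.01) -> float | None:
    """Refine rheobase by bisection on the step amplitude (oracle for the grid)."""
    init = rest_state(params)

    def sustains(I):
        _, _, sp, _ = simulate_neuron(params, duration=step_duration, dt=dt,
                                      i_app=I, init=init, record=False)
        return _steady_frequency(sp, step_duration) is not None

    if not sustains(hi):
        return None
    if sustains(lo):
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if sustains(mid):
            hi = mid
        else:
            lo = mid
    return hi
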