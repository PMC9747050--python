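"""Chemical synapses, gap junctions, connectivity builders and theta drive.

Chemical synapses are GABA_A conductances with a biexponential waveform
g(t) = F (exp(-t/tau1) - exp(-t/tau2)) normalized to unit peak, initiated
a conduction delay after each presynaptic spike, and depressed by a
Tsodyks-Markram depletion variable x (recovery tau_r, release fraction
U_SE).  Gap junctions are ohmic, symmetric, and bimodally distributed
(strong point mass at 1.2 nS, weak half-Gaussian).  The optogenetic theta
drive is a raised sinusoid spanning [0, g_max] so the conductance is zero
at the cycle start and maximal at the theta peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChemicalSynapse", "GapJunction", "ThetaDrive",
    "TAU_DECAY", "TAU_RISE", "TAU_RECOVERY", "U_SE",
    "E_SYN_HYPER", "E_SYN_SHUNT",
    "biexp_normalization", "biexp_peak_time", "std_step", "std_fixed_point",
    "build_chemical_connectivity", "build_gap_connectivity",
    "theta_conductance", "theta_phase",
    "edges_to_frame", "frame_to_edges",
]

TAU_DECAY = 2.0    # ms (tau1)
TAU_RISE = 0.3     # ms (tau2)
TAU_RECOVERY = 100.0  # ms (STD pool recovery)
U_SE = 0.3            # fraction of the available pool released per spike
E_SYN_HYPER = -75.0   # mV
E_SYN_SHUNT = -55.0   # mV
CONNECTION_P = 0.36   # directed chemical connection probability
GAP_PARTNERS = 27     # candidate electrical partners drawn per neuron
GAP_STRONG_P = 0.25   # probability a junction is strong-mode
GAP_STRONG_G = 1.2    # nS (point mass)
GAP_WEAK_SD = 0.4     # nS (half-Gaussian scale)


@dataclass
class ChemicalSynapse:
    pre: int
    post: int
    g_syn: float          # peak conductance (nS)
    delta: float          # conduction delay (ms)
    E_syn: float = E_SYN_HYPER
    tau1: float = TAU_DECAY
    tau2: float = TAU_RISE
    tau_r: float = TAU_RECOVERY
    U_SE: float = U_SE
    x: float = 1.0        # depression state in [0, 1]

    def __post_init__(self):
        if self.g_syn <= 0:
            raise ValueError("g_syn must be positive")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("x must lie in [0, 1]")


@dataclass(frozen=True)
class GapJunction:
    """Unordered electrically coupled pair; one entry per pair."""
    i: int
    j: int
    g_gap: float  # nS

    def __post_init__(self):
        if self.g_gap <= 0:
            raise ValueError("g_gap must be positive")
        if self.i == self.j:
            raise ValueError("no self gap junctions")


@dataclass(frozen=True)
class ThetaDrive:
    """Simulated channelrhodopsin drive (reversal 0 mV).

    mode='sinusoidal': g(t) = (g_max/2)(1 - cos(2 pi f t / 1000)), spanning
    [0, g_max] with the peak mid-cycle.  mode='constant': g(t) = g_const
    (used for phase-response work at the theta midpoint).
    """
    g_max: float = 14.0
    f: float = 8.0         # Hz
    mode: str = "sinusoidal"
    g_const: float = 7.0   # nS, used when mode == "constant"
    E_ChR: float = 0.0

    def __post_init__(self):
        if self.mode not in ("sinusoidal", "constant"):
            raise ValueError("mode must be 'sinusoidal' or 'constant'")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.f


def biexp_peak_time(tau1: float = TAU_DECAY, tau2: float = TAU_RISE) -> float:
    """Closed-form peak time of exp(-t/tau1) - exp(-t/tau2)."""
    if not tau1 > tau2 > 0:
        raise ValueError("need tau1 > tau2 > 0")
    return tau1 * tau2 / (tau1 - tau2) * math.log(tau1 / tau2)


def biexp_normalization(tau1: float = TAU_DECAY, tau2: float = TAU_RISE) -> float:
    """Normalization F that sets the biexponential peak to one."""
    tpk = biexp_peak_time(tau1, tau2)
    return 1.0 / (math.exp(-tpk / tau1) - math.exp(-tpk / tau2))


def std_step(x: float, *, spike: bool = False, dt: float = 0.0,
             tau_r: float = TAU_RECOVERY, u_se: float = U_SE) -> float:
    """Advance the depression variable.

    Between spikes x relaxes toward 1 with time constant tau_r; on a spike
    x -> x (1 - U_SE), applied after x has been read for the transmitted
    amplitude.  dx/dt = (1 - x)/tau_r - U_SE x delta(t - t_k).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    if dt > 0:
        x = 1.0 - (1.0 - x) * math.exp(-dt / tau_r)
    if spike:
        x *= (1.0 - u_se)
    return x


def std_fixed_point(T: float, tau_r: float = TAU_RECOVERY, u_se: float = U_SE) -> float:
    """Steady-state pre-spike x for periodic firing with period T (ms)."""
    e = math.exp(-T / tau_r)
    return (1.0 - e) / (1.0 - (1.0 - u_se) * e)


def build_chemical_connectivity(n: int = 100, mode: str = "heterogeneous",
                                seed=None, *, g_syn: float = 1.65,
                                delta: float = 0.8, E_syn: float = E_SYN_HYPER,
                                p: float = CONNECTION_P, in_degree: int = 36,
                                sigma_log: float = 1.0, median_g: float = 1.0,
                                delta_range: tuple[float, float] = (0.6, 1.0),
                                autapse_fraction: float = 0.0,
                                g_scale: float = 1.0) -> list[ChemicalSynapse]:
    """Chemical synapse list for an n-neuron network.

    homogeneous: every neuron receives exactly in_degree synapses of fixed
    g_syn and delay delta from distinct random partners.
    heterogeneous: independent directed Bernoulli(p) per ordered pair,
    lognormal peak conductances (natural-log scale, median median_g nS,
    sigma sigma_log) scaled by g_scale, delays uniform in delta_range.
    autapse_fraction reroutes that fraction of each neuron's in-degree onto
    a self-synapse of equal total conductance.
    """
    rng = np.random.default_rng(seed)
    syns: list[ChemicalSynapse] = []
    if mode == "homogeneous":
        if n < in_degree + 1:
            raise ValueError(f"need n >= {in_degree + 1} for exact in-degree {in_degree}")
        for j in range(n):
            others = np.concatenate([np.arange(j), np.arange(j + 1, n)])
            for i in rng.choice(others, size=in_degree, replace=False):
                syns.append(ChemicalSynapse(int(i), j, g_syn, delta, E_syn))
    elif mode == "heterogeneous":
        conn = rng.random((n, n)) < p
        np.fill_diagonal(conn, False)
        pre_idx, post_idx = np.nonzero(conn)
        g = rng.lognormal(mean=math.log(median_g), sigma=sigma_log, size=pre_idx.size) * g_scale
        d = rng.uniform(delta_range[0], delta_range[1], size=pre_idx.size)
        for i, j, gg, dd in zip(pre_idx, post_idx, g, d):
            syns.append(ChemicalSynapse(int(i), int(j), float(gg), float(dd), E_syn))
    else:
        raise ValueError("mode must be 'homogeneous' or 'heterogeneous'")
    if autapse_fraction > 0.0:
        syns = _reroute_autapses(syns, n, autapse_fraction, rng)
    return syns


def _reroute_autapses(syns, n, fraction, rng):
    """Move a fraction of each neuron's inhibitory in-degree to an autapse.

    The rerouted synapses are removed and replaced by one self-synapse whose
    peak conductance equals their total, preserving each neuron's summed
    inhibitory conductance.
    """
    by_post: dict[int, list[ChemicalSynapse]] = {}
    for s in syns:
        by_post.setdefault(s.post, []).append(s)
    out: list[ChemicalSynapse] = []
    for j in range(n):
        inputs = by_post.get(j, [])
        k = int(round(fraction * len(inputs)))
        if k == 0:
            out.extend(inputs)
            continue
        moved_idx = set(rng.choice(len(inputs), size=k, replace=False).tolist())
        moved = [inputs[ix] for ix in sorted(moved_idx)]
        kept = [s for ix, s in enumerate(inputs) if ix not in moved_idx]
        total_g = sum(s.g_syn for s in moved)
        mean_d = float(np.mean([s.delta for s in moved]))
        kept.append(ChemicalSynapse(j, j, total_g, mean_d, moved[0].E_syn))
        out.extend(kept)
    return out


def build_gap_connectivity(n: int = 100, seed=None, *,
                           partners: int = GAP_PARTNERS,
                           strong_p: float = GAP_STRONG_P,
                           strong_g: float = GAP_STRONG_G,
                           weak_sd: float = GAP_WEAK_SD,
                           method: str = "partners",
                           pair_p: float = 0.27) -> list[GapJunction]:
    """Electrical synapse list (one symmetric entry per unordered pair).

    method='partners' (default): each neuron draws `partners` candidate
    partners at random; a junction forms for each candidate pair not already
    present.  method='bernoulli': each unordered pair is connected with
    probability pair_p.  Each junction is strong-mode (point mass strong_g)
    with probability strong_p, otherwise weak-mode |N(0, weak_sd^2)|.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    if method == "partners":
        for i in range(n):
            others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            for j in rng.choice(others, size=min(partners, n - 1), replace=False):
                key = (min(i, int(j)), max(i, int(j)))
                if key not in seen:
                    seen.add(key)
                    pairs.append(key)
    elif method == "bernoulli":
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < pair_p:
                    pairs.append((i, j))
    else:
        raise ValueError("method must be 'partners' or 'bernoulli'")
    gaps: list[GapJunction] = []
    for i, j in pairs:
        if rng.random() < strong_p:
            g = strong_g
        else:
            g = abs(rng.normal(0.0, weak_sd))
            while g == 0.0:
                g = abs(rng.normal(0.0, weak_sd))
        gaps.append(GapJunction(i, j, float(g)))
    return gaps


def theta_conductance(t, drive: ThetaDrive):
    """ChR conductance at time t (ms); bounded in [0, g_max]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if drive.mode == "constant":
        g = np.full_like(t, drive.g_const)
    else:
        g = 0.5 * drive.g_max * (1.0 - np.cos(2.0 * np.pi * drive.f * t / 1000.0))
    return float(g) if g.ndim == 0 else g


def theta_phase(t, drive: ThetaDrive):
    """Theta phase of time t in (-pi, pi], zero at the conductance peak.

    Derived analytically from the drive waveform: the raised sinusoid peaks
    mid-cycle, so phase = wrap(2 pi f t / 1000 - pi).
    """
    t = np.asarray(t, dtype=float)
    ph = np.mod(2.0 * np.pi * drive.f * t / 1000.0 - np.pi, 2.0 * np.pi)
    ph = np.where(ph > np.pi, ph - 2.0 * np.pi, ph)
    # map the representative -pi endpoint into (-pi, pi]
    ph = np.where(np.isclose(ph, -np.pi), np.pi, ph)
    return float(ph) if ph.ndim == 0 else ph


def edges_to_frame(edges) -> pd.DataFrame:
    """Edge list (chemical or gap) to a tidy DataFrame."""
    rows = []
    for e in edges:
        if isinstance(e, GapJunction):
            rows.append(dict(pre=e.i, post=e.j, g_nS=e.g_gap, delay_ms=0.0, kind="gap"))
        else:
            rows.append(dict(pre=e.pre, post=e.post, g_nS=e.g_syn,
                             delay_ms=e.delta, kind="chem"))
    return pd.DataFrame(rows, columns=["pre", "post", "g_nS", "delay_ms", "kind"])


def frame_to_edges(df: pd.DataFrame, E_syn: float = E_SYN_HYPER):
    chem, gaps = [], []
    for row in df.itertuples(index=False):
        if row.kind == "gap":
            gaps.append(GapJunction(int(row.pre), int(row.post), float(row.g_nS)))
        else:
            chem.append(ChemicalSynapse(int(row.pre), int(row.post),
                                        float(row.g_nS), float(row.delay_ms), E_syn))
    return chem, gaps
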