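"""Detection and quantification of theta-nested fast oscillations.

Pipeline: spike raster -> instantaneous population rate (0.1 ms bins,
flat window) -> Morlet continuous wavelet transform (order 5, frequencies
50-449 Hz in 3 Hz steps, power = squared modulus, no cross-scale
normalization beyond the wavelet's own 1/sqrt(s) factor) -> per-theta-cycle
dominant frequency, maximum power, and onset/offset theta phases at a 0.3 x
max-power threshold -> circular summaries of the pooled phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import circmean, circstd

from .coupling import ThetaDrive, theta_phase
from .engine import SpikeRaster

__all__ = [
    "Scalogram", "CycleMetrics", "DEFAULT_FREQS",
    "population_rate", "morlet_wavelet", "wavelet_power",
    "cycle_metrics", "circular_summary", "ensemble_metrics",
]

DEFAULT_FREQS = np.arange(50.0, 450.0, 3.0)  # Hz; 50:3:449 inclusive
OMEGA0 = 5.0


@dataclass
class Scalogram:
    times: np.ndarray        # ms
    frequencies: np.ndarray  # Hz
    power: np.ndarray        # (n_freq, n_time), squared wavelet modulus
    fs: float                # Hz, sampling rate of the rate signal

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class CycleMetrics:
    cycle_index: int
    dominant_freq: float    # Hz at the cycle's power maximum
    max_power: float
    onset_phase: float      # rad, (-pi, pi], 0 at the theta-conductance peak
    offset_phase: float
    included: bool


def population_rate(raster: SpikeRaster, n_neurons: int | None = None,
                    bin_ms: float = 0.1):
    """Instantaneous population rate in spikes/s per neuron.

    Binned at bin_ms with a flat window of the same width (i.e. a plain
    histogram estimate); the integral rate * n_neurons * dt recovers the
    spike count exactly.  Returns (t_centers_ms, rate).
    """
    n = n_neurons or raster.n_neurons
    edges = np.arange(0.0, raster.duration + bin_ms * 0.5, bin_ms)
    counts, _ = np.histogram(raster.times, edges)
    rate = counts / (n * bin_ms * 1e-3)
    t = edges[:-1] + 0.5 * bin_ms
    return t, rate


def morlet_wavelet(M: int, s: float, w: float = OMEGA0) -> np.ndarray:
    """Complex Morlet wavelet of length M and width s (samples).

    psi(x) = pi^(-1/4) sqrt(1/s) exp(i w x) exp(-x^2/2), x = (k-(M-1)/2)/s.
    """
    x = (np.arange(0, M) - (M - 1.0) / 2.0) / s
    return np.pi ** (-0.25) * np.sqrt(1.0 / s) * np.exp(1j * w * x) * np.exp(-0.5 * x ** 2)


def wavelet_power(rate: np.ndarray, fs: float, *, omega0: float = OMEGA0,
                  freqs: np.ndarray | None = None,
                  times: np.ndarray | None = None) -> Scalogram:
    """Morlet scalogram of the population rate.

    Per-frequency wavelet width s = omega0 * fs / (2 pi f) samples; the
    transform is the 'same'-mode convolution of the signal with the
    conjugate time-reversed wavelet (support capped at 10 s samples);
    power is the squared modulus.
    """
    freqs = DEFAULT_FREQS.copy() if freqs is None else np.asarray(freqs, float)
    rate = np.asarray(rate, float)
    nt = rate.size
    widths = omega0 * fs / (2.0 * np.pi * freqs)
    if int(10 * widths.max()) > nt:
        raise ValueError("rate signal shorter than the longest wavelet support")
    power = np.empty((freqs.size, nt))
    for k, s in enumerate(widths):
        M = np.min([10 * s, nt]).astype(int)
        wav = np.conj(morlet_wavelet(M, s, omega0)[::-1])
        coef = fftconvolve(rate, wav, mode="same")
        power[k] = np.abs(coef) ** 2
    if times is None:
        times = np.arange(nt) * 1000.0 / fs
    return Scalogram(np.asarray(times, float), freqs, power, fs)


def cycle_metrics(scalogram: Scalogram, drive: ThetaDrive, *,
                  threshold_frac: float = 0.3, discard_first: int = 4,
                  coi_guard: bool = True) -> list[CycleMetrics]:
    """Per-theta-cycle dominant frequency, power and onset/offset phases.

    Cycles are the drive periods covered by the scalogram; the first
    discard_first cycles are dropped (transients), as is any cycle whose
    wavelet support crosses the signal boundary (cone-of-influence guard).
    The threshold is threshold_frac x the maximum power over all retained
    cycles.  Within each cycle the time profile max_f P(f, t) defines onset
    (first upward threshold crossing) and offset (last downward crossing),
    reported as theta phases with 0 at the conductance peak; cycles whose
    power never exceeds the threshold are flagged excluded.
    """
    T = drive.period_ms
    t = scalogram.times
    n_cycles = int(np.floor((t[-1] + (t[1] - t[0])) / T))
    half_support = 5.0 * OMEGA0 * 1000.0 / (2.0 * np.pi * scalogram.frequencies.min())
    retained = []
    for c in range(discard_first, n_cycles):
        t0, t1 = c * T, (c + 1) * T
        if coi_guard and (t0 < half_support or t1 > t[-1] - half_support):
            continue
        retained.append(c)
    if not retained:
        return []
    prof = scalogram.power.max(axis=0)  # max over frequencies, per time
    cyc_slices = {}
    gmax = 0.0
    for c in retained:
        sel = (t >= c * T) & (t < (c + 1) * T)
        cyc_slices[c] = sel
        if np.any(sel):
            gmax = max(gmax, float(prof[sel].max()))
    if gmax <= 0:
        return []
    thr = threshold_frac * gmax
    out = []
    for c in retained:
        sel = cyc_slices[c]
        if not np.any(sel):
            continue
        tc = t[sel]
        pc = prof[sel]
        sub = scalogram.power[:, sel]
        kmax = int(np.argmax(pc))
        fdom = float(scalogram.frequencies[int(np.argmax(sub[:, kmax]))])
        pmax = float(pc[kmax])
        above = pc >= thr
        if not np.any(above):
            out.append(CycleMetrics(c, fdom, pmax, np.nan, np.nan, False))
            continue
        k_on = int(np.argmax(above))
        k_off = len(above) - 1 - int(np.argmax(above[::-1]))
        out.append(CycleMetrics(
            c, fdom, pmax,
            float(theta_phase(tc[k_on], drive)),
            float(theta_phase(tc[k_off], drive)),
            True))
    return out


def circular_summary(phases) -> tuple[float, float]:
    """Circular mean and circular SD (sqrt(-2 ln Rbar)) of phases in radians.

    Raises on an empty list; a (near-)zero resultant makes the mean
    undefined and returns (nan, sd).
    """
    phases = np.asarray(phases, float)
    if phases.size == 0:
        raise ValueError("empty phase list")
    R = np.abs(np.mean(np.exp(1j * phases)))
    sd = float(circstd(phases))
    if R < 1e-12:
        return float("nan"), sd
    mean = float(circmean(phases, high=np.pi, low=-np.pi))
    return mean, sd


def ensemble_metrics(runs: list[list[CycleMetrics]]) -> dict:
    """Pooled statistics over runs (network instantiations).

    Dominant-frequency and max-power mean +/- SD over the included cycles of
    each run, and over the pooled cycles of the whole ensemble; pooled
    onset/offset circular summaries.
    """
    if not runs:
        raise ValueError("need at least one run")
    per_run = []
    pooled_f, pooled_p, pooled_on, pooled_off = [], [], [], []
    for cms in runs:
        inc = [c for c in cms if c.included]
        fvals = [c.dominant_freq for c in inc]
        pvals = [c.max_power for c in inc]
        per_run.append({
            "n_included": len(inc),
            "freq_mean": float(np.mean(fvals)) if fvals else float("nan"),
            "freq_sd": float(np.std(fvals)) if fvals else float("nan"),
            "power_mean": float(np.mean(pvals)) if pvals else float("nan"),
            "power_sd": float(np.std(pvals)) if pvals else float("nan"),
        })
        pooled_f.extend(fvals)
        pooled_p.extend(pvals)
        pooled_on.extend(c.onset_phase for c in inc)
        pooled_off.extend(c.offset_phase for c in inc)
    res = {
        "per_run": per_run,
        "n_cycles": len(pooled_f),
        "freq_mean": float(np.mean(pooled_f)) if pooled_f else float("nan"),
        "freq_sd": float(np.std(pooled_f)) if pooled_f else float("nan"),
        "power_mean": float(np.mean(pooled_p)) if pooled_p else float("nan"),
        "power_sd": float(np.std(pooled_p)) if pooled_p else float("nan"),
    }
    if pooled_on:
        res["onset_mean"], res["onset_sd"] = circular_summary(pooled_on)
        res["offset_mean"], res["offset_sd"] = circular_summary(pooled_off)
    return res
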