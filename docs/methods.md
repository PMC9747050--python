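# Methods

## Scope

`ingnet` implements a calibrated model of the fast-spiking PV+ interneuron
network of layer 2/3 medial entorhinal cortex and the analyses used to study
its theta-nested fast oscillations: single-cell biophysics, heterogeneous
population synthesis, chemical/electrical coupling, fixed-step network
integration, phase-response-curve (PRC) synchrony theory, and
wavelet/circular-statistics quantification. Units are mV, ms, nS, pA, pF
throughout (nS·mV = pA; pA/pF = mV/ms).

## Single-cell model

Five state variables (V, m, h, n, a). Currents: transient Na (m³h), slow
Kv1-type rectifier (a⁴, responsible for early adaptation and for transient
spiking below rheobase), fast Kv3-type rectifier (n⁴, responsible for the
brief spike and the cell's high maximal rates), and leak. Every conductance
drives V toward its own reversal; the leak reversal E_L is a per-cell
parameter (approximately the resting potential in uncoupled cells).

Activation gates use dx/dt = α(1−x) − βx with
α(V) = k₁(θ−V)/(e^((θ−V)/σ₁)−1) (evaluated as k₁σ₁ at the removable
singularity V = θ) and β(V) = k₂e^(V/σ₂).

**Inactivation-gate convention.** For h the (k, σ) pairs attach to the
*opposite* functional forms: opening β_h = k₁e^(V/σ₁) (an exponential that
grows with hyperpolarization, σ₁ = −20 mV) and closing
α_h = k₂(θ_h−V)/(e^((θ_h−V)/σ₂)−1) (the singular form with σ₂ = 3.5 mV,
positive for all V), in dh/dt = β_h(1−h) − α_h h. This is the unique
assignment of the tabulated constants under which (i) both rates are
positive everywhere, (ii) h is high at rest and low during the spike,
(iii) the half-point θ_h remains a meaningful, per-cell parameter, and
(iv) the reference cell reproduces its anchored behavior (free-running
period 5.97 ms / ~168 Hz at a constant 7 nS drive) to the printed precision.
The naive alternative — rectifying the activation-form α_h — yields a system
whose true attractor at 7 nS is a *depolarization block* fixed point near
+3 mV: forward Euler at coarse steps appears to spike indefinitely, but an
accurate integrator (RK4, or Euler at very small steps) collapses onto the
block state. We verified this by integrating every admissible sign/role
reading with RK4 and comparing against the anchor values.

**Integration.** Forward Euler, matching the stiff system's historical
treatment; classic RK4 is available for single cells as a convergence
check. Gates are clamped to [0,1] after each step (they can overshoot during
the sub-0.1 ms spike peak at dt = 0.01 ms). Spikes are upward crossings of
−30 mV with a 1 ms lockout, timed by linear interpolation inside the step.
At dt = 0.01 ms the reference cell's period is 6.026 ms vs 5.969 ms
converged (~1%); single-cell work defaults to dt = 0.01 ms, and dt ≤ 0.002
ms reproduces converged values to <0.2%.

**Features and f/I.** AP features are threshold-referenced: amplitude =
peak − (−30 mV), half-width = time above the threshold/peak midpoint, AHP
depth = threshold − post-spike minimum. On the adopted model the reference
cell measures ≈31 mV / 0.19 ms / 39 mV; these are narrower-spike,
deeper-trough values than the approximate experimental descriptors
(~40 mV / ~0.3 ms / ~20 mV), which evidently used a different reference
convention — no admissible reading of the tabulated kinetics produces a
−50 mV trough, because the printed n-gate kinetics pin the fast AHP near
−69 mV. Selection bands (below) are therefore centered on the model's own
feature scale. f/I curves use 25 pA steps of 500 ms from rest; the steady
frequency is the inverse mean ISI over the last half of the step, reported
only when firing is sustained to the step's end; rheobase is the smallest
sustaining grid level and the cutoff frequency (strictly positive; type-2)
is the frequency there.

## Population synthesis

10,000 candidates = 100 passive × 100 active uniform draws: τ_m ∈ [3,7] ms,
R_input ∈ [50,150] MΩ, E_L ∈ [−80,−60] mV (C_M = τ_m/R_input,
g_L = 1/R_input); g_Na ∈ [6000,35000] nS, g_Kv1 ∈ [15,150] nS,
g_Kv3/g_Na ∈ [0.03,0.05], θ_m ∈ [−60,−45], θ_h ∈ [−60,−50], θ_a ∈ [35,55],
θ_n ∈ [−15,25] mV.

Screening accepts a candidate when it (a) has a subthreshold resting
potential inside the sampled E_L range (±2 mV; rejects cells whose Na window
current drags rest above −58 mV), (b) sustains repetitive firing below
1.5 nA, and (c) has rheobase-level AP features inside the bands
amplitude 15–60 mV, half-width 0.05–0.5 ms, AHP 20–55 mV (the model's
feature scale; roughly ±50% around the reference cell). Rheobase is located
by a coarse-to-fine bracket equivalent to the 25 pA grid. Roughly 40–50% of
candidates pass.

Selection is greedy-stratified: passers are binned on a 10×10 lattice over
(cutoff frequency, rheobase) and drawn round-robin across occupied bins,
which preserves the pool's spread of excitability rather than concentrating
it — the stated goal of maintaining the approximate distributions of cutoff
frequencies and rheobases, without an unstated optimizer. Screening stops
once 1.6·n candidates have passed (or a configurable cap `max_screen` is
reached); the selection is a pure function of the seed.

**Gap-junction leak compensation.** Junctions are processed in draw order;
each accepted junction's conductance is subtracted from the leak of both
endpoints, and junctions that would push either endpoint's g_L below the
1.5 nS floor are skipped, so R_input ≈ 1/(g_L + Σg_gap) is preserved
exactly where the floor does not bind. The leak reversal is then re-solved
from the steady-state current balance at the cell's original rest (with
neighbors at their own rests) — a linear solve, equivalent to the bisection
the interface allows, exact to machine precision. Capacitance is unchanged.
Compensated cells may have no isolated subthreshold rest (their E_L absorbs
the gap-current correction); in-network they rest at their original
potentials.

## Coupling

Chemical synapses: unit-peak biexponential conductance
F(e^(−t/τ₁) − e^(−t/τ₂)), τ₁ = 2.0 ms, τ₂ = 0.3 ms,
F = 1/(e^(−t_pk/τ₁) − e^(−t_pk/τ₂)) with t_pk = τ₁τ₂/(τ₁−τ₂)·ln(τ₁/τ₂)
(= 1.6443 for the defaults). Homogeneous mode: every neuron receives exactly
36 synapses of 1.65 nS at a fixed delay. Heterogeneous mode: directed
Bernoulli(0.36) per ordered pair, lognormal peak conductances (natural log,
median 1 nS, σ = 1 — mean e^0.5 ≈ 1.65 nS, consistent with the homogeneous
value), delays uniform in [0.6, 1.0] ms. An optional autapse mode reroutes a
fraction of each cell's in-degree to a self-synapse of equal total
conductance. Depression follows dx/dt = (1−x)/τ_r − U_SE·x·δ(t−t_k) with
τ_r = 100 ms, U_SE = 0.3; x is read before the spike scales the delivered
conductance, then depressed. Depression state is tracked per presynaptic
cell (all terminals of a cell share its spike history, so per-synapse states
would be identical).

Gap junctions: each neuron draws 27 candidate partners; a junction forms per
unordered pair not already present (a pairwise-Bernoulli(0.27) builder is
exposed as an alternative). Strong mode (probability 0.25) is a 1.2 nS point
mass; weak mode is |N(0, 0.4² nS²)|. Entries are symmetric and single.

Theta drive: g(t) = (g_max/2)(1 − cos 2πft), spanning [0, g_max = 14 nS]
with midpoint 7 nS, at f = 8 Hz (4 Hz available). A pure-sine drive would be
negative half the time, so the raised sinusoid is the only waveform
consistent with a 0–14 nS range and a 7 nS midpoint. Theta phase is defined
analytically from the waveform, zero at the conductance peak, range (−π, π].

## Network integration

Forward Euler with a shared fixed step. Presynaptic spikes schedule
conductance increments w·F·x at t_spike + δ via a ring buffer (delivery in
the first step with t ≥ t_spike + δ); per-neuron synaptic state is the
(A, B) exponential pair, so delivery is O(out-degree) and the step is O(N +
synaptic events + gap edges). Gap currents Σg(V_j − V_i) use same-step
(pre-update) voltages, consistent with the explicit scheme. Defaults:
dt = 0.01 ms without gap junctions; heterogeneous gap-junction runs use
dt = 0.002 ms after a one-time convergence check (dominant frequency and
onset/offset phases shift <3% between dt = 2×10⁻³ and 5×10⁻⁴ ms); 5×10⁻⁴ ms
remains available.

Population frequency: median inverse interval between successive population
spikes — peaks of the 0.1 ms-binned spike histogram exceeding half the
network — after a 50 ms transient. Synchrony verdicts count distinct neurons
in a sliding 1 ms window; convergence/desynchronization is judged at run end
because a small initial phase offset sits inside the window and unstable
modes lose synchrony slowly.

## PRC measurement and predictions

The cell is settled for 200 ms at the constant drive, its state captured at
a threshold crossing, and each trial restarts from that state; the compound
conductance (36 × 1.65 nS unless overridden) is applied at θ·P_i for 100
equally spaced θ. f₁ and f₂ are measured against an unperturbed trial from
the identical state, which cancels the on-grid crossing quantization.
Trials that abolish spiking are flagged undefined. Frequency prediction
interpolates f₁ (optionally + f₂; default first-order, which reproduces the
anchored predictions) at θ = δ/P_i. The stability multiplier 1 − f₁′(θ) uses
centered differences, flags grid edges and nearby discontinuities (jumps
>5× the median adjacent difference).

## Oscillation metrics

Population rate: 0.1 ms histogram (flat window of one bin), spikes/s per
neuron; its integral recovers the spike count exactly. Scalogram: Morlet
CWT, ψ(x) = π^(−1/4)√(1/s)·e^(iω₀x)e^(−x²/2) with ω₀ = 5 and per-frequency
width s = ω₀f_s/(2πf) samples (support capped at 10 s), frequencies 50–449
Hz in 3 Hz steps, power = squared modulus, no further normalization across
scales. Implemented with FFT convolution ('same' mode) against the
conjugate, time-reversed wavelet.

Per theta cycle (first four discarded; cycles whose wavelet support crosses
the signal boundary excluded — cone-of-influence guard, ~80 ms at 50 Hz):
maximum power and the frequency at it; onset/offset = theta phases of the
first upward / last downward crossing of 0.3 × (maximum power over the
run's retained cycles) by the time profile max_f P(f, t); cycles never
exceeding the threshold are flagged excluded. Circular mean is the argument
of the mean resultant vector; circular SD is √(−2 ln R̄) (scipy's
convention); a near-zero resultant flags the mean undefined.

## Experiment drivers and scale

`run_experiment` composes population → coupling → simulation → analysis as
a pure function of (config, seed). Theta-driven runs start from rest (the
drive is zero at the cycle start; the first four cycles are discarded);
constant-drive runs start from random phases on the limit cycle. Ensemble
drivers freeze the intrinsic parameters (one population per base seed) and
vary only connectivity, weights, and delays across instantiations, matching
the study design. The default analysis scale is 1–3 network instantiations
× 8 retained theta cycles (the full-scale study used 30 × 30); outputs
carry their scale so tolerances can widen accordingly, and ensemble
comparisons use 3-SE bands of the reduced ensemble. Test fixtures are
10-neuron miniatures whose in-degree-6 synapses carry 6× weight so each
cell receives the same total inhibition as the 100-neuron network.

## Known limitations

- The AP morphology of the adopted kinetics (narrow spike, −69 mV trough)
  differs from the approximate experimental descriptors; consequently the
  shunting PRC is advancing from phase ~0.09 (its sign reversal sits near
  0.77 rather than ~0.14), second-order hyperpolarizing resetting reaches
  ~6% (slow Kv1 state memory), and the shunting prediction at δ = 1.6 ms is
  ~234 Hz (the matching simulated network gives ~238 Hz, so theory and
  simulation agree within 2% — the offset is in the model's resetting
  shape, not the PRC machinery).
- Heterogeneous networks with calibrated gap junctions hold their nested
  oscillation past the theta peak instead of desynchronizing as the network
  frequency saturates near 200 Hz; onset phases and all STD orderings match,
  but offset phases sit later than the full-scale published means.
- The synthetic population emulates uniform parameter ranges, not the
  empirical distribution shapes; passing tests demonstrate the pipeline's
  behavior under these stated conditions, not under real mEC recordings.
- No spatial structure, synaptic facilitation, channel noise, or
  multi-compartment morphology.
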