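# Methods

## Model

Every cell is a two-variable Izhikevich neuron: membrane potential `v` (mV)
and recovery current `u` (pA) obey

    C dv/dt = k (v − v_r)(v − v_t) − u + I_app + I_syn
      du/dt = a f(v, u)

with a hard reset `v ← c`, `u ← u + d` when `v ≥ v_p`. Regular-spiking (RS)
cells use the linear recovery drive `f = b (v − v_r) − u`; fast-spiking
(FS) cells use `f = U(v) − u` with `U(v) = 0` below an activation potential
`v_b` and `b (v − v_b)³` above. Cell-class constants live in
`src/ffwd_einet/data/cell_params.json`:

| parameter | Src (RS) | Int (FS) | Tgt subthreshold | Tgt network |
|-----------|----------|----------|------------------|-------------|
| C (pF)    | 100      | 20       | 100              | 50          |
| v_r (mV)  | −60      | −55      | −60              | −60         |
| v_t (mV)  | −40      | −40      | −40              | −45         |
| v_p (mV)  | 35       | 25       | 35               | 35          |
| k (nS)    | 0.7      | 1        | 0.7              | 0.7         |
| a (1/ms)  | 0.03     | 0.2      | 0.03             | 0.03        |
| b (nS)    | −2       | 0.025    | −2               | −2          |
| c (mV)    | −50      | −45      | −50              | −50         |
| d (pA)    | 100      | 0        | 100              | 100         |
| v_b (mV)  | —        | −55      | —                | —           |

The network-regime target variant (halved capacitance, threshold lowered to
−45 mV, plus a 10 pA holding current) makes a single source EPSP
suprathreshold, so each subunit acts as a reliable one-spike relay; the
subthreshold variant keeps the target below threshold so compound-PSP shape
can be measured. Interneurons always receive 50 pA of holding current so a
single AMPA input drives them to spike.

Chemical synapses are conductance based with a dimensionless
single-exponential gate incremented by exactly 1 per presynaptic spike:
`I = G s (E − v_post)`, `ds/dt = −s/τ`. AMPA: `E = 0 mV`, `τ = 2 ms`;
GABA_A: `E = −80 mV`, `τ = 10 ms`. Gap junctions are symmetric ohmic
contacts `I = G_elec (v_pre − v_post)`, evaluated from instantaneous
(pre-reset) potentials at every step so that spike upstrokes are
transmitted as spikelets — the mechanism by which a leading interneuron
accelerates its coupled neighbour.

Circuit configurations and conductance defaults (nS):

| config | Src→Int | Src→Tgt | Int→Tgt | Int–Int elec | Int–Int GABA |
|--------|---------|---------|---------|--------------|--------------|
| SCC    | 10      | 3 (1–10)| 6 (1–10)| —            | —            |
| CCC    | 10      | 3       | 8 (6–10)| 0–8 pairwise | 0–7 pairwise |
| CCN    | 5       | 20      | 10      | 0–5 total    | 0–5 total    |

In the CCN the interneuron population is coupled all-to-all; each
individual connection carries `total / N` (N = number of interneurons).
Self-connections are excluded but the divisor stays N, so the summed
conductance converging on a cell is `total · (N−1)/N`. Each interneuron
inhibits only its own subunit's target; only interneuron–interneuron
coupling spans subunits. In the two-arm CCC the pairwise conductances are
used raw (no population scaling).

## Stimuli (the synthetic-data generator)

Only sources receive external input: a rectangular DC pulse of 250 pA for
25 ms (midpoints of the plausible 200–300 pA / 20–30 ms ranges), sized so
an isolated source fires exactly one action potential — asserted in the
test suite. The boxcar is closed at onset and open at offset, so a pulse
occupies exactly `d_inp/dt` steps. Two timing regimes:

* paired (CCC): two identical pulses separated by Δt_inp ∈ 0–20 ms, exact;
* Gaussian (CCN): per-source onsets drawn i.i.d. from `Normal(t0, σ_inp²)`,
  σ_inp ∈ 1–10 ms, redrawn fresh for all sources every trial.

Onsets are centred at t0 = 100 ms in a 200 ms run, leaving ≥ 50 ms of
settling so holding currents reach steady state before any input;
schedules whose earliest onset would precede t = 0 are rejected. One root
seed per experiment; per-trial seeds are spawned from it via
`numpy.random.SeedSequence`, so reruns are byte-identical.

What the generator does *not* emulate: background synaptic bombardment,
trial-to-trial parameter heterogeneity, conduction delays, or correlated
input timing. Passing tests therefore demonstrate the circuit mechanisms
under clean, transient, independently timed inputs — not robustness to in
vivo-like noise.

## Numerical conventions

* Forward Euler at dt = 0.01 ms (subthreshold protocols, 100 ms) or
  0.05 ms (network protocols, 200 ms). Per step: synaptic currents from
  current states → Euler update of all v, u (u uses the pre-step v) → gate
  decay → reset check → gate increments for this step's spikes. Zero-delay
  synapses therefore act with an effective one-step latency; the spike time
  recorded is the end of the step in which `v ≥ v_p` was detected, with no
  threshold-crossing interpolation.
* Halving dt leaves every default protocol's spike counts unchanged and
  moves spike times by less than two coarse steps (first-order error
  accumulated along the slow approach to threshold); an adaptive-step ODE
  oracle with reset events reproduces isolated-cell spike times to
  sub-millisecond accuracy (tested).
* Divergence guard: |v| > 200 mV outside resets aborts with diagnostics.
* Trials are batched along a trailing axis; all-to-all coupling is a sparse
  conductance-matrix product, which makes pairwise electrical currents
  antisymmetric to machine precision.

## Analysis

**Compound PSP.** Baseline is the target potential sampled at input onset
(after settling). The positive portion is the set of samples more than
ε = 0.01 mV above baseline (ε suppresses numerical chatter; the window
definition is otherwise pictorial). Peak = max deviation, window = total
time above ε, AUC = integral of the deviation over that time. The window
counts total time rather than the first contiguous epoch; the two coincide
on all default protocols (tested). A spike in the analysis window raises an
error directing the caller to the spiking pipeline.

**Spike-time densities.** Pooled spike times of a population are
histogrammed at bin width σ_inp/10 (tying resolution to the input spread)
on a grid aligned to the mean source spike time, padded by ten
smoothing-window widths, then convolved with a 20-bin Hanning window
("same" edge handling; its effect is confined to the padded tails). The
result is deliberately *not* a probability density — no division by sample
count — so the area ("total response") tracks spike counts. Statistics:
normalised mean (mean difference vs source, ms), normalised SD (ratio),
normalised max density (ratio), normalised total (area ratio), and relative
latency: the first time the density reaches 10 % of its own maximum, minus
the same measure for the source. A configuration switch
(`latency_basis="src"`) measures the 10 % threshold against the source
maximum instead, for sensitivity analysis. Gain of any statistic is its
difference from the electrically uncoupled value of the same parameter
set, hence identically zero in the uncoupled column.

**Information.** Source and target are input/output channels; each subunit
contributes one matched first-spike pair per trial (first spikes are used
if a cell fires more than once). Marginals are plug-in histograms of the
pooled first-spike times at a fixed 0.01 ms bin; the joint histograms the
matched pairs at the same bin; no smoothing and no bias correction anywhere
in this path — sample size (2500 pairs at the default 50 × 50) is held
fixed across parameter sets so comparisons are internally consistent.
Missing spikes are imputed with `max(X_C) + 2 sd(X_C)` computed once from
the observed spikes of that population and parameter set (computed before,
not iterated with, imputation); a constant fill (e.g. 1000 ms) is available
for demonstrations. Then `I = H(Src) + H(Tgt) − H(Src,Tgt)` bits and
transmission efficiency `100 · I / H(Tgt)` %, undefined when `H(Tgt) = 0`.

**Coupling coefficient.** Measured on two identical FS cells at their
resting potential: settle 300 ms, inject a small DC step (−20 pA default)
into one cell for 300 ms, and take the ratio of steady-state deflections.
The hyperpolarising probe at rest is the standard electrophysiological
convention and is the regime in which the 0–8 nS conductance range maps
onto coupling coefficients of ~0–0.35. The independent check is the
linearised prediction `cc = G/(g_eff + G)`, with `g_eff` the DC leak at the
fixed point (slope of the quadratic I–V term plus the slope of the
recovery drive, from the Jacobian with u slaved to its nullcline). Note
that a depolarising holding current moves the FS fixed point up the I–V
curve where the effective leak is smaller, and the measured cc rises
accordingly — cc values are therefore always reported together with the
holding condition.

## Design choices where the design was open

* Synaptic transmission has zero programmed delay; all latency effects
  emerge from the dynamics (one integration step plus rise times).
* All-to-all scaling divides by N (not N−1) while excluding electrically
  ineffectual self-connections; a sensitivity check is a one-line spec
  change.
* Input timing in the CCN is redrawn for every source on every trial
  (rather than fixed per source), making trials exchangeable.
* Sweep grid steps within the documented ranges: Δt_inp in 0.4 ms steps
  (so 4.4 ms is on-grid), conductances in 0.5–1 nS steps; recorded in each
  sweep's JSON sidecar.
* Problem sizes: the network protocol uses N = 50 subunits and 50 trials
  per parameter set (2500 first-spike pairs); reduced grids used in unit
  tests are supersets-consistent under the same seeds.

## Known limitations

* Plug-in entropies are biased upward at fine bins; since bin width and
  sample size are fixed, comparisons across parameter sets remain valid,
  but absolute bit values should not be compared across different sample
  sizes.
* Forward Euler with per-step reset makes spike times grid-quantised;
  analyses that depend on sub-step timing resolution inherit the 0.05 ms
  granularity of the network protocol.
* Gap junctions are linear and non-rectifying; NMDA, short-term plasticity
  and activity-dependent electrical-synapse plasticity are out of scope.
* In this parameterisation the network target population loses spikes only
  near the top of the coupling range (total G_elec ≈ 5 nS at σ_inp = 1 ms);
  efficiency losses at moderate coupling are carried almost entirely by
  spike-time dispersion rather than response failures.
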