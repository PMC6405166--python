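# ffwd-einet

Simulation and analysis of the canonical feedforward-inhibition microcircuit
with electrically coupled interneurons.

Throughout the brain, an excitatory source neuron (Src) excites both a
target principal cell (Tgt) and a fast-spiking interneuron (Int) that in
turn inhibits the target — disynaptic feedforward inhibition. Interneurons
are frequently joined by gap junctions (electrical synapses) and sometimes
by reciprocal GABAergic synapses. This package is for computational
neuroscientists who want to ask, quantitatively, how the strength of that
interneuron coupling shapes (i) subthreshold summation of closely timed
inputs in the target and (ii) the timing statistics and information content
of the target population's spiking.

## Model

Cells are two-variable Izhikevich neurons,

```
C dv/dt = k (v − v_r)(v − v_t) − u + I_app + I_syn
  du/dt = a (b (v − v_r) − u)                  (regular spiking, RS)
  du/dt = a (U(v) − u),  U = 0 below v_b, b (v − v_b)^3 above   (fast spiking, FS)
  if v ≥ v_p:  v ← c,  u ← u + d
```

integrated by forward Euler (dt = 0.01 ms subthreshold, 0.05 ms network).
Chemical synapses are conductance based with single-exponential gates,
`I = G s (E − v_post)`, `ds/dt = −s/τ + Σ_k δ(t − t_k)` (AMPA: E = 0 mV,
τ = 2 ms; GABA: E = −80 mV, τ = 10 ms); gap junctions are symmetric ohmic
contacts `I = G_elec (v_pre − v_post)`.

Three configurations are built in: the three-cell **SCC**, the five-cell
**CCC** (two arms, one shared target, optionally coupled interneurons) and
the N-subunit **CCN** (default N = 50) whose interneuron population is
coupled all-to-all with per-connection conductance `total / N`. Inputs are
rectangular DC pulses to the sources — either two pulses at a controlled
delay Δt_inp (CCC) or onsets drawn from `Normal(t0, σ_inp²)` per source and
per trial (CCN).

Analysis covers compound-PSP metrics (peak, integration window, AUC),
Hanning-smoothed spike-time densities with source-normalised statistics,
and the Src→Tgt channel measures: plug-in mutual information
`I = H(Src) + H(Tgt) − H(Src,Tgt)` over 0.01 ms-binned first-spike times
and transmission efficiency `100 · I / H(Tgt)`.

## Worked example

```python
import ffwd_einet as fe

# subthreshold: compound PSP of the simple circuit
net = fe.build_scc()                       # Src -> {Int, Tgt}, Int -> Tgt
raster, trace = fe.run(net, fe.stimulus.single_pulse_schedule(target=0),
                       fe.SimulationConfig.subthreshold())
m = fe.psp_metrics(trace, input_onset=50.0, neuron=2, raster=raster)
print(m.peak, m.window, m.auc)
# peak = 1.88 mV, window = 4.13 ms, auc = 4.23 mV*ms

# gap-junction strength of a coupled FS pair
print(fe.coupling_coefficient(8.0))        # 0.343 (linearised prediction 0.348)

# network: information transmission under electrical coupling
raster = fe.simulate_ccn(sigma_inp=5.0, sum_g_elec=4.5, n_trials=50, seed=1)
info = fe.mutual_information(raster.first_spikes("Src"),
                             raster.first_spikes("Tgt"))
print(info.efficiency)
# H_src=8.525, H_tgt=8.498, I=6.958 bits -> efficiency 81.9 %
```

The PSP numbers say a single source spike depolarises the target by ~1.9 mV
but feedforward inhibition closes the summation window after ~4 ms. An
8 nS gap junction between the interneurons corresponds to a coupling
coefficient of ~0.34 — the upper end of experimentally reported strengths.
In the 50-unit network, 4.5 nS of summed electrical coupling disperses
target spike times enough to cut transmission efficiency from 100 % (the
uncoupled network is a noiseless channel) to ~82 %.

Sweeps behind the full heat maps are scripted:

```sh
ffwd-einet describe --config CCN
ffwd-einet run --preset ccn-info --trials 50 --seed 7 --out out/
```

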