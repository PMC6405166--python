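"""Clock-driven fixed-step simulation of wired circuits.

Forward-Euler integration on a fixed grid.  Within each step, in order:

1. synaptic currents are computed from the *current* states (gap-junction
   current from instantaneous membrane-potential differences, including
   spike upstrokes, which is what transmits spikelets);
2. all membrane potentials and recovery currents take one Euler step;
3. synaptic gates decay;
4. the spike condition ``v >= v_p`` is checked and resets applied - the
   spike time recorded is the time at the end of the step;
5. gates of synapses whose presynaptic neuron spiked this step increment.

This ordering gives zero-delay synapses an effective latency of one step.
Default protocols: 100 ms at dt = 0.01 ms for subthreshold work, 200 ms at
dt = 0.05 ms for network (spiking) work.

Trials are batched: the state arrays carry a trailing trial axis, so 50
network trials integrate in one pass.  All-to-all electrical coupling is
evaluated as a sparse conductance-matrix product, which makes the pairwise
current exchange exactly antisymmetric by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .circuits import Network
from .stimulus import InputSchedule
from .synapses import KIND_CONSTANTS

__all__ = ["SimulationConfig", "SpikeRaster", "VoltageTrace", "run", "run_trials"]

#: membrane potentials beyond this magnitude (mV) abort as divergence
V_SANITY_BOUND = 200.0


@dataclass(frozen=True)
class SimulationConfig:
    """Duration and step of one run; voltage recording is opt-in."""

    duration: float = 200.0  # ms
    dt: float = 0.05         # ms
    record_voltages: bool = False
    seed: int | None = None

    @classmethod
    def subthreshold(cls, **kw) -> "SimulationConfig":
        """100 ms at dt = 0.01 ms, voltages recorded."""
        kw.setdefault("duration", 100.0)
        kw.setdefault("dt", 0.01)
        kw.setdefault("record_voltages", True)
        return cls(**kw)

    @classmethod
    def network(cls, **kw) -> "SimulationConfig":
        """200 ms at dt = 0.05 ms, spikes only."""
        kw.setdefault("duration", 200.0)
        kw.setdefault("dt", 0.05)
        kw.setdefault("record_voltages", False)
        return cls(**kw)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("duration and dt must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


class SpikeRaster:
    """Per-trial, per-neuron spike records of one or more simulations."""

    def __init__(
        self,
        trial: np.ndarray,
        neuron: np.ndarray,
        time: np.ndarray,
        n_trials: int,
        network: Network,
    ):
        order = np.lexsort((time, neuron, trial))
        self.trial = np.asarray(trial, dtype=np.int64)[order]
        self.neuron = np.asarray(neuron, dtype=np.int64)[order]
        self.time = np.asarray(time, dtype=float)[order]
        self.n_trials = int(n_trials)
        self.network = network

    def __len__(self) -> int:
        return self.time.size

    def _pop_indices(self, population: str | np.ndarray) -> np.ndarray:
        if isinstance(population, str):
            return self.network.populations[population]
        return np.asarray(population)

    def times(self, population: str | np.ndarray) -> np.ndarray:
        """All spike times of a population, pooled over neurons and trials."""
        idx = self._pop_indices(population)
        return self.time[np.isin(self.neuron, idx)]

    def spike_counts(self, population: str | np.ndarray) -> np.ndarray:
        """(n_neurons_in_pop, n_trials) spike counts."""
        idx = self._pop_indices(population)
        counts = np.zeros((idx.size, self.n_trials), dtype=int)
        pos = {int(n): i for i, n in enumerate(idx)}
        mask = np.isin(self.neuron, idx)
        for n, k in zip(self.neuron[mask], self.trial[mask]):
            counts[pos[int(n)], k] += 1
        return counts

    def first_spikes(self, population: str | np.ndarray) -> np.ndarray:
        """(n_neurons_in_pop, n_trials) first-spike times; NaN where absent."""
        idx = self._pop_indices(population)
        out = np.full((idx.size, self.n_trials), np.nan)
        pos = {int(n): i for i, n in enumerate(idx)}
        mask = np.isin(self.neuron, idx)
        # records are time-sorted within (trial, neuron); keep the earliest
        for n, k, t in zip(
            self.neuron[mask][::-1], self.trial[mask][::-1], self.time[mask][::-1]
        ):
            out[pos[int(n)], k] = t
        return out

    def to_frame(self) -> pd.DataFrame:
        pop_of = np.empty(self.network.n_neurons, dtype=object)
        for name, idx in self.network.populations.items():
            pop_of[idx] = name
        return pd.DataFrame(
            {
                "trial": self.trial,
                "population": pop_of[self.neuron],
                "neuron": self.neuron,
                "t_ms": self.time,
            }
        )


class VoltageTrace:
    """Full-resolution membrane-potential record: (n_samples, n_neurons, n_trials)."""

    def __init__(self, t: np.ndarray, v: np.ndarray):
        self.t = t
        self.v = v

    def of(self, neuron: int, trial: int = 0) -> np.ndarray:
        """v(t) of one neuron in one trial."""
        return self.v[:, neuron, trial]


def _chem_groups(net: Network):
    """Group chemical synapses by kind into (pre indices, post->syn matrix)."""
    groups = []
    for kind, (E, tau) in KIND_CONSTANTS.items():
        syns = [s for s in net.chemical if s.kind == kind and s.G > 0]
        if not syns:
            continue
        pre = np.array([s.pre_id for s in syns])
        post = np.array([s.post_id for s in syns])
        G = np.array([s.G for s in syns])
        A = sparse.csr_matrix(
            (G, (post, np.arange(len(syns)))), shape=(net.n_neurons, len(syns))
        )
        groups.append({"kind": kind, "E": E, "tau": tau, "pre": pre, "A": A})
    return groups


def _elec_matrix(net: Network):
    if not net.electrical:
        return None, None
    i = np.array([s.pre_id for s in net.electrical])
    j = np.array([s.post_id for s in net.electrical])
    g = np.array([s.G_elec for s in net.electrical])
    n = net.n_neurons
    W = sparse.csr_matrix(
        (np.concatenate([g, g]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    deg = np.asarray(W.sum(axis=1)).ravel()
    return W, deg


def _input_events(schedules: list[InputSchedule], dt: float, n_steps: int):
    """Per-step on/off switch events for every pulse, as sorted arrays."""
    steps, targets, trials, amps = [], [], [], []
    for k, sched in enumerate(schedules):
        for p in sched.pulses:
            on = int(math.ceil(p.t_inp / dt - 1e-9))
            off = int(math.ceil((p.t_inp + p.d_inp) / dt - 1e-9))
            if on >= n_steps:
                continue
            steps += [on, min(off, n_steps)]
            targets += [p.target, p.target]
            trials += [k, k]
            amps += [p.I0, -p.I0]
    if not steps:
        z = np.zeros(0, dtype=int)
        return z, z, z, np.zeros(0)
    order = np.argsort(np.array(steps), kind="stable")
    return (
        np.array(steps)[order],
        np.array(targets)[order],
        np.array(trials)[order],
        np.array(amps)[order],
    )


def _simulate(
    net: Network, schedules: list[InputSchedule], config: SimulationConfig
) -> tuple[SpikeRaster, VoltageTrace | None]:
    n = net.n_neurons
    nT = len(schedules)
    dt = config.dt
    n_steps = config.n_steps

    p = net.cell_params
    C = np.array([q.C for q in p])[:, None]
    vr = np.array([q.v_r for q in p])[:, None]
    vt = np.array([q.v_t for q in p])[:, None]
    vp = np.array([q.v_p for q in p])[:, None]
    kk = np.array([q.k for q in p])[:, None]
    a = np.array([q.a for q in p])[:, None]
    b = np.array([q.b for q in p])[:, None]
    c = np.array([q.c for q in p])[:, None]
    d = np.array([q.d for q in p])[:, None]
    vb = np.array([q.v_b if q.v_b is not None else 0.0 for q in p])[:, None]
    is_fs = np.array([q.is_fs for q in p])[:, None]

    v = np.broadcast_to(vr, (n, nT)).copy()
    u = np.zeros((n, nT))
    Ihold = np.broadcast_to(net.holding[:, None], (n, nT))
    Iinp = np.zeros((n, nT))

    groups = _chem_groups(net)
    for g in groups:
        g["s"] = np.zeros((len(g["pre"]), nT))
        g["decay"] = 1.0 - dt / g["tau"]
    W, deg = _elec_matrix(net)

    ev_step, ev_tgt, ev_trial, ev_amp = _input_events(schedules, dt, n_steps)
    ev_ptr = 0

    record = config.record_voltages
    if record:
        V = np.empty((n_steps + 1, n, nT))
        V[0] = v

    sp_trials: list[np.ndarray] = []
    sp_neurons: list[np.ndarray] = []
    sp_times: list[np.ndarray] = []

    for step in range(n_steps):
        while ev_ptr < ev_step.size and ev_step[ev_ptr] == step:
            Iinp[ev_tgt[ev_ptr], ev_trial[ev_ptr]] += ev_amp[ev_ptr]
            ev_ptr += 1

        # synaptic currents from current states
        Isyn = np.zeros((n, nT))
        if W is not None:
            Isyn += W @ v - deg[:, None] * v
        for g in groups:
            Isyn += (g["A"] @ g["s"]) * (g["E"] - v)

        # Euler update of v and u from the pre-step state
        drive = np.where(
            is_fs,
            np.where(v < vb, 0.0, b * (v - vb) ** 3),
            b * (v - vr),
        )
        dv = (kk * (v - vr) * (v - vt) - u + Ihold + Iinp + Isyn) / C
        du = a * (drive - u)
        v += dt * dv
        u += dt * du

        for g in groups:
            g["s"] *= g["decay"]

        spiked = v >= vp
        if spiked.any():
            v = np.where(spiked, c, v)
            u = np.where(spiked, u + d, u)
            nn, tt = np.nonzero(spiked)
            sp_neurons.append(nn)
            sp_trials.append(tt)
            sp_times.append(np.full(nn.size, (step + 1) * dt))
            for g in groups:
                g["s"] += spiked[g["pre"], :]

        if np.abs(v).max() > V_SANITY_BOUND:
            raise RuntimeError(
                f"membrane potential diverged at t={(step + 1) * dt:.3f} ms "
                f"(|v|max={np.abs(v).max():.1f} mV)"
            )
        if record:
            V[step + 1] = v

    raster = SpikeRaster(
        trial=np.concatenate(sp_trials) if sp_trials else np.zeros(0, dtype=int),
        neuron=np.concatenate(sp_neurons) if sp_neurons else np.zeros(0, dtype=int),
        time=np.concatenate(sp_times) if sp_times else np.zeros(0),
        n_trials=nT,
        network=net,
    )
    trace = VoltageTrace(np.arange(n_steps + 1) * dt, V) if record else None
    return raster, trace


def run(
    network: Network, schedule: InputSchedule, config: SimulationConfig
) -> tuple[SpikeRaster, VoltageTrace | None]:
    """Simulate one trial; returns the spike raster and, if recorded, voltages."""
    _validate_schedule(network, schedule)
    return _simulate(network, [schedule], config)


def run_trials(
    network: Network,
    schedule_factory,
    config: SimulationConfig,
    n_trials: int,
    seed: int | np.random.SeedSequence = 0,
) -> SpikeRaster:
    """Aggregate raster over ``n_trials`` with per-trial derived seeds.

    ``schedule_factory`` is called once per trial with a child
    ``numpy.random.SeedSequence`` spawned deterministically from ``seed``,
    and must return the trial's :class:`InputSchedule`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    schedules = [schedule_factory(child) for child in root.spawn(n_trials)]
    for sched in schedules:
        _validate_schedule(network, sched)
    raster, _ = _simulate(network, schedules, config)
    return raster


def _validate_schedule(network: Network, schedule: InputSchedule) -> None:
    for pulse in schedule.pulses:
        if not 0 <= pulse.target < network.n_neurons:
            raise ValueError(
                f"pulse targets neuron {pulse.target} outside the network"
            )
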