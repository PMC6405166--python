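"""Electrical (gap-junction) and single-exponential chemical synapses.

An electrical synapse is a symmetric ohmic contact: the current into the
postsynaptic cell is ``G_elec (v_pre - v_post)`` (pA for nS x mV), so a
coupled pair exchanges equal and opposite currents at every instant.

Chemical synapses are conductance based with a single-exponential gate:

    I_chem = G s (E - v_post),      ds/dt = -s / tau + sum_k delta(t - t_k)

i.e. the dimensionless gate ``s`` jumps by exactly 1 per presynaptic spike
and decays with the transmitter time constant.  AMPA: E = 0 mV, tau = 2 ms;
GABA_A: E = -80 mV, tau = 10 ms.

For homogeneous all-to-all coupling across an interneuron population the
per-connection conductance is the population total divided by the number of
interneurons (``scale_population_coupling``); self-connections are excluded
but the divisor stays the full population size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "E_AMPA",
    "TAU_AMPA",
    "E_GABA",
    "TAU_GABA",
    "KIND_CONSTANTS",
    "ElectricalSynapse",
    "ChemicalSynapse",
    "electrical_current",
    "chemical_current",
    "decay_gate",
    "on_presynaptic_spike",
    "scale_population_coupling",
    "connections_to_frame",
]

Scalar = Union[float, np.ndarray]

E_AMPA: float = 0.0     # mV
TAU_AMPA: float = 2.0   # ms
E_GABA: float = -80.0   # mV
TAU_GABA: float = 10.0  # ms

#: reversal potential (mV) and decay time constant (ms) per transmitter kind
KIND_CONSTANTS: dict[str, tuple[float, float]] = {
    "AMPA": (E_AMPA, TAU_AMPA),
    "GABA": (E_GABA, TAU_GABA),
}


@dataclass
class ElectricalSynapse:
    """Symmetric gap junction between two neurons (conductance in nS)."""

    pre_id: int
    post_id: int
    G_elec: float

    def __post_init__(self) -> None:
        if self.G_elec < 0:
            raise ValueError("G_elec must be non-negative")
        if self.pre_id == self.post_id:
            raise ValueError("electrical self-coupling is not allowed")


@dataclass
class ChemicalSynapse:
    """Directed conductance-based synapse with a single-exponential gate."""

    pre_id: int
    post_id: int
    kind: str  # "AMPA" | "GABA"
    G: float   # maximal conductance, nS
    s: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.kind not in KIND_CONSTANTS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.G < 0:
            raise ValueError("conductance must be non-negative")
        if self.s < 0:
            raise ValueError("gate state must be non-negative")

    @property
    def E(self) -> float:
        return KIND_CONSTANTS[self.kind][0]

    @property
    def tau(self) -> float:
        return KIND_CONSTANTS[self.kind][1]


def electrical_current(G_elec: Scalar, v_pre: Scalar, v_post: Scalar) -> Scalar:
    """Gap-junction current into the post cell: G_elec (v_pre - v_post), pA."""
    if np.any(np.asarray(G_elec) < 0):
        raise ValueError("G_elec must be non-negative")
    return G_elec * (np.asarray(v_pre) - np.asarray(v_post))


def chemical_current(syn: ChemicalSynapse, v_post: Scalar) -> Scalar:
    """Chemical synaptic current into the post cell: G s (E - v_post), pA."""
    return syn.G * syn.s * (syn.E - np.asarray(v_post))


def decay_gate(s: Scalar, tau: float, dt: float) -> Scalar:
    """One forward-Euler step of the gate's exponential decay."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return s * (1.0 - dt / tau)


def on_presynaptic_spike(s: Scalar, n_spikes: int = 1) -> Scalar:
    """Increment the gate by one per registered presynaptic spike."""
    if n_spikes < 0:
        raise ValueError("n_spikes must be non-negative")
    return s + n_spikes


def scale_population_coupling(total: float, n_int: int) -> float:
    """Per-connection conductance for all-to-all coupling: total / n_int."""
    if n_int < 1:
        raise ValueError("n_int must be at least 1")
    if total < 0:
        raise ValueError("total conductance must be non-negative")
    return total / n_int


def connections_to_frame(
    chemical: Iterable[ChemicalSynapse],
    electrical: Iterable[ElectricalSynapse],
) -> pd.DataFrame:
    """Flat (pre, post, kind, conductance_nS) table of a connection set."""
    rows = [
        {"pre": s.pre_id, "post": s.post_id, "kind": s.kind, "conductance_nS": s.G}
        for s in chemical
    ]
    rows += [
        {"pre": s.pre_id, "post": s.post_id, "kind": "ELEC", "conductance_nS": s.G_elec}
        for s in electrical
    ]
    return pd.DataFrame(rows, columns=["pre", "post", "kind", "conductance_nS"])
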