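"""Izhikevich regular-spiking (RS) and fast-spiking (FS) point neurons.

The two-variable quadratic integrate-and-fire model of Izhikevich describes a
membrane potential ``v`` (mV) and a recovery current ``u`` (pA):

    C dv/dt = k (v - v_r)(v - v_t) - u + I_app + I_syn
      du/dt = a * f(v, u)

with a hard reset ``v <- c``, ``u <- u + d`` whenever ``v >= v_p``.  The
recovery drive ``f`` differs between cell classes: RS cells use the linear
form ``b (v - v_r) - u``; FS cells use ``U(v) - u`` where ``U(v)`` is zero
below an activation potential ``v_b`` and grows cubically above it.

Cell-class constants live in a JSON registry shipped with the package
(:data:`REGISTRY_FILE`); the named presets are ``"Src"``, ``"Int"``,
``"Tgt_subthreshold"`` and ``"Tgt_network"`` (the network target variant has
halved capacitance and a lowered spike threshold so a single excitatory
input drives it to spike).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Union

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "load_registry",
    "get_params",
    "membrane_rhs",
    "recovery_rhs",
    "recovery_drive",
    "apply_reset",
]

Scalar = Union[float, np.ndarray]

REGISTRY_FILE = resources.files("ffwd_einet") / "data" / "cell_params.json"


@dataclass(frozen=True)
class NeuronParams:
    """Constants of one Izhikevich cell class.

    Units: C in pF, potentials in mV, k and b in nS, a in 1/ms, d in pA.
    ``v_b`` (the FS recovery activation potential) is only defined for FS
    cells.
    """

    cell_type: str
    C: float
    v_r: float
    v_t: float
    v_p: float
    k: float
    a: float
    b: float
    c: float
    d: float
    v_b: float | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in ("RS", "FS"):
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if not (self.v_r < self.v_t < self.v_p):
            raise ValueError("require v_r < v_t < v_p")
        if not self.c < self.v_p:
            raise ValueError("reset potential c must lie below v_p")
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if self.cell_type == "FS" and self.v_b is None:
            raise ValueError("FS cells require v_b")

    @property
    def is_fs(self) -> bool:
        return self.cell_type == "FS"


@dataclass
class NeuronState:
    """Instantaneous state: membrane potential v (mV), recovery current u (pA).

    ``v`` and ``u`` may be scalars or equally shaped arrays.
    """

    v: Scalar
    u: Scalar

    @classmethod
    def resting(cls, params: NeuronParams) -> "NeuronState":
        return cls(v=params.v_r, u=0.0)


def load_registry() -> dict[str, NeuronParams]:
    """Load all named cell-parameter presets from the packaged registry."""
    with REGISTRY_FILE.open() as fh:
        raw = json.load(fh)
    return {name: NeuronParams(**entry) for name, entry in raw.items()}


_REGISTRY_CACHE: dict[str, NeuronParams] | None = None


def get_params(name: str) -> NeuronParams:
    """Look up a preset (``Src``, ``Int``, ``Tgt_subthreshold``, ``Tgt_network``)."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = load_registry()
    try:
        return _REGISTRY_CACHE[name]
    except KeyError:
        raise KeyError(
            f"unknown cell preset {name!r}; available: {sorted(_REGISTRY_CACHE)}"
        ) from None


def _check_finite(*values: Scalar) -> None:
    for x in values:
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input")


def membrane_rhs(
    state: NeuronState,
    params: NeuronParams,
    I_app: Scalar = 0.0,
    I_syn: Scalar = 0.0,
) -> Scalar:
    """dv/dt in mV/ms: (k (v-v_r)(v-v_t) - u + I_app + I_syn) / C."""
    _check_finite(state.v, state.u, I_app, I_syn)
    p = params
    return (p.k * (state.v - p.v_r) * (state.v - p.v_t) - state.u + I_app + I_syn) / p.C


def recovery_drive(v: Scalar, params: NeuronParams) -> Scalar:
    """Steady-state target of u at potential v (the f(v, .) drive, pA)."""
    p = params
    if p.is_fs:
        return np.where(np.asarray(v) < p.v_b, 0.0, p.b * (np.asarray(v) - p.v_b) ** 3)
    return p.b * (np.asarray(v) - p.v_r)


def recovery_rhs(state: NeuronState, params: NeuronParams) -> Scalar:
    """du/dt in pA/ms: a (f(v) - u), with the RS linear or FS cubic drive."""
    _check_finite(state.v, state.u)
    drive = recovery_drive(state.v, params)
    out = params.a * (drive - state.u)
    if np.ndim(out) == 0:
        return float(out)
    return out


def apply_reset(state: NeuronState, params: NeuronParams) -> tuple[NeuronState, bool]:
    """Apply the spike-reset rule to a post-update candidate state.

    Returns the (possibly reset) state and whether the spiking condition
    ``v >= v_p`` held.  Scalar states only; the engine applies the same rule
    vectorised.
    """
    if np.ndim(state.v) != 0:
        raise ValueError("apply_reset operates on scalar states")
    if state.v >= params.v_p:
        return NeuronState(v=params.c, u=state.u + params.d), True
    return state, False
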