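"""Builders for the three feedforward-inhibition configurations.

* SCC - simple canonical circuit: one source (Src, RS), one interneuron
  (Int, FS) and one target (Tgt, RS).  Src excites both Int and Tgt via
  AMPA; Int inhibits Tgt via GABA (disynaptic feedforward inhibition).
* CCC - coupled canonical circuit: two SCC arms converging on a common Tgt
  (5 cells).  The two interneurons may be joined by a gap junction and/or
  reciprocal GABA synapses.
* CCN - coupled canonical network: N independent SCC subunits (3N cells)
  whose interneuron population is coupled all-to-all, electrically and
  (optionally) with reciprocal inhibition, each per-connection conductance
  scaled as total / N.  The CCN target cells use the spiking-regime variant
  (halved capacitance, lowered threshold, 10 pA holding) so a single source
  spike drives the target over threshold.

Default conductances per configuration (nS):

    =========  ========  ========  ========  ==============  ==============
    config     Src->Int  Src->Tgt  Int->Tgt  Int-Int elec    Int-Int GABA
    =========  ========  ========  ========  ==============  ==============
    SCC        10        3 (1-10)  6 (1-10)  --              --
    CCC        10        3         8 (6-10)  0 (0-8)         0 (0-7)
    CCN        5         20        10        total 0 (0-5)   total 0 (0-5)
    =========  ========  ========  ========  ==============  ==============

Interneurons always receive a 50 pA holding current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .neurons import NeuronParams, get_params
from .synapses import (
    ChemicalSynapse,
    ElectricalSynapse,
    connections_to_frame,
    scale_population_coupling,
)

__all__ = ["CircuitSpec", "Network", "build_scc", "build_ccc", "build_ccn", "build"]

I_HOLD_INT: float = 50.0  # pA, always
I_HOLD_TGT_CCN: float = 10.0  # pA, network configuration only

#: Table of default conductances and documented sweep ranges (nS).
CONDUCTANCE_TABLE: dict[str, dict[str, tuple[float, tuple[float, float]]]] = {
    "SCC": {
        "g_ampa_int": (10.0, (10.0, 10.0)),
        "g_ampa_tgt": (3.0, (1.0, 10.0)),
        "g_gaba_tgt": (6.0, (1.0, 10.0)),
    },
    "CCC": {
        "g_ampa_int": (10.0, (10.0, 10.0)),
        "g_ampa_tgt": (3.0, (3.0, 3.0)),
        "g_gaba_tgt": (8.0, (6.0, 10.0)),
        "g_elec": (0.0, (0.0, 8.0)),
        "g_gaba_int": (0.0, (0.0, 7.0)),
    },
    "CCN": {
        "g_ampa_int": (5.0, (5.0, 5.0)),
        "g_ampa_tgt": (20.0, (20.0, 20.0)),
        "g_gaba_tgt": (10.0, (10.0, 10.0)),
        "g_elec": (0.0, (0.0, 5.0)),      # population total
        "g_gaba_int": (0.0, (0.0, 5.0)),  # population total
    },
}


@dataclass(frozen=True)
class CircuitSpec:
    """Resolved parameterisation of one circuit configuration.

    ``g_elec``/``g_gaba_int`` are the pairwise conductances for the CCC and
    the *population totals* for the CCN (divided by N per connection).
    """

    config: str  # "SCC" | "CCC" | "CCN"
    n_units: int = 1
    g_ampa_int: float = 0.0
    g_ampa_tgt: float = 0.0
    g_gaba_tgt: float = 0.0
    g_elec: float = 0.0
    g_gaba_int: float = 0.0
    holding: dict = field(default_factory=dict)  # pA per population

    @classmethod
    def defaults(cls, config: str, **overrides) -> "CircuitSpec":
        """Spec with the documented default conductances for ``config``."""
        if config not in CONDUCTANCE_TABLE:
            raise ValueError(f"unknown configuration {config!r}")
        values = {k: v[0] for k, v in CONDUCTANCE_TABLE[config].items()}
        values.update({k: v for k, v in overrides.items() if k in values})
        extra = set(overrides) - set(values) - {"n_units", "holding"}
        if extra:
            raise TypeError(f"unknown overrides: {sorted(extra)}")
        n_units = overrides.get("n_units", {"SCC": 1, "CCC": 2, "CCN": 50}[config])
        holding = {"Src": 0.0, "Int": I_HOLD_INT,
                   "Tgt": I_HOLD_TGT_CCN if config == "CCN" else 0.0}
        holding.update(overrides.get("holding", {}))
        return cls(config=config, n_units=n_units, holding=holding, **values)

    def __post_init__(self) -> None:
        if self.config not in CONDUCTANCE_TABLE:
            raise ValueError(f"unknown configuration {self.config!r}")
        for name in ("g_ampa_int", "g_ampa_tgt", "g_gaba_tgt", "g_elec", "g_gaba_int"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
            bounds = CONDUCTANCE_TABLE[self.config].get(name)
            if bounds is not None and not bounds[1][0] <= value <= bounds[1][1]:
                warnings.warn(
                    f"{name}={value} nS outside documented {self.config} "
                    f"range {bounds[1]}",
                    stacklevel=2,
                )


@dataclass
class Network:
    """A wired circuit: cells, populations, connections, holding currents.

    Neurons are indexed ``0..3n-1`` in population blocks: all Src first,
    then all Int, then all Tgt; neuron ``pop_block + j`` belongs to subunit
    ``j``.
    """

    spec: CircuitSpec
    cell_params: list[NeuronParams]
    populations: dict[str, np.ndarray]  # name -> neuron indices
    unit_of: np.ndarray                 # subunit id per neuron
    holding: np.ndarray                 # pA per neuron
    chemical: list[ChemicalSynapse]
    electrical: list[ElectricalSynapse]

    @property
    def n_neurons(self) -> int:
        return len(self.cell_params)

    def connection_frame(self):
        return connections_to_frame(self.chemical, self.electrical)

    def describe(self) -> dict:
        """Audit summary: populations, per-cell parameters, connection counts."""
        kinds: dict[str, int] = {}
        for syn in self.chemical:
            kinds[syn.kind] = kinds.get(syn.kind, 0) + 1
        return {
            "config": self.spec.config,
            "n_units": self.spec.n_units,
            "n_neurons": self.n_neurons,
            "populations": {k: len(v) for k, v in self.populations.items()},
            "holding_pA": {
                k: float(self.holding[v[0]]) for k, v in self.populations.items()
            },
            "chemical_synapses": kinds,
            "electrical_pairs": len(self.electrical),
            "conductances_nS": {
                "g_ampa_int": self.spec.g_ampa_int,
                "g_ampa_tgt": self.spec.g_ampa_tgt,
                "g_gaba_tgt": self.spec.g_gaba_tgt,
                "g_elec": self.spec.g_elec,
                "g_gaba_int": self.spec.g_gaba_int,
            },
            "cell_types": {
                k: self.cell_params[v[0]].cell_type
                for k, v in self.populations.items()
            },
        }


def _assemble(spec: CircuitSpec, tgt_preset: str) -> Network:
    n = spec.n_units
    src = np.arange(0, n)
    intn = np.arange(n, 2 * n)
    tgt = np.arange(2 * n, 3 * n)
    cell_params = (
        [get_params("Src")] * n + [get_params("Int")] * n + [get_params(tgt_preset)] * n
    )
    holding = np.zeros(3 * n)
    holding[src] = spec.holding.get("Src", 0.0)
    holding[intn] = spec.holding.get("Int", I_HOLD_INT)
    holding[tgt] = spec.holding.get("Tgt", 0.0)

    chem: list[ChemicalSynapse] = []
    for j in range(n):  # per-subunit feedforward arms
        chem.append(ChemicalSynapse(src[j], intn[j], "AMPA", spec.g_ampa_int))
        chem.append(ChemicalSynapse(src[j], tgt[j], "AMPA", spec.g_ampa_tgt))
        chem.append(ChemicalSynapse(intn[j], tgt[j], "GABA", spec.g_gaba_tgt))

    return Network(
        spec=spec,
        cell_params=cell_params,
        populations={"Src": src, "Int": intn, "Tgt": tgt},
        unit_of=np.tile(np.arange(n), 3),
        holding=holding,
        chemical=chem,
        electrical=[],
    )


def build_scc(spec: CircuitSpec | None = None, **overrides) -> Network:
    """Three-cell simple canonical circuit (Src, Int, Tgt; no Int-Int coupling)."""
    if spec is None:
        spec = CircuitSpec.defaults("SCC", **overrides)
    if spec.config != "SCC":
        raise ValueError("build_scc requires an SCC spec")
    spec = replace(spec, n_units=1)
    return _assemble(spec, "Tgt_subthreshold")


def build_ccc(
    spec: CircuitSpec | None = None,
    g_elec: float | None = None,
    g_gaba_int: float | None = None,
    **overrides,
) -> Network:
    """Five-cell coupled canonical circuit: two SCC arms sharing one Tgt.

    ``g_elec`` and ``g_gaba_int`` are the raw pairwise Int-Int conductances
    (no population scaling for a single pair).
    """
    if spec is None:
        spec = CircuitSpec.defaults("CCC", **overrides)
    if spec.config != "CCC":
        raise ValueError("build_ccc requires a CCC spec")
    if g_elec is not None:
        spec = replace(spec, g_elec=g_elec)
    if g_gaba_int is not None:
        spec = replace(spec, g_gaba_int=g_gaba_int)
    spec = replace(spec, n_units=2)

    # 5 cells: Src_1, Src_2, Int_1, Int_2, shared Tgt
    src = np.array([0, 1])
    intn = np.array([2, 3])
    tgt = np.array([4])
    cell_params = [get_params("Src")] * 2 + [get_params("Int")] * 2 + [
        get_params("Tgt_subthreshold")
    ]
    holding = np.zeros(5)
    holding[src] = spec.holding.get("Src", 0.0)
    holding[intn] = spec.holding.get("Int", I_HOLD_INT)
    holding[tgt] = spec.holding.get("Tgt", 0.0)

    chem: list[ChemicalSynapse] = []
    for j in range(2):
        chem.append(ChemicalSynapse(int(src[j]), int(intn[j]), "AMPA", spec.g_ampa_int))
        chem.append(ChemicalSynapse(int(src[j]), 4, "AMPA", spec.g_ampa_tgt))
        chem.append(ChemicalSynapse(int(intn[j]), 4, "GABA", spec.g_gaba_tgt))
    elec: list[ElectricalSynapse] = []
    if spec.g_elec > 0:
        elec.append(ElectricalSynapse(2, 3, spec.g_elec))
    if spec.g_gaba_int > 0:
        chem.append(ChemicalSynapse(2, 3, "GABA", spec.g_gaba_int))
        chem.append(ChemicalSynapse(3, 2, "GABA", spec.g_gaba_int))

    return Network(
        spec=spec,
        cell_params=cell_params,
        populations={"Src": src, "Int": intn, "Tgt": tgt},
        unit_of=np.array([0, 1, 0, 1, 0]),
        holding=holding,
        chemical=chem,
        electrical=elec,
    )


def build_ccn(
    spec: CircuitSpec | None = None,
    n: int | None = None,
    sum_g_elec: float | None = None,
    sum_g_gaba_int: float | None = None,
    **overrides,
) -> Network:
    """N-subunit coupled canonical network with all-to-all Int coupling.

    ``sum_g_elec`` / ``sum_g_gaba_int`` are population totals; every
    individual Int-Int connection carries total / N (self-connections
    excluded, divisor kept at N).
    """
    if spec is None:
        spec = CircuitSpec.defaults("CCN", **overrides)
    if spec.config != "CCN":
        raise ValueError("build_ccn requires a CCN spec")
    if n is not None:
        spec = replace(spec, n_units=n)
    if sum_g_elec is not None:
        spec = replace(spec, g_elec=sum_g_elec)
    if sum_g_gaba_int is not None:
        spec = replace(spec, g_gaba_int=sum_g_gaba_int)
    if spec.n_units < 1:
        raise ValueError("CCN requires at least one subunit")

    net = _assemble(spec, "Tgt_network")
    ints = net.populations["Int"]
    n_int = len(ints)
    if spec.g_elec > 0:
        g = scale_population_coupling(spec.g_elec, n_int)
        for i, j in combinations(ints.tolist(), 2):
            net.electrical.append(ElectricalSynapse(i, j, g))
    if spec.g_gaba_int > 0:
        g = scale_population_coupling(spec.g_gaba_int, n_int)
        for i in ints.tolist():
            for j in ints.tolist():
                if i != j:
                    net.chemical.append(ChemicalSynapse(i, j, "GABA", g))
    return net


def build(spec: CircuitSpec) -> Network:
    """Dispatch to the builder matching ``spec.config``."""
    return {"SCC": build_scc, "CCC": build_ccc, "CCN": build_ccn}[spec.config](spec)
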