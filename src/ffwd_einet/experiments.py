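"""Parameter sweeps over the circuit configurations, with tidy outputs.

Presets (grids follow the documented conductance ranges):

* ``scc-psp``       - SCC: G_AMPA->Tgt x G_GABA->Tgt, compound-PSP metrics.
* ``ccc-delay``     - CCC, no Int-Int coupling: input delay x G_GABA->Tgt.
* ``ccc-elec``      - CCC: input delay x pairwise G_elec (0-8 nS).
* ``ccc-elec-gaba`` - CCC: G_elec x reciprocal G_GABA->Int at two delays.
* ``ccn-density``   - CCN: sigma_inp x total G_elec; spike-time distribution
  statistics, response rate and their gains versus the uncoupled column.
* ``ccn-gain``      - as ``ccn-density`` with reciprocal-inhibition levels.
* ``ccn-info``      - CCN: mutual information and transmission efficiency
  over sigma_inp x total G_elec x total G_GABA->Int.

Each sweep writes one tidy CSV plus a JSON sidecar recording every resolved
parameter and seed, so a rerun with the same root seed reproduces the CSV
byte for byte.  Per-point failures are recorded in an ``error`` column
without aborting the sweep.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuits, engine, info_metrics, spike_statistics, stimulus, subthreshold

__all__ = [
    "SweepConfig",
    "PRESETS",
    "preset",
    "run_experiment",
    "simulate_ccn",
    "ccn_summary",
    "scc_psp",
    "ccc_psp_sweep",
]

#: onset mean for Gaussian network input: leaves >=50 ms of settling even
#: for the widest input spread (sigma_inp = 10 ms) over 2500 draws
CCN_INPUT_T0 = 100.0

SIGMA_GRID = (1.0, 3.0, 5.0, 10.0)
SUM_G_ELEC_GRID = (0.0, 1.0, 2.0, 3.0, 4.5)
SUM_G_GABA_INT_GRID = (0.0, 1.0, 3.0, 5.0)
DELTA_T_GRID = tuple(np.round(np.arange(0.0, 20.0 + 1e-9, 0.4), 10))


@dataclass(frozen=True)
class SweepConfig:
    """One resolved sweep: circuit family, axes, trial count, seed."""

    name: str
    circuit: str  # "SCC" | "CCC" | "CCN"
    axes: dict[str, tuple] = field(default_factory=dict)
    n_trials: int = 50
    n_units: int = 50
    seed: int = 0
    out_dir: str | None = None


def _presets() -> dict[str, SweepConfig]:
    g10 = tuple(float(g) for g in range(1, 11))
    return {
        "scc-psp": SweepConfig(
            name="scc-psp",
            circuit="SCC",
            axes={"g_ampa_tgt": g10, "g_gaba_tgt": g10},
        ),
        "ccc-delay": SweepConfig(
            name="ccc-delay",
            circuit="CCC",
            axes={"delta_t": DELTA_T_GRID, "g_gaba_tgt": (6.0, 8.0, 10.0)},
        ),
        "ccc-elec": SweepConfig(
            name="ccc-elec",
            circuit="CCC",
            axes={
                "delta_t": DELTA_T_GRID,
                "g_elec": tuple(float(g) for g in range(0, 9)),
            },
        ),
        "ccc-elec-gaba": SweepConfig(
            name="ccc-elec-gaba",
            circuit="CCC",
            axes={
                "delta_t": (2.0, 4.4),
                "g_elec": (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
                "g_gaba_int": (1.0, 3.0, 5.0, 7.0),
            },
        ),
        "ccn-density": SweepConfig(
            name="ccn-density",
            circuit="CCN",
            axes={"sigma_inp": SIGMA_GRID, "sum_g_elec": SUM_G_ELEC_GRID},
        ),
        "ccn-gain": SweepConfig(
            name="ccn-gain",
            circuit="CCN",
            axes={
                "sigma_inp": SIGMA_GRID,
                "sum_g_elec": SUM_G_ELEC_GRID,
                "sum_g_gaba_int": SUM_G_GABA_INT_GRID,
            },
        ),
        "ccn-info": SweepConfig(
            name="ccn-info",
            circuit="CCN",
            axes={
                "sigma_inp": SIGMA_GRID,
                "sum_g_elec": SUM_G_ELEC_GRID,
                "sum_g_gaba_int": SUM_G_GABA_INT_GRID,
            },
        ),
    }


PRESETS = _presets()


def preset(name: str, **overrides) -> SweepConfig:
    """A preset sweep, optionally with trial count / seed / grid overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return dataclasses.replace(PRESETS[name], **overrides)


# ---------------------------------------------------------------------------
# single-point simulations


def scc_psp(
    g_ampa_tgt: float = 3.0,
    g_gaba_tgt: float = 6.0,
    onset: float = stimulus.SETTLE_MS,
) -> subthreshold.PSPMetrics:
    """Compound-PSP metrics of one SCC parameter point."""
    net = circuits.build_scc(g_ampa_tgt=g_ampa_tgt, g_gaba_tgt=g_gaba_tgt)
    raster, trace = engine.run(
        net,
        stimulus.single_pulse_schedule(target=0, t0=onset),
        engine.SimulationConfig.subthreshold(),
    )
    return subthreshold.psp_metrics(trace, onset, neuron=2, raster=raster)


def ccc_psp_sweep(
    delta_ts,
    g_elec: float = 0.0,
    g_gaba_int: float = 0.0,
    g_gaba_tgt: float = 8.0,
    onset: float = stimulus.SETTLE_MS,
) -> list[subthreshold.PSPMetrics]:
    """Compound-PSP metrics of one CCC over a batch of input delays.

    The delays share one network, so they integrate as one batched run.
    """
    net = circuits.build_ccc(
        g_elec=g_elec, g_gaba_int=g_gaba_int, g_gaba_tgt=g_gaba_tgt
    )
    schedules = [stimulus.paired_schedule(dt_, t0=onset) for dt_ in delta_ts]
    raster, trace = engine._simulate(
        net, schedules, engine.SimulationConfig.subthreshold()
    )
    tgt = int(net.populations["Tgt"][0])
    return [
        subthreshold.psp_metrics(trace, onset, neuron=tgt, trial=k, raster=raster)
        for k in range(len(schedules))
    ]


def simulate_ccn(
    sigma_inp: float,
    sum_g_elec: float = 0.0,
    sum_g_gaba_int: float = 0.0,
    n_units: int = 50,
    n_trials: int = 50,
    seed: int | np.random.SeedSequence = 0,
    t0: float = CCN_INPUT_T0,
) -> engine.SpikeRaster:
    """Run the network protocol: Gaussian input times, fresh draws per trial."""
    net = circuits.build_ccn(
        n=n_units, sum_g_elec=sum_g_elec, sum_g_gaba_int=sum_g_gaba_int
    )
    src = net.populations["Src"]

    def factory(child: np.random.SeedSequence) -> stimulus.InputSchedule:
        return stimulus.gaussian_schedule(
            n=n_units, sigma_inp=sigma_inp, t0=t0, seed=child, targets=src
        )

    return engine.run_trials(
        net, factory, engine.SimulationConfig.network(), n_trials, seed=seed
    )


def ccn_summary(raster: engine.SpikeRaster, sigma_inp: float) -> dict[str, float]:
    """Distribution statistics, response rate and channel measures of one run."""
    out: dict[str, float] = {}
    for pop in ("Int", "Tgt"):
        stats = spike_statistics.distribution_stats(
            raster, population=pop, sigma_inp=sigma_inp
        )
        for key, value in dataclasses.asdict(stats).items():
            out[f"{pop.lower()}_{key}"] = value
    out["tgt_response_rate_pct"] = spike_statistics.response_rate(raster, "Tgt")
    info = info_metrics.mutual_information(
        raster.first_spikes("Src"), raster.first_spikes("Tgt")
    )
    out.update(
        H_src=info.H_src,
        H_tgt=info.H_tgt,
        H_joint=info.H_joint,
        mutual_info_bits=info.mutual_info,
        efficiency_pct=info.efficiency,
    )
    return out


# ---------------------------------------------------------------------------
# sweep driver


def _grid(axes: dict[str, tuple]):
    names = list(axes)
    mesh = np.meshgrid(*[np.arange(len(axes[n])) for n in names], indexing="ij")
    for flat in zip(*[m.ravel() for m in mesh]):
        yield {n: axes[n][i] for n, i in zip(names, flat)}


def _ccn_point(point: dict, cfg: SweepConfig, seed_int: int) -> dict:
    raster = simulate_ccn(
        sigma_inp=point["sigma_inp"],
        sum_g_elec=point.get("sum_g_elec", 0.0),
        sum_g_gaba_int=point.get("sum_g_gaba_int", 0.0),
        n_units=cfg.n_units,
        n_trials=cfg.n_trials,
        seed=seed_int,
    )
    return ccn_summary(raster, point["sigma_inp"])


def _subthreshold_point(point: dict, cfg: SweepConfig) -> dict:
    if cfg.circuit == "SCC":
        m = scc_psp(
            g_ampa_tgt=point.get("g_ampa_tgt", 3.0),
            g_gaba_tgt=point.get("g_gaba_tgt", 6.0),
        )
    else:
        m = ccc_psp_sweep(
            [point.get("delta_t", 0.0)],
            g_elec=point.get("g_elec", 0.0),
            g_gaba_int=point.get("g_gaba_int", 0.0),
            g_gaba_tgt=point.get("g_gaba_tgt", 8.0),
        )[0]
    return {"peak_mV": m.peak, "window_ms": m.window, "auc_mVms": m.auc}


GAIN_COLUMNS = (
    "int_norm_mean", "int_norm_sd", "int_norm_max_density", "int_norm_total",
    "int_rel_latency", "tgt_norm_mean", "tgt_norm_sd", "tgt_norm_max_density",
    "tgt_norm_total", "tgt_rel_latency", "tgt_response_rate_pct",
    "mutual_info_bits", "efficiency_pct",
)


def _add_gains(df: pd.DataFrame) -> pd.DataFrame:
    """Gain columns: statistic minus its value in the uncoupled column."""
    if "sum_g_elec" not in df.columns:
        return df
    other_axes = [
        c for c in ("sigma_inp", "sum_g_gaba_int") if c in df.columns
    ]
    base = df[df["sum_g_elec"] == 0.0]
    if other_axes:
        base = base.set_index(other_axes)
    for col in GAIN_COLUMNS:
        if col not in df.columns:
            continue
        if other_axes:
            ref = df[other_axes].apply(
                lambda row: base.loc[tuple(row) if len(row) > 1 else row.iloc[0], col],
                axis=1,
            )
        else:
            ref = base[col].iloc[0]
        df[f"gain_{col}"] = spike_statistics.gain(df[col], ref)
    return df


def run_experiment(
    config: SweepConfig | str,
    out_dir: str | Path | None = None,
    **overrides,
) -> pd.DataFrame:
    """Run every grid point of a sweep; optionally write CSV + metadata JSON."""
    if isinstance(config, str):
        config = preset(config, **overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)

    root = np.random.SeedSequence(config.seed)
    points = list(_grid(config.axes))
    point_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(points))]

    rows = []
    for point, pseed in zip(points, point_seeds):
        row = dict(point)
        try:
            if config.circuit == "CCN":
                row["seed"] = pseed
                row.update(_ccn_point(point, config, pseed))
            else:
                row.update(_subthreshold_point(point, config))
            row["error"] = ""
        except Exception as exc:  # record, keep sweeping
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    df = pd.DataFrame(rows)
    if config.circuit == "CCN":
        df = _add_gains(df)

    target = out_dir or config.out_dir
    if target is not None:
        target = Path(target)
        target.mkdir(parents=True, exist_ok=True)
        df.to_csv(target / f"{config.name}.csv", index=False)
        meta = dataclasses.asdict(config)
        meta["point_seeds"] = point_seeds
        (target / f"{config.name}.meta.json").write_text(
            json.dumps(meta, indent=2, default=str)
        )
    return df
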