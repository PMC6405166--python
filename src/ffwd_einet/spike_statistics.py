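"""Smoothed spike-time densities and source-normalised population statistics.

For each population the pooled spike times (all neurons, all trials) are
histogrammed with a bin width of ``sigma_inp / 10`` - tied to the input
spread so small spreads are not under-sampled nor large ones over-smoothed -
and convolved with a 20-bin Hanning window to give the unnormalised density
``d(t)``.  Neither ``d`` nor its source-scaled version ``D`` is a
probability density: the histograms are deliberately not normalised by
sample count, so total response (area) carries spike-count information.

Source-normalised statistics of a population C against the source Src:

* normalised mean     - mean(X_C) - mean(X_Src), ms
* normalised SD       - sd(X_C) / sd(X_Src)
* normalised max density - max d_C / max d_Src
* normalised total    - area under d_C / area under d_Src
* relative latency    - (first time d_C reaches 10% of its own max) minus
  the same measure for Src, ms

The gain of any statistic is its difference from the electrically
uncoupled (G_elec = 0) value of the same parameter set, so the uncoupled
column of a gain map is identically zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .engine import SpikeRaster

__all__ = [
    "DensityEstimate",
    "DistributionStats",
    "estimate_density",
    "shared_edges",
    "distribution_stats",
    "gain",
    "response_rate",
]

HANN_BINS = 20
LATENCY_FRACTION = 0.1
EDGE_PAD_WINDOWS = 10  # histogram padding, in smoothing-window widths


@dataclass
class DensityEstimate:
    """Smoothed spike-time histogram (not a probability density)."""

    bin_width: float
    centers: np.ndarray  # ms
    d: np.ndarray        # smoothed counts, same length as centers

    @property
    def max(self) -> float:
        return float(self.d.max()) if self.d.size else 0.0

    @property
    def total(self) -> float:
        """Area under d(t) up to the constant bin width."""
        return float(self.d.sum())

    def normalized(self, reference: "DensityEstimate") -> np.ndarray:
        """Density scaled by the reference (source) density maximum."""
        return self.d / reference.max

    def latency(self, fraction: float = LATENCY_FRACTION) -> float:
        """First bin center at which d reaches ``fraction`` of its own max."""
        if self.max == 0:
            return np.nan
        idx = np.nonzero(self.d >= fraction * self.max)[0][0]
        return float(self.centers[idx])


def shared_edges(
    times: np.ndarray, sigma_inp: float, align_to: float | None = None
) -> np.ndarray:
    """Histogram edges covering ``times`` at bin width sigma_inp/10.

    Edges are aligned so that ``align_to`` (default: the mean of ``times``)
    falls on an edge, and padded by ``EDGE_PAD_WINDOWS`` smoothing-window
    widths on both sides so the Hanning convolution tails stay in range.
    """
    if sigma_inp <= 0:
        raise ValueError("sigma_inp must be positive")
    bw = sigma_inp / 10.0
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        lo, hi = 0.0, bw
    else:
        lo, hi = times.min(), times.max()
    if align_to is None:
        align_to = float(times.mean()) if times.size else 0.0
    pad = EDGE_PAD_WINDOWS * HANN_BINS * bw
    first = np.floor((lo - pad - align_to) / bw)
    last = np.ceil((hi + pad - align_to) / bw)
    return align_to + np.arange(first, last + 1) * bw


def estimate_density(
    spike_times: np.ndarray,
    sigma_inp: float,
    edges: np.ndarray | None = None,
    t_ref: float = 0.0,
) -> DensityEstimate:
    """Smoothed spike-time density of one pooled spike-time array.

    ``edges`` may be supplied (e.g. from :func:`shared_edges`) so source
    and target densities live on the same grid; bin centers are reported
    relative to ``t_ref`` (typically the mean source spike time).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        warnings.warn("empty spike set; density is identically zero", stacklevel=2)
    if edges is None:
        edges = shared_edges(spike_times, sigma_inp)
    counts, _ = np.histogram(spike_times, bins=edges)
    window = np.hanning(HANN_BINS)
    d = np.convolve(counts.astype(float), window, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:]) - t_ref
    return DensityEstimate(bin_width=float(edges[1] - edges[0]), centers=centers, d=d)


@dataclass
class DistributionStats:
    """Source-normalised spike-time distribution statistics."""

    norm_mean: float         # ms
    norm_sd: float           # ratio
    norm_max_density: float  # ratio
    norm_total: float        # ratio
    rel_latency: float       # ms


def _pooled_times(source, population) -> np.ndarray:
    if isinstance(source, SpikeRaster):
        return source.times(population)
    return np.asarray(source, dtype=float)


def distribution_stats(
    raster,
    population="Tgt",
    sigma_inp: float = 1.0,
    src_population="Src",
    src_raster=None,
    latency_basis: str = "own",
) -> DistributionStats:
    """All five source-normalised statistics of a population's spike times.

    ``raster`` may be a :class:`SpikeRaster` (with ``population`` naming the
    population) or a plain array of pooled spike times; likewise for the
    source.  ``latency_basis`` selects whether the 10% latency threshold is
    taken from each distribution's own maximum (default) or from the source
    maximum (``"src"``, for sensitivity analysis).
    """
    times_c = _pooled_times(raster, population)
    src = src_raster if src_raster is not None else raster
    times_src = _pooled_times(src, src_population)
    if times_src.size == 0:
        raise ValueError("source population produced no spikes")
    if latency_basis not in ("own", "src"):
        raise ValueError("latency_basis must be 'own' or 'src'")
    if times_c.size == 0:
        warnings.warn("empty target population; statistics undefined", stacklevel=2)
        return DistributionStats(*([np.nan] * 5))

    src_mean = float(times_src.mean())
    edges = shared_edges(
        np.concatenate([times_src, times_c]), sigma_inp, align_to=src_mean
    )
    d_src = estimate_density(times_src, sigma_inp, edges=edges, t_ref=src_mean)
    d_c = estimate_density(times_c, sigma_inp, edges=edges, t_ref=src_mean)

    if latency_basis == "own":
        lat_c = d_c.latency()
        lat_src = d_src.latency()
    else:
        thr = LATENCY_FRACTION * d_src.max
        lat_c = _first_reaching(d_c, thr)
        lat_src = _first_reaching(d_src, thr)

    return DistributionStats(
        norm_mean=float(times_c.mean() - src_mean),
        norm_sd=float(times_c.std() / times_src.std()) if times_src.std() > 0 else np.nan,
        norm_max_density=d_c.max / d_src.max,
        norm_total=d_c.total / d_src.total,
        rel_latency=lat_c - lat_src,
    )


def _first_reaching(dens: DensityEstimate, threshold: float) -> float:
    idx = np.nonzero(dens.d >= threshold)[0]
    return float(dens.centers[idx[0]]) if idx.size else np.nan


def gain(stat_value: float, stat_value_uncoupled: float) -> float:
    """Change of a statistic relative to the electrically uncoupled case."""
    return stat_value - stat_value_uncoupled


def response_rate(raster: SpikeRaster, population="Tgt") -> float:
    """Percent of neurons with at least one spike, averaged over trials."""
    counts = raster.spike_counts(population)
    return float((counts > 0).mean() * 100.0)
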