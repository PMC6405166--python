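"""Synthetic external input: DC pulses with controlled timing.

Only source neurons receive external input, as a rectangular DC pulse

    I_inp(t) = I0   for t in [t_inp, t_inp + d_inp),  else 0

with amplitude 200-300 pA and duration 20-30 ms, sized to evoke exactly one
action potential in the source cell.  Defaults are the range midpoints
(250 pA, 25 ms).

Two timing regimes are provided:

* paired: two identical pulses whose onsets differ by a controlled delay
  ``delta_t_inp`` (0-20 ms) - the coupled-circuit (CCC) protocol;
* Gaussian: one pulse per source with onsets drawn i.i.d. from
  ``Normal(t0, sigma_inp^2)``, ``sigma_inp`` in 1-10 ms - the network (CCN)
  protocol, redrawn fresh each trial.

Onsets are placed after a settling buffer (default 50 ms past t = 0) so the
holding currents reach steady state before any input arrives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_I0",
    "DEFAULT_DURATION",
    "SETTLE_MS",
    "PulseInput",
    "InputSchedule",
    "dc_pulse",
    "single_pulse_schedule",
    "paired_schedule",
    "gaussian_schedule",
]

DEFAULT_I0: float = 250.0       # pA, midpoint of 200-300
DEFAULT_DURATION: float = 25.0  # ms, midpoint of 20-30
SETTLE_MS: float = 50.0         # settling buffer before the earliest input


@dataclass(frozen=True)
class PulseInput:
    """One rectangular current pulse delivered to a single neuron."""

    target: int
    I0: float = DEFAULT_I0
    t_inp: float = SETTLE_MS
    d_inp: float = DEFAULT_DURATION

    def __post_init__(self) -> None:
        if self.d_inp <= 0:
            raise ValueError("pulse duration must be positive")
        if self.t_inp < 0:
            raise ValueError("pulse onset must not precede t=0")

    def current(self, t: float) -> float:
        return dc_pulse(self.I0, self.t_inp, self.d_inp, t)


@dataclass(frozen=True)
class InputSchedule:
    """A set of pulses plus the timing metadata that generated them."""

    pulses: tuple[PulseInput, ...]
    delta_t_inp: float | None = None
    sigma_inp: float | None = None
    seed: int | None = None

    def onsets(self) -> np.ndarray:
        return np.array([p.t_inp for p in self.pulses])

    def to_frame(self) -> pd.DataFrame:
        """Serialisable (neuron, onset, duration, amplitude, seed) table."""
        return pd.DataFrame(
            {
                "neuron": [p.target for p in self.pulses],
                "onset_ms": [p.t_inp for p in self.pulses],
                "duration_ms": [p.d_inp for p in self.pulses],
                "amplitude_pA": [p.I0 for p in self.pulses],
                "seed": self.seed,
            }
        )


def dc_pulse(I0: float, t_inp: float, d_inp: float, t: float) -> float:
    """Boxcar pulse: I0 for t in [t_inp, t_inp + d_inp), else 0 (pA)."""
    if d_inp <= 0:
        raise ValueError("pulse duration must be positive")
    return I0 if t_inp <= t < t_inp + d_inp else 0.0


def single_pulse_schedule(
    target: int = 0,
    t0: float = SETTLE_MS,
    I0: float = DEFAULT_I0,
    d_inp: float = DEFAULT_DURATION,
) -> InputSchedule:
    """One default pulse to one source neuron."""
    return InputSchedule(pulses=(PulseInput(target, I0, t0, d_inp),))


def paired_schedule(
    delta_t: float,
    targets: tuple[int, int] = (0, 1),
    t0: float = SETTLE_MS,
    I0: float = DEFAULT_I0,
    d_inp: float = DEFAULT_DURATION,
) -> InputSchedule:
    """Two identical pulses: the second source leads the first by ``delta_t``.

    ``delta_t`` may be negative, mirroring which source leads.
    """
    base = min(t0, t0 + delta_t)
    if base < 0:
        raise ValueError("schedule onset precedes t=0; increase t0")
    pulses = (
        PulseInput(targets[0], I0, t0, d_inp),
        PulseInput(targets[1], I0, t0 + delta_t, d_inp),
    )
    return InputSchedule(pulses=pulses, delta_t_inp=delta_t)


def gaussian_schedule(
    n: int,
    sigma_inp: float,
    t0: float,
    seed: int | np.random.SeedSequence,
    targets: np.ndarray | None = None,
    I0: float = DEFAULT_I0,
    d_inp: float = DEFAULT_DURATION,
) -> InputSchedule:
    """One pulse per source, onsets ~ Normal(t0, sigma_inp^2), seeded.

    Raises if any drawn onset precedes t = 0 (choose ``t0`` large enough).
    """
    if n < 1:
        raise ValueError("need at least one source")
    if sigma_inp <= 0:
        raise ValueError("sigma_inp must be positive")
    rng = np.random.default_rng(seed)
    onsets = rng.normal(loc=t0, scale=sigma_inp, size=n)
    if onsets.min() < 0:
        raise ValueError("an onset precedes t=0; increase t0 relative to sigma_inp")
    if targets is None:
        targets = np.arange(n)
    seed_int = seed if isinstance(seed, int) else None
    pulses = tuple(
        PulseInput(int(tgt), I0, float(t), d_inp) for tgt, t in zip(targets, onsets)
    )
    return InputSchedule(pulses=pulses, sigma_inp=sigma_inp, seed=seed_int)
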