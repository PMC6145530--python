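"""Synthetic damped-sinusoid generator used throughout the test studies.

The generator emits ``y[m] = sum_i A_i exp(-sigma_i m) cos(2 pi m dt / T_i +
theta_i) + w[m]`` for m = 0..N-1 with i.i.d. Gaussian noise w of standard
deviation ``noise_sd``.  The standard four-component preset combines an almost
constant trend with slowly decaying ~24.8 h, growing ~11.8 h and decaying
~7.5 h oscillations, emulating a circadian gene-expression profile with
ultradian structure.  Hourly sampling (dt = 1) is the default study condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .timeseries import OscillationComponent, TimeSeries, evaluate_components

__all__ = ["SimulationSpec", "standard_preset", "generate", "subsample", "split_parts"]


def standard_preset() -> list[OscillationComponent]:
    """The standard simulation preset: trend + 24.8 h + 11.8 h + 7.5 h modes.

    Component (A, sigma, theta, T):
    (1, 0.005, 0, inf), (1, 0.004, pi/2 - 6, 24.8),
    (0.3, -0.002, pi/2, 11.8), (0.1, 0.005, pi/2 + 1, 7.5).
    The implied true poles are exp(-sigma) * exp(2j*pi/T).
    """
    return [
        OscillationComponent(1.0, 0.005, 0.0, math.inf),
        OscillationComponent(1.0, 0.004, math.pi / 2 - 6.0, 24.8),
        OscillationComponent(0.3, -0.002, math.pi / 2, 11.8),
        OscillationComponent(0.1, 0.005, math.pi / 2 + 1.0, 7.5),
    ]


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic record."""

    components: tuple = field(default_factory=lambda: tuple(standard_preset()))
    n_samples: int = 50
    dt: float = 1.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "components", tuple(self.components))


def generate(spec: SimulationSpec) -> TimeSeries:
    """Generate one record; deterministic given (spec, seed)."""
    clean = evaluate_components(spec.components, spec.n_samples, spec.dt)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    return TimeSeries(clean, t0=0.0, dt=spec.dt, label="synthetic")


def subsample(ts: TimeSeries, stride: int, offset: int = 0) -> TimeSeries:
    """Keep samples at positions offset, offset+stride, ...; dt scales by stride."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not (0 <= offset < stride):
        raise ValueError("offset must satisfy 0 <= offset < stride")
    vals = ts.values[offset::stride]
    if vals.size < 4:
        raise ValueError("subsampled series would be shorter than 4 samples")
    return TimeSeries(vals, t0=ts.t0 + offset * ts.dt, dt=ts.dt * stride,
                      label=ts.label)


def split_parts(ts: TimeSeries) -> dict[str, TimeSeries]:
    """Derived records for the sampling-rate study.

    AD = all data, FHD/SHD = first/second half, OD/ED = odd/even positions
    (1-based positions: OD keeps samples 1, 3, 5, ...).
    """
    n = len(ts)
    if n < 8:
        raise ValueError("need at least 8 samples to split")
    h = n // 2
    return {
        "AD": ts,
        "FHD": TimeSeries(ts.values[:h], t0=ts.t0, dt=ts.dt, label=ts.label),
        "SHD": TimeSeries(ts.values[h:], t0=ts.t0 + h * ts.dt, dt=ts.dt,
                          label=ts.label),
        "OD": TimeSeries(ts.values[0::2], t0=ts.t0, dt=2 * ts.dt, label=ts.label),
        "ED": TimeSeries(ts.values[1::2], t0=ts.t0 + ts.dt, dt=2 * ts.dt,
                         label=ts.label),
    }
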