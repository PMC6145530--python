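"""Core domain types for oscillation analysis of uniformly sampled series.

A decomposition method represents a signal as a sum of exponential modes

    y_hat[n] = sum_i P_i * lambda_i**(n-1),        n = 1, ..., N,

where each complex pole ``lambda = exp(sigma + j*omega)`` carries a per-sample
decay rate ``sigma`` and an angular frequency ``omega`` (radians per sample),
and the complex residue ``P`` carries amplitude and phase.  For real signals
poles occur in conjugate pairs; a pair collapses to one real damped cosine

    f[n] = A * exp(-sigma * m) * cos(2*pi * m * dt / T + theta),   m = n - 1,

with peak amplitude ``A = 2|P|``, phase ``theta = arg P`` and period
``T = 2*pi*dt / |omega|`` in hours.  A real positive pole near 1 is the dc
(infinite-period) trend term.  This module holds the containers for both
parameterizations, the conversions between them, and the signal inner
product / angle used for the orthogonality diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TimeSeries",
    "OscillationComponent",
    "PoleSet",
    "DecompositionResult",
    "inner_product",
    "angle_degrees",
    "poles_to_components",
    "components_to_poles",
    "evaluate_components",
    "DC_IMAG_TOL",
]

#: a pole is treated as dc when |Im lambda| < DC_IMAG_TOL and Re lambda > 0
DC_IMAG_TOL = 1e-6

#: relative tolerance for matching a complex pole with its conjugate
CONJUGATE_TOL = 1e-6


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued record.

    Parameters
    ----------
    values : array-like
        Measurements, arbitrary units.
    t0 : float
        Time of the first sample, hours.
    dt : float
        Sampling interval, hours (> 0).
    label : str
        Identifier (gene name, mouse id, ...).
    """

    values: np.ndarray
    t0: float = 0.0
    dt: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if vals.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries values must all be finite")
        if not (self.dt > 0):
            raise ValueError("sampling interval dt must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        """Sample times in hours."""
        return self.t0 + self.dt * np.arange(len(self))

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)


@dataclass(frozen=True)
class OscillationComponent:
    """One damped-cosine mode: ``A * exp(-decay*m) * cos(2*pi*m*dt/period + phase)``.

    ``period`` is in hours; ``math.inf`` denotes the dc (trend) term and is
    printed as ``"dc"``.  ``decay`` is a per-sample rate (positive = decaying,
    negative = growing).  Phase is normalized to (-pi, pi].
    """

    amplitude: float
    decay: float
    phase: float
    period: float
    paired: bool = True  # False when a complex pole lacked a conjugate partner

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not (self.period > 0):  # inf is fine
            raise ValueError("period must be positive (or inf for dc)")
        object.__setattr__(self, "phase", _wrap_phase(self.phase))

    @property
    def is_dc(self) -> bool:
        return math.isinf(self.period)

    def period_label(self, decimals: int = 4) -> str:
        return "dc" if self.is_dc else f"{self.period:.{decimals}f}"

    def evaluate(self, n_samples: int, dt: float = 1.0) -> np.ndarray:
        """Sample the mode on indices m = 0..n_samples-1 (the n-1 convention)."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        m = np.arange(n_samples, dtype=float)
        omega = 0.0 if self.is_dc else 2.0 * math.pi * dt / self.period
        return self.amplitude * np.exp(-self.decay * m) * np.cos(omega * m + self.phase)


@dataclass(frozen=True)
class PoleSet:
    """Complex poles with one residue each, on a grid of ``dt`` hours/sample."""

    poles: np.ndarray
    residues: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.poles, dtype=complex))
        r = np.atleast_1d(np.asarray(self.residues, dtype=complex))
        if p.shape != r.shape:
            raise ValueError("poles and residues must have equal length")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        object.__setattr__(self, "poles", p)
        object.__setattr__(self, "residues", r)

    def __len__(self) -> int:
        return self.poles.size

    def evaluate(self, n_samples: int) -> np.ndarray:
        """Direct mode sum ``sum_i P_i lambda_i**m`` on m = 0..n_samples-1."""
        m = np.arange(n_samples)
        return (self.residues[:, None] * self.poles[:, None] ** m[None, :]).sum(axis=0)

    def periods(self) -> np.ndarray:
        """Period in hours per pole (inf for dc-like real positive poles)."""
        out = np.empty(len(self))
        for i, lam in enumerate(self.poles):
            w = abs(np.angle(lam))
            out[i] = math.inf if w < DC_IMAG_TOL else 2.0 * math.pi * self.dt / w
        return out


@dataclass(frozen=True)
class DecompositionResult:
    """Outcome of a pole-based decomposition of one series.

    ``approximant + residual`` reproduces the input elementwise and
    ``relative_error = ||residual|| / ||input||``.  Components are sorted with
    dc first, then by descending amplitude.
    """

    components: tuple
    pole_set: PoleSet
    approximant: TimeSeries
    residual: TimeSeries
    relative_error: float
    order: int
    singular_values: np.ndarray | None = field(default=None, compare=False)

    def component_table(self):
        """Per-component table with columns A (amplitude), P (pole magnitude),
        T (period, "dc" allowed), phase and decay — the layout used for
        reporting model parameters."""
        import pandas as pd

        rows = []
        for c in self.components:
            lam_mag = math.exp(-c.decay)
            rows.append({
                "A": c.amplitude,
                "P": lam_mag,
                "T": c.period_label(),
                "phase": c.phase,
                "decay": c.decay,
            })
        return pd.DataFrame(rows, columns=["A", "P", "T", "phase", "decay"])


def _wrap_phase(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    t = (theta + math.pi) % (2.0 * math.pi) - math.pi
    if t <= -math.pi + 1e-15:
        t = math.pi
    return float(t)


def inner_product(a, b) -> complex:
    """Complex inner product ``sum_j conj(a_j) * b_j`` of two equal-length signals."""
    a = np.atleast_1d(np.asarray(a))
    b = np.atleast_1d(np.asarray(b))
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inner_product requires two equal-length 1-D signals")
    return complex(np.vdot(a, b))


def angle_degrees(a, b) -> float:
    """Angle between two signals in degrees, in [0, 180].

    ``arccos(<a,b> / (||a|| ||b||))``; for complex inputs the real part of the
    normalized inner product is used, clipped to [-1, 1].  90 degrees means
    the signals are orthogonal.
    """
    a = np.atleast_1d(np.asarray(a))
    b = np.atleast_1d(np.asarray(b))
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angle is undefined for a zero signal")
    c = inner_product(a, b) / (na * nb)
    cr = float(np.clip(c.real, -1.0, 1.0))
    if not (np.iscomplexobj(a) or np.iscomplexobj(b)) and abs(cr) > 1.0 - 1e-8:
        # arccos is ill-conditioned near +-1; use the chord formula there
        u, v = a / na, b / nb
        if cr > 0:
            return float(np.degrees(2.0 * np.arcsin(np.linalg.norm(u - v) / 2.0)))
        return 180.0 - float(np.degrees(2.0 * np.arcsin(np.linalg.norm(u + v) / 2.0)))
    return float(np.degrees(np.arccos(cr)))


def poles_to_components(pole_set: PoleSet) -> list[OscillationComponent]:
    """Collapse a conjugate-closed pole/residue set into real damped cosines.

    Each conjugate pair (lambda, conj lambda) with residues (P, conj P) becomes
    one component with period ``2*pi*dt/|arg lambda|`` hours, per-sample decay
    ``-ln|lambda|``, amplitude ``2|P|`` and phase ``arg P``.  A real positive
    pole maps to a dc/aperiodic component of amplitude ``|P|``.  An unpaired
    complex pole is kept as a single component flagged ``paired=False`` (with a
    warning); its real-part evaluation then only approximates the mode sum.
    """
    poles = pole_set.poles
    residues = pole_set.residues
    if np.any(np.abs(poles) < 1e-12):
        raise ValueError("pole at or near zero: decay rate undefined")
    dt = pole_set.dt
    used = np.zeros(len(poles), dtype=bool)
    comps: list[OscillationComponent] = []
    for i, lam in enumerate(poles):
        if used[i]:
            continue
        used[i] = True
        P = residues[i]
        if abs(lam.imag) < DC_IMAG_TOL:
            # real pole: dc when positive, Nyquist alternation when negative
            sigma = -math.log(abs(lam))
            if lam.real > 0:
                period = math.inf
                theta = 0.0 if P.real >= 0 else math.pi
            else:
                period = 2.0 * dt
                theta = 0.0 if P.real >= 0 else math.pi
            comps.append(OscillationComponent(abs(P), sigma, theta, period))
            continue
        # find the conjugate partner among unused poles
        tol = CONJUGATE_TOL * max(1.0, abs(lam))
        partner = -1
        for j in range(i + 1, len(poles)):
            if not used[j] and abs(poles[j] - lam.conjugate()) < tol:
                partner = j
                break
        if partner >= 0:
            used[partner] = True
            # use the member with positive imaginary part
            if lam.imag < 0:
                lam, P = poles[partner], residues[partner]
            omega = abs(np.angle(lam))
            comps.append(OscillationComponent(
                2.0 * abs(P), -math.log(abs(lam)), float(np.angle(P)),
                2.0 * math.pi * dt / omega))
        else:
            warnings.warn(
                f"complex pole {lam:.6g} has no conjugate partner; kept unpaired",
                stacklevel=2)
            omega = abs(np.angle(lam))
            comps.append(OscillationComponent(
                abs(P), -math.log(abs(lam)), float(np.angle(P)),
                2.0 * math.pi * dt / omega, paired=False))
    comps.sort(key=lambda c: (not c.is_dc, -c.amplitude))
    return comps


def components_to_poles(components, dt: float = 1.0) -> PoleSet:
    """Inverse of :func:`poles_to_components` (up to pole ordering)."""
    poles: list[complex] = []
    residues: list[complex] = []
    for c in components:
        mag = math.exp(-c.decay)
        if c.is_dc:
            poles.append(complex(mag))
            residues.append(complex(c.amplitude * math.cos(c.phase)))
            continue
        omega = 2.0 * math.pi * dt / c.period
        lam = mag * complex(math.cos(omega), math.sin(omega))
        if not c.paired:
            poles.append(lam)
            residues.append(c.amplitude * complex(math.cos(c.phase), math.sin(c.phase)))
            continue
        if abs(omega - math.pi) < DC_IMAG_TOL:  # Nyquist: single real negative pole
            poles.append(complex(-mag))
            residues.append(complex(c.amplitude * math.cos(c.phase)))
            continue
        P = 0.5 * c.amplitude * complex(math.cos(c.phase), math.sin(c.phase))
        poles.extend([lam, lam.conjugate()])
        residues.extend([P, P.conjugate()])
    return PoleSet(np.array(poles, dtype=complex), np.array(residues, dtype=complex), dt)


def evaluate_components(components, n_samples: int, dt: float = 1.0) -> np.ndarray:
    """Pointwise sum of component evaluations on sample indices 0..n_samples-1."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    out = np.zeros(n_samples)
    for c in components:
        out += c.evaluate(n_samples, dt)
    return out
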