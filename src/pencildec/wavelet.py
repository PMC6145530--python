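"""Complex-Morlet continuous wavelet transform with honest edge reporting.

The scalogram is the magnitude of the convolution of the signal with scaled
complex Morlet atoms.  Scale and period are linked through the wavelet center
frequency fc: period = scale * dt / fc.  Records are finite, so coefficients
near the boundaries are computed against implicit zero padding; the cone of
influence (COI) marks those cells instead of hiding the effect behind
reflection padding.  The COI half-width grows linearly with period: it is the
e-folding time of the Morlet Gaussian envelope, sqrt(bandwidth) * scale
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .timeseries import TimeSeries

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

__all__ = ["Scalogram", "cwt_morlet", "MorletCWT"]


@dataclass(frozen=True)
class Scalogram:
    """CWT magnitudes (period x time) with period/time axes and a COI mask.

    Rows are ordered by increasing period; ``coi_mask`` is True where the
    wavelet support crosses the record boundary (edge-affected cells).
    """

    magnitudes: np.ndarray
    periods: np.ndarray
    times: np.ndarray
    coi_mask: np.ndarray
    complex_coeffs: np.ndarray | None = None

    def ridge_period(self, column: int | None = None) -> float:
        """Period of the magnitude maximum at one time column (default: middle)."""
        j = self.magnitudes.shape[1] // 2 if column is None else column
        return float(self.periods[int(np.argmax(self.magnitudes[:, j]))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.magnitudes, index=self.periods, columns=self.times)


def cwt_morlet(ts: TimeSeries | np.ndarray, periods, *, bandwidth: float = 1.5,
               center_frequency: float = 1.0, dt: float | None = None) -> Scalogram:
    """Complex-Morlet scalogram on a requested period grid (hours).

    Parameters
    ----------
    ts : TimeSeries or 1-D array
    periods : array-like
        Requested periods in hours; each must lie in (2*dt, N*dt).
    bandwidth, center_frequency : float
        Morlet parameters B and fc of the ``cmorB-fc`` wavelet.
    """
    if isinstance(ts, TimeSeries):
        y, dt_ = ts.values, ts.dt
    else:
        y, dt_ = np.asarray(ts, dtype=float).ravel(), 1.0
    if dt is not None:
        dt_ = dt
    periods = np.sort(np.asarray(periods, dtype=float))
    n = y.size
    if np.any(periods <= 2 * dt_) or np.any(periods >= n * dt_):
        raise ValueError(
            f"periods must lie strictly inside (2*dt, N*dt) = ({2 * dt_}, {n * dt_})")
    wavelet = f"cmor{bandwidth}-{center_frequency}"
    scales = periods * center_frequency / dt_
    coeffs, _ = pywt.cwt(y, scales, wavelet)
    times = (np.arange(n) * dt_) + (ts.t0 if isinstance(ts, TimeSeries) else 0.0)
    # e-folding half-width of the Gaussian envelope exp(-t^2/B) at scale s
    half = np.sqrt(bandwidth) * scales[:, None] * dt_
    t_rel = np.arange(n)[None, :] * dt_
    coi = (t_rel < half) | (t_rel > (n - 1) * dt_ - half)
    return Scalogram(magnitudes=np.abs(coeffs), periods=periods, times=times,
                     coi_mask=coi, complex_coeffs=coeffs)


class MorletCWT(BaseEstimator):
    """Transformer-style wrapper: ``fit`` computes the scalogram in ``scalogram_``."""

    def __init__(self, periods=None, bandwidth: float = 1.5,
                 center_frequency: float = 1.0, dt: float | None = None):
        self.periods = periods
        self.bandwidth = bandwidth
        self.center_frequency = center_frequency
        self.dt = dt

    def fit(self, y, X=None):
        if isinstance(y, TimeSeries):
            n, dt_ = len(y), y.dt
        else:
            n, dt_ = np.asarray(y).size, (self.dt or 1.0)
        periods = self.periods
        if periods is None:
            periods = np.geomspace(2.5 * dt_, 0.9 * n * dt_, 64)
        self.scalogram_ = cwt_morlet(y, periods, bandwidth=self.bandwidth,
                                     center_frequency=self.center_frequency,
                                     dt=self.dt)
        return self

    def transform(self, y=None):
        if not hasattr(self, "scalogram_"):
            raise AttributeError("MorletCWT is not fitted yet; call fit first")
        return self.scalogram_.magnitudes
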