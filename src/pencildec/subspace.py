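"""Parametric comparison methods: Prony least squares, ESPRIT, MUSIC, DFT.

All methods share the Hankel snapshot convention of the pencil module: from N
samples a k x (k+1) Hankel matrix is formed (k = N // 2) and its columns are
the M = k + 1 snapshots whose sample covariance R = H H' / M drives the
subspace methods.  ESPRIT estimates poles (frequency and decay) from the
shift invariance of the signal subspace; MUSIC scans the noise-subspace
pseudospectrum and can only place poles on the unit circle (it estimates
frequencies, never decay rates); Prony fits autoregressive coefficients by
least squares and takes the characteristic roots, which noise pulls inside
the unit circle.  Amplitudes for all of them come from a Vandermonde
least-squares fit (:func:`ls_amplitudes`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .pencil import build_hankel
from .timeseries import PoleSet, TimeSeries

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

__all__ = [
    "SubspaceConfig",
    "prony_ls",
    "esprit",
    "music_spectrum",
    "root_music",
    "ls_amplitudes",
    "dft_decompose",
    "Esprit",
    "SpectralMusic",
    "RootMusic",
    "PronyLS",
]


@dataclass(frozen=True)
class SubspaceConfig:
    """Shared knobs: model order K, snapshot length, MUSIC grid resolution."""

    K: int
    hankel_rows: int | None = None  # default: floor(N/2)
    grid_size: int = 4096

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.grid_size < 16:
            raise ValueError("grid_size too small")

    def rows(self, n: int) -> int:
        k = n // 2 if self.hankel_rows is None else self.hankel_rows
        if not (self.K < k <= n // 2 + 1):
            raise ValueError(
                f"need K < hankel_rows <= N/2 + 1 (K={self.K}, rows={k}, N={n})")
        return k


def _values(y) -> tuple[np.ndarray, float]:
    if isinstance(y, TimeSeries):
        return y.values, y.dt
    return np.asarray(y, dtype=float).ravel(), 1.0


def _snapshot_cov(y: np.ndarray, rows: int) -> np.ndarray:
    """Sample covariance of the Hankel snapshot columns (no centering)."""
    cols = y.size - rows + 1
    H = sla.hankel(y[:rows], y[rows - 1:])
    return (H @ H.T) / cols


def prony_ls(y, K: int, dt: float | None = None,
             fit_amplitudes: bool = True) -> PoleSet:
    """Prony's method: least-squares AR coefficients, then characteristic roots.

    Solves ``y[n+K] + g[K-1] y[n+K-1] + ... + g[0] y[n] = 0`` for g by least
    squares over all N - K shifts and returns the roots of
    ``z**K + g[K-1] z**(K-1) + ... + g[0]``.  Noiseless exponential sums with
    exactly K modes are recovered exactly; under noise the estimated poles are
    biased toward the interior of the unit disk.
    """
    y, dt_ = _values(y)
    if dt is not None:
        dt_ = dt
    n = y.size
    if n < 2 * K + 1:
        raise ValueError(f"need N >= 2K+1 samples (N={n}, K={K})")
    rows = n - K
    M = sla.hankel(y[:rows], y[rows - 1:n - 1])  # rows x K, M[i, j] = y[i + j]
    rhs = -y[K:]
    g, _, rank, _ = np.linalg.lstsq(M, rhs, rcond=None)
    if rank < K:
        warnings.warn("rank-deficient Prony system; minimum-norm solution used",
                      stacklevel=2)
    poles = np.roots(np.concatenate(([1.0], g[::-1])))
    ps = PoleSet(poles, np.zeros_like(poles), dt=dt_)
    return ls_amplitudes(y, ps) if fit_amplitudes else ps


def esprit(y, cfg: SubspaceConfig, dt: float | None = None) -> PoleSet:
    """ESPRIT: poles from the shift invariance of the signal subspace.

    The K principal eigenvectors S of the snapshot covariance satisfy
    S2 = S1 Psi with S1/S2 the subspace minus its last/first row; the
    eigenvalues of the least-squares rotation Psi are the poles (frequency
    and decay).  Amplitudes are fitted afterwards by least squares.
    """
    y, dt_ = _values(y)
    if dt is not None:
        dt_ = dt
    rows = cfg.rows(y.size)
    R = _snapshot_cov(y, rows)
    w, v = sla.eigh(R)
    S = v[:, ::-1][:, :cfg.K]  # principal eigenvectors, descending
    S1, S2 = S[:-1, :], S[1:, :]
    psi = np.linalg.lstsq(S1, S2, rcond=None)[0]
    poles = np.linalg.eigvals(psi)
    return ls_amplitudes(y, PoleSet(poles, np.zeros_like(poles), dt=dt_))


def _noise_subspace(y: np.ndarray, cfg: SubspaceConfig) -> np.ndarray:
    rows = cfg.rows(y.size)
    R = _snapshot_cov(y, rows)
    w, v = sla.eigh(R)  # ascending
    return v[:, :rows - cfg.K]


def music_spectrum(y, cfg: SubspaceConfig, dt: float | None = None):
    """Spectral MUSIC: pseudospectrum scan plus the K peak frequencies.

    Returns ``(omega_grid, pseudospectrum, PoleSet)``.  The pseudospectrum is
    ``1 / ||G' e(omega)||**2`` with G the noise-subspace eigenvectors and
    e(omega) the snapshot-length steering vector; peaks are local maxima on
    the circular grid over [0, 2*pi), of which the K largest are reported as
    unit-magnitude poles exp(j*omega).  Decay rates are not estimable.
    """
    y, dt_ = _values(y)
    if dt is not None:
        dt_ = dt
    G = _noise_subspace(np.asarray(y, dtype=float), cfg)
    rows = G.shape[0]
    omega = np.linspace(0.0, 2.0 * np.pi, cfg.grid_size, endpoint=False)
    # steering matrix rows x grid: e(w)_m = exp(j m w)
    E = np.exp(1j * np.outer(np.arange(rows), omega))
    denom = np.sum(np.abs(G.conj().T @ E) ** 2, axis=0)
    pseudo = 1.0 / np.maximum(denom, 1e-300)
    # circular local maxima
    left = np.roll(pseudo, 1)
    right = np.roll(pseudo, -1)
    peaks = np.flatnonzero((pseudo >= left) & (pseudo > right))
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(pseudo))])
    order = peaks[np.argsort(pseudo[peaks])[::-1]]
    sel = order[:cfg.K]
    if sel.size < cfg.K:
        warnings.warn(f"found only {sel.size} pseudospectrum peaks "
                      f"(K={cfg.K})", stacklevel=2)
    poles = np.exp(1j * omega[sel])
    ps = ls_amplitudes(y, PoleSet(poles, np.zeros_like(poles), dt=dt_))
    return omega, pseudo, ps


def root_music(y, cfg: SubspaceConfig, dt: float | None = None) -> PoleSet:
    """Root MUSIC: roots of the null-spectrum polynomial p'(1/z) G G' p(z).

    The K roots with |z| <= 1 closest to the unit circle are selected and
    projected onto the circle for frequency reporting.
    """
    y, dt_ = _values(y)
    if dt is not None:
        dt_ = dt
    G = _noise_subspace(np.asarray(y, dtype=float), cfg)
    rows = G.shape[0]
    Cmat = G @ G.conj().T
    # polynomial coefficients c_l = sum of the l-th diagonal, l = -(rows-1)..rows-1
    coeffs = np.array([np.trace(Cmat, offset=l) for l in range(rows - 1, -rows, -1)])
    roots = np.roots(coeffs)
    inside = roots[np.abs(roots) <= 1.0 + 1e-10]
    inside = inside[np.argsort(np.abs(1.0 - np.abs(inside)))]
    sel = inside[:cfg.K]
    if sel.size < cfg.K:
        warnings.warn("fewer in-disk roots than K", stacklevel=2)
    poles = np.exp(1j * np.angle(sel))
    return ls_amplitudes(y, PoleSet(poles, np.zeros_like(poles), dt=dt_))


def ls_amplitudes(y, poles: PoleSet) -> PoleSet:
    """Vandermonde least-squares fit of complex amplitudes for given poles.

    Replaces the residues of ``poles``.  Nearly coincident poles make the
    Vandermonde system ill-conditioned; a warning with the condition number
    is emitted above 1e10.
    """
    y, _ = _values(y)
    lam = poles.poles
    if lam.size > 1:
        d = np.abs(lam[:, None] - lam[None, :]) + np.eye(lam.size)
        if d.min() < 1e-10:
            raise ValueError("poles must be distinct for amplitude fitting")
    m = np.arange(y.size)
    V = lam[None, :] ** m[:, None]
    cond = np.linalg.cond(V)
    if cond > 1e10:
        warnings.warn(f"ill-conditioned Vandermonde system (cond = {cond:.3e})",
                      stacklevel=2)
    a = np.linalg.lstsq(V, y.astype(complex), rcond=None)[0]
    return PoleSet(lam, a, dt=poles.dt)


def dft_decompose(y, dt: float | None = None):
    """Discrete Fourier decomposition as a (period, amplitude, phase) table.

    The available periods are exactly the grid N*dt/k for k = 0..N//2 (the dc
    row has period inf); an oscillation whose true period falls between grid
    points leaks across bins.  Amplitudes are scaled so a pure cosine of peak
    amplitude A at a grid frequency yields A in its bin.
    """
    import pandas as pd

    y, dt_ = _values(y)
    if dt is not None:
        dt_ = dt
    n = y.size
    spec = np.fft.rfft(y)
    kk = np.arange(spec.size)
    periods = np.full(spec.size, np.inf)
    periods[1:] = n * dt_ / kk[1:]
    amp = np.abs(spec) * 2.0 / n
    amp[0] = np.abs(spec[0]) / n
    if n % 2 == 0:
        amp[-1] = np.abs(spec[-1]) / n
    return pd.DataFrame({
        "period": periods,
        "amplitude": amp,
        "phase": np.angle(spec),
        "energy": np.abs(spec) ** 2,
    })


class _SubspaceEstimatorBase(BaseEstimator):
    """Shared fit plumbing for the pole-estimating baselines."""

    def _store(self, ps: PoleSet):
        from .timeseries import poles_to_components

        self.pole_set_ = ps
        self.poles_ = ps.poles
        self.residues_ = ps.residues
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                self.components_ = tuple(poles_to_components(ps))
            except ValueError:
                self.components_ = ()
        self.periods_ = ps.periods()
        return self


class PronyLS(_SubspaceEstimatorBase):
    """Prony least-squares pole estimator (fit-style wrapper of :func:`prony_ls`)."""

    def __init__(self, K: int = 7, dt: float | None = None):
        self.K = K
        self.dt = dt

    def fit(self, y, X=None):
        return self._store(prony_ls(y, self.K, dt=self.dt))


class Esprit(_SubspaceEstimatorBase):
    """ESPRIT pole estimator."""

    def __init__(self, K: int = 7, hankel_rows: int | None = None,
                 dt: float | None = None):
        self.K = K
        self.hankel_rows = hankel_rows
        self.dt = dt

    def fit(self, y, X=None):
        cfg = SubspaceConfig(K=self.K, hankel_rows=self.hankel_rows)
        return self._store(esprit(y, cfg, dt=self.dt))


class SpectralMusic(_SubspaceEstimatorBase):
    """Spectral MUSIC frequency estimator (poles constrained to |z| = 1)."""

    def __init__(self, K: int = 7, hankel_rows: int | None = None,
                 grid_size: int = 4096, dt: float | None = None):
        self.K = K
        self.hankel_rows = hankel_rows
        self.grid_size = grid_size
        self.dt = dt

    def fit(self, y, X=None):
        cfg = SubspaceConfig(K=self.K, hankel_rows=self.hankel_rows,
                             grid_size=self.grid_size)
        self.omega_grid_, self.pseudospectrum_, ps = music_spectrum(y, cfg, dt=self.dt)
        return self._store(ps)


class RootMusic(_SubspaceEstimatorBase):
    """Root MUSIC frequency estimator."""

    def __init__(self, K: int = 7, hankel_rows: int | None = None,
                 dt: float | None = None):
        self.K = K
        self.hankel_rows = hankel_rows
        self.dt = dt

    def fit(self, y, X=None):
        cfg = SubspaceConfig(K=self.K, hankel_rows=self.hankel_rows)
        return self._store(root_music(y, cfg, dt=self.dt))
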