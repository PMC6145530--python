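"""The matrix-pencil decomposition.

Given N uniform samples, the method stacks the first 2k samples (k = N // 2)
into a k x (k+1) Hankel matrix H and reads off a raw descriptor model

    E = H[:, :k],  A = H[:, 1:],  B = H[:, 0],  C = H[0, :k],

i.e. the discrete-time system E x[n+1] = A x[n], y[n] = C x[n], E x[0] = B.
The dominant order-r subsystem is obtained by projecting with the leading
singular vectors of the horizontal concatenation [E, A] (columns X) and of the
vertical stack [E; A] (rows Y):

    Er = X' E Y,  Ar = X' A Y,  Br = X' B,  Cr = C Y.

The generalized eigenvalues of the pencil (Ar, Er) are the signal poles
lambda_i = exp(sigma_i + j omega_i); the partial-fraction residues
P_i = (Cr v_i)(vhat_i Er^{-1} Br) reconstruct the data as
y_hat[n] = sum_i P_i lambda_i**(n-1).  The order r is chosen by the singular
value ratio rule sigma_r / sigma_1 >= epsilon (default epsilon = 0.01), with a
bump of one when truncation would split a conjugate pole pair.

On exact sums of m damped cosines (2m+1 <= k) with r equal to the true model
order, the recovery of poles and residues is exact to machine precision; under
additive noise the pencil projection is what makes the estimates robust.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .timeseries import (
    DecompositionResult,
    PoleSet,
    TimeSeries,
    angle_degrees,
    poles_to_components,
)

try:  # BaseEstimator gives get_params/set_params for pipeline compatibility
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

__all__ = [
    "PencilModel",
    "ReducedModel",
    "build_hankel",
    "raw_model",
    "select_order",
    "reduce_model",
    "eig_poles",
    "decompose",
    "orthogonality_report",
    "MatrixPencil",
]


@dataclass(frozen=True)
class PencilModel:
    """Raw descriptor quadruple (E, A, B, C) plus the two singular spectra.

    ``s1`` are the singular values of the vertical stack [E; A] (2k x k),
    ``s2`` those of the horizontal concatenation [E, A] (k x 2k).
    """

    E: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    s1: np.ndarray
    s2: np.ndarray

    @property
    def k(self) -> int:
        return self.E.shape[0]


@dataclass(frozen=True)
class ReducedModel:
    """Order-r projection of a raw model, with the projectors used."""

    Er: np.ndarray
    Ar: np.ndarray
    Br: np.ndarray
    Cr: np.ndarray
    X: np.ndarray
    Y: np.ndarray

    @property
    def r(self) -> int:
        return self.Er.shape[0]


def build_hankel(y) -> np.ndarray:
    """Hankel matrix H[i, j] = y[i + j] (0-based) of shape k x (k+1), k = N // 2.

    Only the first 2k samples are used; with N odd the last sample does not
    enter the model (it still counts in approximation errors downstream).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 samples for a nontrivial pencil")
    k = n // 2
    return sla.hankel(y[:k], y[k - 1:2 * k])


def raw_model(H: np.ndarray) -> PencilModel:
    """Extract the raw quadruple and the two singular spectra from a Hankel matrix."""
    H = np.asarray(H, dtype=float)
    k = H.shape[0]
    if H.shape[1] != k + 1:
        raise ValueError("expected a k x (k+1) Hankel matrix")
    E = H[:, :k]
    A = H[:, 1:k + 1]
    B = H[:, 0].copy()
    C = H[0, :k].copy()
    s1 = sla.svdvals(np.vstack([E, A]))
    s2 = sla.svdvals(np.hstack([E, A]))
    return PencilModel(E=E, A=A, B=B, C=C, s1=s1, s2=s2)


def select_order(s, epsilon: float = 0.01) -> int:
    """Number of singular values with s[i] / s[0] >= epsilon.

    ``epsilon = 0`` keeps everything (no truncation).  The conjugate-pair
    protection (bumping r by one when a pair would be split) is applied later,
    once the eigenvalues are known — see :func:`decompose`.
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("singular values are all zero; nothing to model")
    if epsilon <= 0:
        return int(s.size)
    return int(np.count_nonzero(s / s[0] >= epsilon)) or 1


def reduce_model(model: PencilModel, r: int) -> ReducedModel:
    """Project the raw model onto its dominant order-r subsystem."""
    k = model.k
    if not (1 <= r <= k):
        raise ValueError(f"order r must be in [1, {k}], got {r}")
    # X: leading left singular vectors of [E, A]; Y: leading right singular
    # vectors of [E; A].
    u2, _, _ = sla.svd(np.hstack([model.E, model.A]), full_matrices=False)
    _, _, v1t = sla.svd(np.vstack([model.E, model.A]), full_matrices=False)
    X = u2[:, :r]
    Y = v1t[:r, :].T
    return ReducedModel(
        Er=X.T @ model.E @ Y,
        Ar=X.T @ model.A @ Y,
        Br=X.T @ model.B,
        Cr=model.C @ Y,
        X=X,
        Y=Y,
    )


def eig_poles(reduced: ReducedModel, dt: float = 1.0) -> PoleSet:
    """Poles and residues from the generalized eigenproblem of (Ar, Er).

    Solved QZ-style (scipy's generalized solver) rather than by forming
    Er^{-1} Ar; infinite or overflowing eigenvalues are dropped with a warning.
    Residues are P_i = (Cr v_i) * (vhat_i Er^{-1} Br) with vhat_i the rows of
    the inverse right-eigenvector matrix.
    """
    lam, V = sla.eig(reduced.Ar, reduced.Er)
    finite = np.isfinite(lam) & (np.abs(lam) < 1e12)
    if not np.all(finite):
        warnings.warn(
            f"dropped {int(np.count_nonzero(~finite))} infinite generalized "
            "eigenvalue(s) (nearly singular Er)", stacklevel=2)
    condV = np.linalg.cond(V)
    if not np.isfinite(condV) or condV > 1e14:
        raise np.linalg.LinAlgError(
            "defective pencil: eigenvector basis is numerically singular "
            f"(cond ~ {condV:.2e})")
    # initial-condition vector in modal coordinates
    btilde = sla.lstsq(reduced.Er, reduced.Br.astype(complex),
                       lapack_driver="gelsd")[0]
    Vinv = np.linalg.inv(V)
    residues = (reduced.Cr.astype(complex) @ V) * (Vinv @ btilde)
    return PoleSet(lam[finite], residues[finite], dt=dt)


def _conjugate_closed(poles: np.ndarray, tol: float = 1e-6) -> bool:
    for lam in poles:
        if abs(lam.imag) <= tol * max(1.0, abs(lam)):
            continue
        d = np.abs(poles - lam.conjugate())
        if d.min() > tol * max(1.0, abs(lam)):
            return False
    return True


def decompose(ts: TimeSeries | np.ndarray, order: int | str = "auto",
              epsilon: float = 0.01, dt: float | None = None,
              center: bool = False) -> DecompositionResult:
    """Full pencil decomposition of one series.

    Chains Hankel construction -> raw model -> order selection -> projection ->
    generalized eigen-decomposition -> component conversion.  The approximant
    is evaluated over all N input samples and the relative error is
    ``||y - y_hat|| / ||y||``.

    Parameters
    ----------
    ts : TimeSeries or 1-D array
        Input record (dt taken from the TimeSeries unless overridden).
    order : int or "auto"
        Reduced order r; "auto" applies the singular-value ratio rule with
        ``epsilon`` to the pencil spectrum s2.
    epsilon : float
        Tolerance of the order rule (0 keeps the full order k).
    center : bool
        Subtract the mean before modeling (off by default: the trend is
        modeled as a dc pole near 1 rather than removed).
    """
    if isinstance(ts, TimeSeries):
        y = ts.values
        dt_ = ts.dt if dt is None else dt
    else:
        y = np.asarray(ts, dtype=float).ravel()
        dt_ = 1.0 if dt is None else dt
    mean = y.mean() if center else 0.0
    yc = y - mean

    H = build_hankel(yc)
    model = raw_model(H)
    k = model.k
    if order == "auto":
        r = select_order(model.s2, epsilon)
    else:
        r = int(order)
        if not (1 <= r <= k):
            raise ValueError(f"order must be in [1, {k}], got {r}")

    pole_set = eig_poles(reduce_model(model, r), dt=dt_)
    if r < k and not _conjugate_closed(pole_set.poles):
        # truncation split a conjugate pair; keep one more direction
        pole_set = eig_poles(reduce_model(model, r + 1), dt=dt_)
        r += 1

    n = y.size
    yhat = pole_set.evaluate(n)
    if np.max(np.abs(yhat.imag)) > 1e-6 * max(1.0, np.max(np.abs(yhat.real))):
        warnings.warn("approximant has a non-negligible imaginary part "
                      "(unpaired complex poles); taking the real part",
                      stacklevel=2)
    yhat = yhat.real + mean
    residual = y - yhat
    norm_y = np.linalg.norm(y)
    rel_err = float(np.linalg.norm(residual) / norm_y) if norm_y > 0 else 0.0

    t0 = ts.t0 if isinstance(ts, TimeSeries) else 0.0
    label = ts.label if isinstance(ts, TimeSeries) else ""
    return DecompositionResult(
        components=tuple(poles_to_components(pole_set)),
        pole_set=pole_set,
        approximant=TimeSeries(yhat, t0=t0, dt=dt_, label=label),
        residual=TimeSeries(residual, t0=t0, dt=dt_, label=label),
        relative_error=rel_err,
        order=r,
        singular_values=model.s2,
    )


def orthogonality_report(result: DecompositionResult,
                         original: TimeSeries | np.ndarray) -> dict:
    """Angles (degrees) between extracted components and between fit and error.

    Returns a dict with ``pairwise`` (DataFrame of angles between the sampled
    component vectors f_i, labeled by period) and ``approximant_vs_error`` (the
    angle between y_hat and y - y_hat).  Near-90 angles indicate that the
    oscillations are mutually independent contributions to the record.
    Zero-norm components are flagged in ``skipped`` and omitted.
    """
    import pandas as pd

    y = original.values if isinstance(original, TimeSeries) else np.asarray(original)
    n = y.size
    dt = result.approximant.dt
    vectors, labels, skipped = [], [], []
    for c in result.components:
        v = c.evaluate(n, dt)
        lbl = f"T={c.period_label(2)}"
        if np.linalg.norm(v) == 0.0:
            skipped.append(lbl)
            continue
        vectors.append(v)
        labels.append(lbl)
    m = len(vectors)
    pw = np.full((m, m), np.nan)
    for i in range(m):
        pw[i, i] = 0.0
        for j in range(i + 1, m):
            pw[i, j] = pw[j, i] = angle_degrees(vectors[i], vectors[j])
    pairwise = pd.DataFrame(pw, index=labels, columns=labels)
    err = y - result.approximant.values
    ang = (angle_degrees(result.approximant.values, err)
           if np.linalg.norm(err) > 0 and np.linalg.norm(result.approximant.values) > 0
           else math.nan)
    return {"pairwise": pairwise, "approximant_vs_error": ang, "skipped": skipped}


class MatrixPencil(BaseEstimator):
    """Matrix-pencil decomposition as a fit-style estimator.

    Parameters
    ----------
    order : int or "auto", default "auto"
        Reduced model order r ("auto" = singular-value ratio rule).
    epsilon : float, default 0.01
        Tolerance of the order rule.
    dt : float or None, default None
        Sampling interval in hours; None takes it from a TimeSeries input
        (and defaults to 1.0 for plain arrays).
    center : bool, default False
        Mean-center before modeling.

    Attributes
    ----------
    result_ : DecompositionResult
    components_ : tuple of OscillationComponent
    poles_ : ndarray of complex poles
    residues_ : ndarray of complex residues
    order_ : int, the order actually used
    relative_error_ : float
    singular_values_ : ndarray (pencil spectrum s2)

    Examples
    --------
    >>> from pencildec import MatrixPencil, simulate
    >>> ts = simulate.generate(simulate.SimulationSpec(n_samples=50))
    >>> mp = MatrixPencil(order=7).fit(ts)
    >>> sorted(round(p, 1) for p in mp.periods_ if p != float("inf"))
    [7.5, 11.8, 24.8]
    """

    def __init__(self, order="auto", epsilon: float = 0.01,
                 dt: float | None = None, center: bool = False):
        self.order = order
        self.epsilon = epsilon
        self.dt = dt
        self.center = center

    def fit(self, y, X=None):
        """Decompose one series (TimeSeries or 1-D array)."""
        self.result_ = decompose(y, order=self.order, epsilon=self.epsilon,
                                 dt=self.dt, center=self.center)
        self.components_ = self.result_.components
        self.pole_set_ = self.result_.pole_set
        self.poles_ = self.result_.pole_set.poles
        self.residues_ = self.result_.pole_set.residues
        self.order_ = self.result_.order
        self.relative_error_ = self.result_.relative_error
        self.singular_values_ = self.result_.singular_values
        self.periods_ = tuple(c.period for c in self.components_)
        return self

    def transform(self, y=None):
        """Return the fitted approximant values."""
        self._check_fitted()
        return self.result_.approximant.values

    def fit_transform(self, y, X=None):
        return self.fit(y).transform()

    def orthogonality(self, original) -> dict:
        self._check_fitted()
        return orthogonality_report(self.result_, original)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise AttributeError("MatrixPencil is not fitted yet; call fit first")
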