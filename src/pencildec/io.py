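"""Expression-matrix I/O and cohort scanning.

The on-disk dialect is TSV (or CSV) with optional ``# key=value`` comment
headers.  Two layouts are supported, mirroring the common supplementary-data
conventions: ``time-row`` (first row holds the time grid in hours, remaining
rows are measurements) and ``genes-rows`` (every row is a measurement series
on an implicit hourly grid 1..N, with row labels in the first column).
Internally everything becomes an :class:`ExpressionMatrix` of
:class:`~pencildec.timeseries.TimeSeries` sharing one uniform grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix", "cohort_scan"]

#: relative tolerance on time-grid uniformity
UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class ExpressionMatrix:
    """A set of series sharing one uniform time grid (hours)."""

    series: tuple
    time: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        if len(self.series) < 1:
            raise ValueError("need at least one series")
        n = len(self.series[0])
        if any(len(s) != n for s in self.series):
            raise ValueError("all rows must have equal length")
        if len(self.labels) != len(self.series):
            raise ValueError("one label per series required")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def dt(self) -> float:
        return self.series[0].dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.values for s in self.series],
                            index=list(self.labels), columns=self.time)

    def mean_series(self, label: str = "mean") -> TimeSeries:
        """Average of all rows (e.g. averaging animals before decomposition)."""
        vals = np.mean([s.values for s in self.series], axis=0)
        s0 = self.series[0]
        return TimeSeries(vals, t0=s0.t0, dt=s0.dt, label=label)


def _check_uniform(time: np.ndarray) -> float:
    diffs = np.diff(time)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0))
        raise ValueError(f"time grid not strictly increasing at index {bad}")
    dt = float(np.mean(diffs))
    rel = np.abs(diffs - dt) / dt
    if np.any(rel > UNIFORM_RTOL):
        bad = int(np.argmax(rel > UNIFORM_RTOL))
        raise ValueError(
            f"non-uniform time grid at index {bad}: step {diffs[bad]:.6g} "
            f"vs mean {dt:.6g}")
    return dt


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: empty file")


def read_matrix(path: str, orientation: str = "time-row") -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV.

    Parameters
    ----------
    path : str
    orientation : {"time-row", "genes-rows"}
        ``time-row``: first data row is the time grid (hours); remaining rows
        are series, optionally labeled in the first column.  ``genes-rows``:
        every row is ``label, v1..vN`` on the implicit hourly grid t = 1..N.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[0] < 1 or df.shape[1] < 2:
        raise ValueError(f"{path}: matrix too small ({df.shape})")

    first_col_labels = not pd.api.types.is_numeric_dtype(df.iloc[:, 0])
    if first_col_labels:
        labels_col = df.iloc[:, 0].astype(str).tolist()
        body = df.iloc[:, 1:]
    else:
        labels_col = [f"row{i + 1}" for i in range(df.shape[0])]
        body = df
    try:
        values = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in data block: {exc}") from None
    if np.any(~np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{path}: non-finite value at row {i}, column {j}")

    if orientation == "time-row":
        if values.shape[0] < 2:
            raise ValueError(f"{path}: time-row layout needs >= 2 rows")
        time = values[0]
        dt = _check_uniform(time)
        data = values[1:]
        labels = labels_col[1:]
    elif orientation == "genes-rows":
        time = np.arange(1, values.shape[1] + 1, dtype=float)
        dt = 1.0
        data = values
        labels = labels_col
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    series = tuple(
        TimeSeries(row, t0=float(time[0]), dt=dt, label=lbl)
        for row, lbl in zip(data, labels))
    return ExpressionMatrix(series=series, time=time, labels=tuple(labels))


def write_matrix(matrix: ExpressionMatrix, path: str,
                 orientation: str = "time-row", header: dict | None = None) -> None:
    """Write a matrix in the TSV dialect with an optional ``# key=value`` header."""
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        if orientation == "time-row":
            fh.write("time\t" + "\t".join(f"{t:.10g}" for t in matrix.time) + "\n")
            for s in matrix.series:
                fh.write(s.label + "\t"
                         + "\t".join(f"{v:.10g}" for v in s.values) + "\n")
        elif orientation == "genes-rows":
            for s in matrix.series:
                fh.write(s.label + "\t"
                         + "\t".join(f"{v:.10g}" for v in s.values) + "\n")
        else:
            raise ValueError(f"unknown orientation {orientation!r}")


_METHOD_NAMES = ("pencil", "esprit", "prony", "music", "root-music")


def _fit_method(method: str, ts: TimeSeries, order):
    from . import pencil as _pencil
    from . import subspace as _subspace

    if method == "pencil":
        est = _pencil.MatrixPencil(order=order)
    elif method == "esprit":
        K = order if isinstance(order, int) else 7
        est = _subspace.Esprit(K=K)
    elif method == "prony":
        K = order if isinstance(order, int) else 7
        est = _subspace.PronyLS(K=K)
    elif method == "music":
        K = order if isinstance(order, int) else 7
        est = _subspace.SpectralMusic(K=K)
    elif method == "root-music":
        K = order if isinstance(order, int) else 7
        est = _subspace.RootMusic(K=K)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {_METHOD_NAMES}")
    return est.fit(ts)


def _select_pole(poles: np.ndarray, periods: np.ndarray,
                 target_period: float) -> complex | None:
    """The non-dc pole (positive frequency) with period nearest the target."""
    mask = np.isfinite(periods) & (np.imag(poles) > 0)
    if not np.any(mask):
        mask = np.isfinite(periods)
    if not np.any(mask):
        return None
    idx = np.flatnonzero(mask)
    return complex(poles[idx[np.argmin(np.abs(periods[idx] - target_period))]])


def cohort_scan(matrix: ExpressionMatrix, methods=("pencil",),
                order=7, target_period: float = 12.0):
    """Run pole-estimating methods across a cohort of series.

    For every series and method the pole with period nearest ``target_period``
    hours is selected and its magnitude recorded; ideal sustained oscillations
    have magnitude 1.  Per-series failures are logged and skipped, never
    fatal.

    Returns ``(per_series, summary)``: a tidy DataFrame with one row per
    (series, method) and a summary DataFrame with the mean and sd of the
    selected pole magnitudes per method.
    """
    methods = tuple(methods)
    if not methods:
        raise ValueError("need at least one method")
    rows = []
    for ts in matrix.series:
        for method in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = _fit_method(method, ts, order)
                pole = _select_pole(est.poles_, est.pole_set_.periods(),
                                    target_period)
            except Exception as exc:
                warnings.warn(f"{method} failed on {ts.label!r}: {exc}",
                              stacklevel=2)
                continue
            if pole is None:
                continue
            w = abs(np.angle(pole))
            rows.append({
                "label": ts.label,
                "method": method,
                "pole_magnitude": abs(pole),
                "period": math.inf if w < 1e-9 else 2 * math.pi * ts.dt / w,
            })
    per_series = pd.DataFrame(rows,
                              columns=["label", "method", "pole_magnitude",
                                       "period"])
    if per_series.empty:
        raise RuntimeError("every series failed for every method")
    summary = (per_series.groupby("method")["pole_magnitude"]
               .agg(["mean", "std", "count"]).reset_index())
    return per_series, summary
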