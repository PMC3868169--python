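"""Signal-level cleaning of voxel time series.

The pipeline order is: linear detrend -> band-pass 0.01-0.08 Hz -> optional
nuisance regression. The band-pass is a Butterworth filter (order 4 per band
edge) applied forward-backward (zero phase) with even (reflect) padding, the
standard resting-state choice when the acquisition pipeline does not dictate
one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

DEFAULT_BAND = (0.01, 0.08)
DEFAULT_FILTER_ORDER = 4


@dataclass
class NuisanceSet:
    """T x K matrix of nuisance regressors (motion, global mean, WM, CSF...)."""

    matrix: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.ndim != 2:
            raise ValueError("nuisance matrix must be T x K")
        if not self.labels:
            self.labels = tuple(f"nuis{k}" for k in range(self.matrix.shape[1]))

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


def detrend_linear(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Remove the least-squares linear trend (intercept + slope).

    The output has zero mean and is orthogonal to the time ramp. Works on a
    vector or along ``axis`` of a matrix.
    """
    series = np.asarray(series, dtype=np.float64)
    t = series.shape[axis]
    if t < 3:
        raise ValueError("need at least 3 time points to detrend")
    x = np.moveaxis(series, axis, 0)
    ramp = np.arange(t, dtype=np.float64)
    ramp -= ramp.mean()
    out = x - x.mean(axis=0)
    slope = np.tensordot(ramp, out, axes=(0, 0)) / (ramp @ ramp)
    out -= np.multiply.outer(ramp, slope)
    return np.moveaxis(out, 0, axis)


def bandpass_sos(tr: float, low: float, high: float, order: int):
    """Second-order sections of the Butterworth band-pass for sampling 1/tr."""
    nyq = 1.0 / (2.0 * tr)
    if not (0.0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz for TR={tr}s")
    return signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")


def bandpass(
    series: np.ndarray,
    tr: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    Forward-backward application preserves phase; reflect padding keeps the
    short series (T ~ 170) free of edge transients.
    """
    series = np.asarray(series, dtype=np.float64)
    sos = bandpass_sos(tr, low, high, order)
    padlen = min(3 * (2 * sos.shape[0] + 1), series.shape[axis] - 1)
    return signal.sosfiltfilt(sos, series, axis=axis, padtype="even", padlen=padlen)


def regress_nuisance(series: np.ndarray, nuis: NuisanceSet | None) -> np.ndarray:
    """OLS residual of ``series`` on [intercept | nuisance regressors].

    With K=0 this reduces to mean-centering. Collinear columns are dropped
    with a warning (rank-deficient designs would otherwise make the residual
    depend on the solver).
    """
    series = np.asarray(series, dtype=np.float64)
    one_d = series.ndim == 1
    y = series[:, None] if one_d else series
    t = y.shape[0]
    design = np.ones((t, 1))
    if nuis is not None and nuis.n_regressors > 0:
        if nuis.matrix.shape[0] != t:
            raise ValueError("nuisance rows must align with time points")
        design = np.column_stack([design, nuis.matrix])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            keep = [0]
            for j in range(1, design.shape[1]):
                cand = design[:, keep + [j]]
                if np.linalg.matrix_rank(cand) == len(keep) + 1:
                    keep.append(j)
            warnings.warn(
                f"nuisance design rank-deficient; dropped "
                f"{design.shape[1] - len(keep)} collinear column(s)",
                stacklevel=2,
            )
            design = design[:, keep]
    if t <= design.shape[1]:
        raise ValueError("need T > number of regressors + 1")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid[:, 0] if one_d else resid


def preprocess_series(
    series: np.ndarray,
    tr: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
    nuisance: NuisanceSet | None = None,
    axis: int = 0,
) -> np.ndarray:
    """Full cleaning pipeline: detrend -> band-pass -> nuisance regression."""
    out = detrend_linear(series, axis=axis)
    out = bandpass(out, tr, low=low, high=high, order=order, axis=axis)
    if nuisance is not None and nuisance.n_regressors > 0:
        if axis != 0:
            out = np.moveaxis(out, axis, 0)
        out = regress_nuisance(out, nuisance)
        if axis != 0:
            out = np.moveaxis(out, 0, axis)
    return out
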