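"""Minimum-norm source estimation with per-frame GCV regularization.

Sensor data ``phi`` (n_sensors x n_frames) is mapped to source amplitudes
through a lead field ``L`` (n_sensors x n_sources, underdetermined) via the
regularized minimum-norm solution

    S = L.T @ (L @ L.T + lam * I)^-1 @ phi

with ``lam`` chosen per frame by generalized cross-validation (GCV) and the
resulting lambda series cleaned of outliers by linear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)


@dataclass
class LeadField:
    """Linear forward operator from source amplitudes to sensor readings."""

    L: np.ndarray  # (n_sensors, n_sources)

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2:
            raise ValueError("lead field must be a 2-D matrix")
        if not np.all(np.isfinite(self.L)):
            raise ValueError("lead field contains non-finite entries")

    @property
    def n_sensors(self) -> int:
        return self.L.shape[0]

    @property
    def n_sources(self) -> int:
        return self.L.shape[1]

    def gram(self) -> np.ndarray:
        """The sensor-space Gram matrix L @ L.T."""
        return self.L @ self.L.T


@dataclass
class SensorSeries:
    """Multichannel sensor time series (n_sensors x n_frames)."""

    phi: np.ndarray
    fs: float

    def __post_init__(self):
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.phi.shape[1]


@dataclass
class SourceSeries:
    """Estimated or simulated source amplitudes (n_sources x n_frames)."""

    S: np.ndarray
    fs: float

    def __post_init__(self):
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))


@dataclass
class LambdaSeries:
    """Per-frame regularization parameters with an outlier-repair mask."""

    values: np.ndarray
    outlier_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool).ravel()


def mne_inverse(lead_field: LeadField, sensor_frame: np.ndarray, lam: float) -> np.ndarray:
    """Regularized minimum-norm estimate of source amplitudes.

    Computes ``L.T @ (L @ L.T + lam * I)^-1 @ phi``. ``sensor_frame`` may be
    a single frame (vector) or a matrix of frames (n_sensors x n_frames)
    sharing one lambda; the estimate is linear in the frame.
    """
    if isinstance(lead_field, np.ndarray):
        lead_field = LeadField(lead_field)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    L = lead_field.L
    phi = np.asarray(sensor_frame, dtype=float)
    G = lead_field.gram() + lam * np.eye(lead_field.n_sensors)
    try:
        c, low = scipy.linalg.cho_factor(G)
        x = scipy.linalg.cho_solve((c, low), phi)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "L @ L.T + lam*I is singular: lead field is rank deficient "
            f"(rank {np.linalg.matrix_rank(L)} < {lead_field.n_sensors} sensors) "
            "and lam=0 is not usable"
        )
    return L.T @ x


def default_lambda_grid(lead_field: LeadField, n_points: int = 30) -> np.ndarray:
    """Log-spaced lambda grid over [1e-6, 1e2] x mean eigenvalue of L@L.T."""
    scale = np.trace(lead_field.gram()) / lead_field.n_sensors
    return scale * np.logspace(-6, 2, n_points)


def gcv_score(lead_field: LeadField, sensor_frame: np.ndarray, lam: float) -> float:
    """The GCV statistic n*||(I - A)phi||^2 / trace(I - A)^2 at one lambda."""
    G = lead_field.gram()
    n = G.shape[0]
    M = G + lam * np.eye(n)
    A = G @ np.linalg.inv(M)
    resid = (np.eye(n) - A) @ np.asarray(sensor_frame, dtype=float)
    denom = np.trace(np.eye(n) - A) ** 2
    if denom == 0:
        return np.inf
    return n * float(resid @ resid) / denom


def gcv_select_lambda(
    lead_field: LeadField,
    sensor_frame: np.ndarray,
    lam_grid: np.ndarray | None = None,
    _eig=None,
) -> float:
    """Pick lambda from a grid by minimizing generalized cross-validation.

    GCV(lam) = n * ||(I - A(lam)) phi||^2 / trace(I - A(lam))^2 with the
    influence matrix A(lam) = L@L.T @ (L@L.T + lam I)^-1. Ties break toward
    the smaller lambda. Grid points where trace(I - A) vanishes are skipped.
    """
    if isinstance(lead_field, np.ndarray):
        lead_field = LeadField(lead_field)
    if lam_grid is None:
        lam_grid = default_lambda_grid(lead_field)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(np.diff(lam_grid) < 0):
        raise ValueError("lambda grid must be sorted ascending")
    if _eig is None:
        _eig = scipy.linalg.eigh(lead_field.gram())
    d, U = _eig
    phi = np.asarray(sensor_frame, dtype=float).ravel()
    z = U.T @ phi
    n = d.size
    best_lam, best_score = None, np.inf
    for lam in lam_grid:
        shrink = lam / (d + lam)  # diagonal of I - A(lam) in the eigenbasis
        denom = shrink.sum() ** 2
        if denom == 0:
            logger.warning("trace(I - A) = 0 at lambda=%g; grid point skipped", lam)
            continue
        score = n * float(np.sum((shrink * z) ** 2)) / denom
        if score < best_score:  # strict: ties keep the earlier (smaller) lambda
            best_lam, best_score = float(lam), score
    if best_lam is None:
        raise ValueError("no usable lambda on the grid")
    return best_lam


def gcv_lambda_series(
    lead_field: LeadField,
    sensors: SensorSeries | np.ndarray,
    lam_grid: np.ndarray | None = None,
) -> LambdaSeries:
    """GCV-selected lambda for every frame of a sensor series.

    Frames are independent, so the result does not depend on frame order.
    """
    if isinstance(lead_field, np.ndarray):
        lead_field = LeadField(lead_field)
    phi = sensors.phi if isinstance(sensors, SensorSeries) else np.atleast_2d(sensors)
    if lam_grid is None:
        lam_grid = default_lambda_grid(lead_field)
    eig = scipy.linalg.eigh(lead_field.gram())
    vals = np.array(
        [
            gcv_select_lambda(lead_field, phi[:, t], lam_grid, _eig=eig)
            for t in range(phi.shape[1])
        ]
    )
    return LambdaSeries(vals)


def regularize_lambda_series(
    lam_series: LambdaSeries | np.ndarray,
    n_sd: float = 3.0,
    log_scale: bool = False,
) -> LambdaSeries:
    """Repair outlying lambda values by interpolating from their neighbors.

    Values farther than ``n_sd`` standard deviations from the whole-series
    mean are replaced by linear interpolation between the nearest non-outlier
    neighbors; outliers at the ends take the nearest valid value. With
    ``log_scale`` the outlier statistics are computed on log10(lambda), which
    is often better behaved since lambda can span decades.
    """
    if isinstance(lam_series, LambdaSeries):
        vals = lam_series.values.copy()
    else:
        vals = np.asarray(lam_series, dtype=float).ravel().copy()
    if vals.size < 3:
        raise ValueError("lambda series must have length >= 3")
    stat = np.log10(vals) if log_scale else vals
    sd = stat.std()
    if sd == 0:
        return LambdaSeries(vals)  # constant series: no outliers by definition
    mask = np.abs(stat - stat.mean()) > n_sd * sd
    if mask.all():
        raise ValueError("every lambda flagged as an outlier; series degenerate")
    if mask.any():
        good = np.flatnonzero(~mask)
        vals[mask] = np.interp(np.flatnonzero(mask), good, vals[good])
    return LambdaSeries(vals, mask)


def inverse_series(
    lead_field: LeadField,
    sensors: SensorSeries,
    lam_series: LambdaSeries | None = None,
    lam_grid: np.ndarray | None = None,
    n_sd: float = 3.0,
) -> tuple[SourceSeries, LambdaSeries]:
    """Full inverse stage: per-frame GCV, lambda repair, minimum-norm solve."""
    if lam_series is None:
        lam_series = regularize_lambda_series(
            gcv_lambda_series(lead_field, sensors, lam_grid), n_sd=n_sd
        )
    S = np.empty((lead_field.n_sources, sensors.n_frames))
    for t in range(sensors.n_frames):
        S[:, t] = mne_inverse(lead_field, sensors.phi[:, t], lam_series.values[t])
    return SourceSeries(S, sensors.fs), lam_series
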