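"""Time-averaged network estimation: STFT series, temporal ICA, beta maps.

The pipeline: z-score sensor channels, take non-overlapping 1-s STFT
windows (1 Hz bins), average complex coefficients over the alpha bins,
concatenate participants along the window axis, unmix with a complex-valued
fixed-point ICA, project time-domain alpha data through the demixing matrix
for component time courses, and regress per-source envelope time courses on
the component envelopes to obtain participant beta maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._util import check_rng
from .envelope import hilbert_envelope

logger = logging.getLogger(__name__)


@dataclass
class SpectralSeries:
    """Complex STFT coefficients (channels x frequency bins x windows)."""

    coeffs: np.ndarray
    freqs: np.ndarray  # Hz, one per bin
    window_s: float
    fs: float

    @property
    def n_windows(self) -> int:
        return self.coeffs.shape[2]


@dataclass
class ICModel:
    """Unmixing/mixing matrices and downstream network representations."""

    W: np.ndarray  # (components x channels) demixing
    A: np.ndarray  # (channels x components) mixing (pseudo-inverse of W)
    sources: np.ndarray  # component series on the training data
    neuronal_ids: list = None  # retained component indices (default: all)
    participant_betas: dict = field(default_factory=dict)  # pid -> (comp x sources)
    group_betas: np.ndarray = None

    @property
    def n_components(self) -> int:
        return self.W.shape[0]

    def __post_init__(self):
        if self.neuronal_ids is None:
            self.neuronal_ids = list(range(self.W.shape[0]))


def stft_spectral_series(
    eeg: np.ndarray,
    fs: float,
    max_freq: float = 100.0,
    window_s: float = 1.0,
    zscore_channels: bool = True,
) -> SpectralSeries:
    """Non-overlapping rectangular-window STFT at integer frequencies.

    Each ``window_s`` segment is Fourier transformed; bins run from 0 Hz to
    ``max_freq`` in steps of ``1 / window_s``. A trailing partial window is
    dropped (logged). Channels are z-scored across time first, mirroring the
    convention used before group concatenation.
    """
    X = np.atleast_2d(np.asarray(eeg, dtype=float))
    if fs < 2 * max_freq:
        raise ValueError(f"fs={fs} cannot resolve {max_freq} Hz")
    if zscore_channels:
        sd = X.std(axis=1, keepdims=True, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance channel; cannot z-score")
        X = (X - X.mean(axis=1, keepdims=True)) / sd
    win = int(round(window_s * fs))
    n_win = X.shape[1] // win
    if n_win < 2:
        raise ValueError("need at least 2 full windows")
    dropped = X.shape[1] - n_win * win
    if dropped:
        logger.info("stft: trailing partial window of %d samples dropped", dropped)
    segs = X[:, : n_win * win].reshape(X.shape[0], n_win, win)
    spec = np.fft.rfft(segs, axis=2) / win  # (channels, windows, bins)
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    keep = freqs <= max_freq + 1e-9
    return SpectralSeries(
        spec[:, :, keep].transpose(0, 2, 1), freqs[keep], window_s, fs
    )


def alpha_band_average(spec: SpectralSeries, band=(8.0, 12.0)) -> np.ndarray:
    """Mean complex coefficient over the inclusive band bins, per window."""
    sel = (spec.freqs >= band[0] - 1e-9) & (spec.freqs <= band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return spec.coeffs[:, sel, :].mean(axis=1)  # (channels, windows)


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    M = W.conj().T @ W
    d, E = scipy.linalg.eigh(M)
    d = np.maximum(d, 1e-12)
    return W @ (E @ np.diag(1.0 / np.sqrt(d)) @ E.conj().T)


def complex_fastica(
    X: np.ndarray,
    n_components: int,
    seed=0,
    max_iter: int = 500,
    tol: float = 1e-7,
    a1: float = 0.1,
):
    """Fixed-point ICA for circular complex signals.

    Symmetric-decorrelation variant with the smooth nonlinearity
    ``G(y) = sqrt(a1 + y)`` applied to ``y = |w^H z|^2`` on whitened data
    ``z``. Returns ``(W_full, K, sources)`` with the full demixing matrix
    ``W_full`` (components x channels) acting on centered data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=complex))
    n_ch, n_samp = X.shape
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed channels")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    C = (Xc @ Xc.conj().T) / n_samp
    d, E = scipy.linalg.eigh(C)
    order = np.argsort(d)[::-1]
    d, E = d[order], E[:, order]
    usable = int(np.sum(d > max(d[0], 1e-30) * 1e-10))
    if usable < n_components:
        logger.warning(
            "rank %d < requested %d components; reducing", usable, n_components
        )
        n_components = usable
    d, E = d[:n_components], E[:, :n_components]
    K = np.diag(1.0 / np.sqrt(d)) @ E.conj().T  # whitening (comp x channels)
    Z = K @ Xc

    rng = check_rng(seed)
    W = rng.standard_normal((n_components, n_components)) + 1j * rng.standard_normal(
        (n_components, n_components)
    )
    W = _sym_decorrelate(W)
    for it in range(max_iter):
        Y = W @ Z  # (comp x samples); row i is y = w^H z with w = W[i]^H
        absY2 = np.abs(Y) ** 2
        g = 1.0 / (2.0 * np.sqrt(a1 + absY2))
        gp = -1.0 / (4.0 * (a1 + absY2) ** 1.5)
        # w+ = E[z (w^H z)^* g] - E[g + |y|^2 g'] w, written in row form
        Wn = (Y * g) @ Z.conj().T / n_samp - (
            (g + absY2 * gp).mean(axis=1)[:, None] * W
        )
        Wn = _sym_decorrelate(Wn)
        conv = np.abs(np.abs(np.diag(Wn @ W.conj().T)) - 1).max()
        W = Wn
        if conv < tol:
            break
    else:
        logger.info("complex FastICA hit max_iter without full convergence")
    W_full = W @ K  # (components x channels)
    return W_full, K, W_full @ Xc


def group_temporal_ica(
    series_by_participant: list,
    n_components: int = 48,
    seed=0,
    method: str = "complex",
) -> ICModel:
    """Concatenate participants' complex window series and unmix.

    ``method='complex'`` runs the complex fixed-point ICA; ``'realstack'``
    stacks real and imaginary parts as extra samples and runs the same core
    on the realified series (documented fallback). Deterministic under a
    fixed seed; identical seeds give identical W up to component sign/phase.
    """
    series = [np.atleast_2d(np.asarray(s)) for s in series_by_participant]
    X = np.concatenate(series, axis=1)  # (channels, total windows)
    if X.shape[1] <= n_components:
        raise ValueError("need more total windows than components")
    n_components = min(n_components, X.shape[0])
    if method == "complex":
        W, _, sources = complex_fastica(X, n_components, seed=seed)
    elif method == "realstack":
        Xr = np.concatenate([X.real, X.imag], axis=1).astype(complex)
        W, _, _ = complex_fastica(Xr, n_components, seed=seed)
        sources = W @ (X - X.mean(axis=1, keepdims=True))
    else:
        raise ValueError("method must be 'complex' or 'realstack'")
    A = np.linalg.pinv(W)
    return ICModel(W=W, A=A, sources=sources)


def ic_time_courses(alpha_eeg: np.ndarray, model: ICModel) -> np.ndarray:
    """Project time-domain alpha-band data through the demixing matrix."""
    X = np.atleast_2d(np.asarray(alpha_eeg))
    if X.shape[0] != model.W.shape[1]:
        raise ValueError(
            f"channel dimension {X.shape[0]} does not match demixing "
            f"matrix ({model.W.shape[1]} channels)"
        )
    return model.W @ X


def ic_envelopes(courses: np.ndarray, zscore: bool = True) -> np.ndarray:
    """Component instantaneous amplitudes, optionally z-scored per series.

    Complex component series already carry an instantaneous amplitude
    (their modulus); real series go through the Hilbert transform.
    """
    if np.iscomplexobj(courses):
        env = np.abs(courses)
    else:
        env = hilbert_envelope(courses)
    if zscore:
        sd = env.std(axis=1, keepdims=True, ddof=1)
        sd[sd == 0] = 1.0
        env = (env - env.mean(axis=1, keepdims=True)) / sd
    return env


def regress_rsn_maps(
    dipole_env_z: np.ndarray, ic_env_z: np.ndarray
) -> np.ndarray:
    """Per-source OLS of the source envelope on all component envelopes.

    Includes an intercept (z-scored inputs make it ~0). Returns beta maps
    (components x sources). Rank-deficient designs fall back to the
    minimum-norm least-squares solution; the condition number is logged.
    """
    Y = np.atleast_2d(np.asarray(dipole_env_z, dtype=float)).T  # (T, sources)
    Xr = np.atleast_2d(np.asarray(ic_env_z, dtype=float)).T  # (T, comp)
    if Y.shape[0] != Xr.shape[0]:
        raise ValueError("time axes of sources and regressors differ")
    n_t, n_comp = Xr.shape
    if n_t <= n_comp + 1:
        raise ValueError("need more timepoints than regressors + intercept")
    X = np.column_stack([np.ones(n_t), Xr])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        logger.warning("collinear regressors (cond=%.3g); minimum-norm solution", cond)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return B[1:]  # (components, sources)


def group_average(participant_betas: dict) -> np.ndarray:
    """Unweighted mean of participant beta maps."""
    return np.mean([np.asarray(v, dtype=float) for v in participant_betas.values()], axis=0)
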