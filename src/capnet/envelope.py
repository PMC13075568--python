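"""Band-limiting, Hilbert envelopes, ROI reduction, and z-scoring.

The front end shared by the clustering and network-estimation branches:
alpha-band filter each channel, take the magnitude of the analytic signal,
average source nodes into ROIs, and standardize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

logger = logging.getLogger(__name__)


@dataclass
class EnvelopeFrameSet:
    """Z-scored ROI amplitude frames for one participant.

    ``Z`` is (n_roi x n_frames). ``provenance`` records band, filter, and the
    z-score convention so branches cannot silently mix conventions.
    """

    Z: np.ndarray
    fs: float
    participant: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("envelope frames contain non-finite values")

    @property
    def n_roi(self) -> int:
        return self.Z.shape[0]

    @property
    def n_frames(self) -> int:
        return self.Z.shape[1]


def bandpass_alpha(ts: np.ndarray, fs: float, band=(8.0, 12.0), order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time (last) axis.

    A 4th-order design applied forward-backward (`sosfiltfilt`), so the
    effective attenuation is doubled and phase is exactly zero.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < low < high")
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or beyond Nyquist ({fs / 2} Hz)")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=-1)


def hilbert_envelope(ts: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the analytic signal, per channel."""
    ts = np.asarray(ts, dtype=float)
    if not np.all(np.isfinite(ts)):
        raise ValueError("input contains non-finite values")
    return np.abs(scipy.signal.hilbert(ts, axis=-1))


def roi_reduce(
    source_env: np.ndarray,
    membership,
    roi_ids=None,
) -> tuple[np.ndarray, list]:
    """Average source-node series into ROI series.

    ``membership`` maps node index -> ROI id; accepted forms are a sequence
    aligned with the node axis (None/NaN = unassigned) or a DataFrame with
    columns ``node_id``/``roi_id``. ROI value at a frame is the arithmetic
    mean of its member nodes. Unassigned nodes are ignored (count logged);
    an expected ROI with zero members is an error.

    Returns ``(roi_env, roi_ids)`` with rows ordered by ``roi_ids``.
    """
    source_env = np.atleast_2d(np.asarray(source_env, dtype=float))
    n_nodes = source_env.shape[0]
    if isinstance(membership, pd.DataFrame):
        mapping = dict(zip(membership["node_id"].astype(int), membership["roi_id"]))
        labels = [mapping.get(i) for i in range(n_nodes)]
    else:
        labels = list(membership)
        if len(labels) != n_nodes:
            raise ValueError(
                f"membership length {len(labels)} != number of nodes {n_nodes}"
            )
    assigned = [
        (i, r)
        for i, r in enumerate(labels)
        if r is not None and not (isinstance(r, float) and np.isnan(r))
    ]
    n_unassigned = n_nodes - len(assigned)
    if n_unassigned:
        logger.info("roi_reduce: %d unassigned source nodes ignored", n_unassigned)
    if roi_ids is None:
        roi_ids = sorted({r for _, r in assigned})
    members = {r: [] for r in roi_ids}
    for i, r in assigned:
        if r in members:
            members[r].append(i)
    empty = [r for r in roi_ids if not members[r]]
    if empty:
        raise ValueError(f"ROI(s) with zero member nodes: {empty}")
    out = np.empty((len(roi_ids), source_env.shape[1]))
    for j, r in enumerate(roi_ids):
        out[j] = source_env[members[r]].mean(axis=0)
    return out, list(roi_ids)


def zscore_rois(
    roi_env: np.ndarray,
    fs: float = 1.0,
    participant: str = "",
    mode: str = "roi",
    ddof: int = 1,
    provenance: dict | None = None,
) -> EnvelopeFrameSet:
    """Standardize ROI amplitude series into an EnvelopeFrameSet.

    ``mode='roi'`` (default) z-scores each ROI across time, weighting all
    ROIs equally in later clustering; ``mode='frame'`` z-scores each
    timeframe across ROIs (the alternative reading). Sample sd (ddof=1) by
    default.
    """
    roi_env = np.atleast_2d(np.asarray(roi_env, dtype=float))
    if mode not in ("roi", "frame"):
        raise ValueError("mode must be 'roi' or 'frame'")
    axis = 1 if mode == "roi" else 0
    sd = roi_env.std(axis=axis, ddof=ddof, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        what = "ROI" if mode == "roi" else "frame"
        raise ValueError(f"zero-variance {what} series at indices {bad.tolist()}")
    Z = (roi_env - roi_env.mean(axis=axis, keepdims=True)) / sd
    prov = {"zscore_mode": mode, "ddof": ddof}
    if provenance:
        prov.update(provenance)
    return EnvelopeFrameSet(Z, fs, participant, prov)


def envelope_pipeline(
    ts: np.ndarray,
    fs: float,
    membership=None,
    band=(8.0, 12.0),
    edge_trim_s: float = 0.0,
    participant: str = "",
    zscore_mode: str = "roi",
) -> EnvelopeFrameSet:
    """bandpass -> Hilbert envelope -> optional ROI reduction -> z-score."""
    env = hilbert_envelope(bandpass_alpha(ts, fs, band))
    if membership is not None:
        env, _ = roi_reduce(env, membership)
    if edge_trim_s > 0:
        n = int(round(edge_trim_s * fs))
        env = env[:, n : env.shape[1] - n]
    return zscore_rois(
        env,
        fs,
        participant,
        mode=zscore_mode,
        provenance={"band": list(band), "filter": "butter4-filtfilt",
                    "edge_trim_s": edge_trim_s},
    )
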