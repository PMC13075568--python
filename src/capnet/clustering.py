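"""Correlation-distance k-means over concatenated z-scored timeframes.

Frames from all participants are pooled and clustered with
``d(x, c) = 1 - pearson(x, c)``; the algorithm is Lloyd iteration on
row-standardized frames (center + unit norm per frame), for which the
cluster mean (re-standardized) is the correlation-distance centroid. Maps
are then rebuilt from the raw z-scored frames (optionally at a finer
spatial resolution than the clustering frames).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class CapSet:
    """Clustering output: labels, centroids, and participant/group maps."""

    k: int
    labels: np.ndarray  # (N,) int in [1, k] over concatenated frames
    centroids: np.ndarray  # (k, R) row-standardized
    participant_index: np.ndarray  # (N,) participant id per frame
    participant_maps: dict = field(default_factory=dict)  # pid -> (k, R_map), NaN rows = absent
    group_maps: np.ndarray = None  # (k, R_map)
    inertia: float = 0.0
    config: dict = field(default_factory=dict)

    def labels_for(self, pid) -> np.ndarray:
        return self.labels[self.participant_index == pid]


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"frame(s) with zero spatial variance at indices {bad.tolist()}: "
            "correlation distance undefined"
        )
    return Xc / norms[:, None]


def _plusplus_init(Xs: np.ndarray, k: int, rng) -> np.ndarray:
    """k-means++ style seeding in correlation distance on standardized rows."""
    N = Xs.shape[0]
    centers = np.empty((k, Xs.shape[1]))
    idx = int(rng.integers(N))
    centers[0] = Xs[idx]
    d = 1.0 - Xs @ centers[0]
    d = np.maximum(d, 0)
    for j in range(1, k):
        d64 = d.astype(np.float64)
        total = d64.sum()
        if total <= 0:
            idx = int(rng.integers(N))
        else:
            idx = int(rng.choice(N, p=d64 / total))
        centers[j] = Xs[idx]
        d = np.minimum(d, np.maximum(1.0 - Xs @ centers[j], 0))
    return centers


def _norm_centroids(C: np.ndarray) -> np.ndarray:
    Cc = C - C.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Cc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Cc / norms


def kmeans_correlation(
    frames: np.ndarray,
    k: int,
    n_init: int = 10,
    max_iter: int = 300,
    seed=0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd k-means with 1 - Pearson correlation as the distance.

    Returns ``(labels, centroids, inertia)`` of the best of ``n_init``
    restarts by total within-cluster correlation distance. Labels are
    1-based. Deterministic under a fixed seed. An emptied cluster is
    re-seeded from the frame farthest from its current centroid.
    """
    X = np.atleast_2d(np.asarray(frames))
    if X.dtype != np.float32:  # float32 input keeps the fast path; else f64
        X = X.astype(np.float64, copy=False)
    N = X.shape[0]
    if N <= k:
        raise ValueError(f"need more frames ({N}) than clusters ({k})")
    Xs = _standardize_rows(X)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_init)):
        C = _plusplus_init(Xs, k, rng)
        labels = None
        for _ in range(max_iter):
            sim = Xs @ _norm_centroids(C).T  # (N, k) correlations
            new_labels = sim.argmax(axis=1)
            for j in range(k):
                if not np.any(new_labels == j):
                    far = int((sim.max(axis=1)).argmin())
                    new_labels[far] = j
                    logger.info("re-seeded empty cluster %d from frame %d", j, far)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                C[j] = Xs[labels == j].mean(axis=0)
        Cn = _norm_centroids(C)
        inertia = float(np.sum(1.0 - (Xs * Cn[labels]).sum(axis=1)))
        if best is None or inertia < best[2]:
            best = (labels + 1, Cn, inertia)
    return best


def build_cap_maps(
    labels: np.ndarray,
    map_frames: np.ndarray,
    participant_index: np.ndarray,
    k: int | None = None,
) -> tuple[dict, np.ndarray]:
    """Participant- and group-level spatial maps from frame labels.

    ``map_frames`` may live at a finer spatial resolution than the frames
    used for clustering, as long as it is time-aligned with ``labels``.
    A participant's map for a cluster is the mean of their frames carrying
    that label; the group map averages only participants that expressed the
    cluster (absent ones contribute nothing, recorded as NaN rows).
    """
    labels = np.asarray(labels, dtype=int)
    map_frames = np.atleast_2d(np.asarray(map_frames, dtype=float))
    participant_index = np.asarray(participant_index)
    if labels.size != map_frames.shape[0] or labels.size != participant_index.size:
        raise ValueError("labels, map_frames and participant_index must align")
    if k is None:
        k = int(labels.max())
    R = map_frames.shape[1]
    pids = list(dict.fromkeys(participant_index.tolist()))
    participant_maps = {}
    for pid in pids:
        sel = participant_index == pid
        maps = np.full((k, R), np.nan)
        for j in range(1, k + 1):
            m = sel & (labels == j)
            if np.any(m):
                maps[j - 1] = map_frames[m].mean(axis=0)
        participant_maps[pid] = maps
    stack = np.stack(list(participant_maps.values()))  # (P, k, R)
    with np.errstate(invalid="ignore"):
        group = np.nanmean(stack, axis=0)
    return participant_maps, group


def cluster_cohort(
    frame_sets: dict,
    k: int,
    n_init: int = 10,
    max_iter: int = 300,
    seed=0,
    map_frame_sets: dict | None = None,
) -> CapSet:
    """Concatenate participants' frames, cluster, and build the CapSet.

    ``frame_sets`` maps participant id -> (R x T) z-scored frame matrix
    (time on the last axis). ``map_frame_sets`` optionally supplies finer-
    resolution frames for map construction.
    """
    pids = list(frame_sets)
    blocks = [np.asarray(frame_sets[p], dtype=float).T for p in pids]  # (T, R)
    X = np.vstack(blocks)
    pidx = np.concatenate(
        [np.full(b.shape[0], i) for i, b in enumerate(blocks)]
    )
    pid_arr = np.array([pids[i] for i in pidx], dtype=object)
    labels, centroids, inertia = kmeans_correlation(
        X, k, n_init=n_init, max_iter=max_iter, seed=seed
    )
    if map_frame_sets is None:
        map_X = X
    else:
        map_X = np.vstack([np.asarray(map_frame_sets[p], dtype=float).T for p in pids])
    participant_maps, group = build_cap_maps(labels, map_X, pid_arr, k)
    return CapSet(
        k=k,
        labels=labels,
        centroids=centroids,
        participant_index=pid_arr,
        participant_maps=participant_maps,
        group_maps=group,
        inertia=inertia,
        config={"n_init": n_init, "max_iter": max_iter, "seed": seed,
                "distance": "correlation"},
    )
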