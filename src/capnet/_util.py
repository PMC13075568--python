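"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def check_rng(seed):
    """Return a Generator from a seed, Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mirror_permutation(mirror_pairs: np.ndarray, n_roi: int) -> np.ndarray:
    """Build the index permutation that swaps left/right hemisphere ROIs.

    Parameters
    ----------
    mirror_pairs : (n_roi // 2, 2) int array
        Each row pairs a left-hemisphere ROI index with its right mirror.
    n_roi : int
        Total ROI count; the pairs must cover every index exactly once.

    Returns
    -------
    perm : (n_roi,) int array such that ``x[perm]`` is the mirrored map.
    """
    pairs = np.asarray(mirror_pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("mirror_pairs must be an (n, 2) array")
    flat = pairs.ravel()
    if pairs.shape[0] * 2 != n_roi or not np.array_equal(
        np.sort(flat), np.arange(n_roi)
    ):
        raise ValueError(
            "mirror table is not a bijection between hemispheres: the pairs "
            f"must cover each of the {n_roi} ROI indices exactly once"
        )
    perm = np.empty(n_roi, dtype=int)
    perm[pairs[:, 0]] = pairs[:, 1]
    perm[pairs[:, 1]] = pairs[:, 0]
    return perm


def default_mirror_pairs(n_roi: int) -> np.ndarray:
    """Pair ROI i with ROI i + n_roi/2 (left block / right block layout)."""
    if n_roi % 2:
        raise ValueError("n_roi must be even to form mirror pairs")
    half = n_roi // 2
    return np.column_stack([np.arange(half), np.arange(half) + half])


def pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    An = np.linalg.norm(Ac, axis=1, keepdims=True)
    Bn = np.linalg.norm(Bc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Ac / An) @ (Bc / Bn).T
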