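"""Temporal CAP statistics: occurrences, lifetimes, time courses, group tests."""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


def compute_runs(
    labels: np.ndarray,
    fs: float,
    participant: str = "",
    min_run: int = 1,
) -> pd.DataFrame:
    """Run-length encode a label series into an occurrence table.

    An occurrence is a maximal run of consecutive frames with the same
    label. Columns: participant, cap_id, start_frame, run_length_frames,
    lifetime_ms. Runs shorter than ``min_run`` frames are dropped (default
    keeps single-frame runs).
    """
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        raise ValueError("label series is empty")
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    lengths = ends - starts
    table = pd.DataFrame(
        {
            "participant": participant,
            "cap_id": labels[starts],
            "start_frame": starts,
            "run_length_frames": lengths,
            "lifetime_ms": lengths * 1000.0 / fs,
        }
    )
    if min_run > 1:
        table = table[table["run_length_frames"] >= min_run].reset_index(drop=True)
    return table


def occurrence_stats(
    runs: pd.DataFrame, duration_s: float, cap_ids=None
) -> pd.DataFrame:
    """Per-(participant, cap) occurrence rate (Hz) and mean lifetime (ms).

    Caps listed in ``cap_ids`` but without runs are reported with rate 0 and
    missing lifetime rather than silently omitted.
    """
    rows = []
    for (part, cap), grp in runs.groupby(["participant", "cap_id"]):
        rows.append(
            {
                "participant": part,
                "cap_id": cap,
                "n_occurrences": len(grp),
                "occurrence_rate_hz": len(grp) / duration_s,
                "mean_lifetime_ms": grp["lifetime_ms"].mean(),
            }
        )
    out = pd.DataFrame(rows)
    if cap_ids is not None:
        for part in out["participant"].unique() if len(out) else []:
            present = set(out.loc[out["participant"] == part, "cap_id"])
            for cap in cap_ids:
                if cap not in present:
                    out.loc[len(out)] = {
                        "participant": part,
                        "cap_id": cap,
                        "n_occurrences": 0,
                        "occurrence_rate_hz": 0.0,
                        "mean_lifetime_ms": np.nan,
                    }
    return out.sort_values(["participant", "cap_id"]).reset_index(drop=True)


def cohort_run_table(labels_by_participant: dict, fs: float, min_run: int = 1):
    """Concatenate per-participant run tables plus their occurrence stats."""
    tables = [
        compute_runs(lab, fs, participant=pid, min_run=min_run)
        for pid, lab in labels_by_participant.items()
    ]
    runs = pd.concat(tables, ignore_index=True)
    stats = pd.concat(
        [
            occurrence_stats(t, len(labels_by_participant[pid]) / fs)
            for pid, t in zip(labels_by_participant, tables)
        ],
        ignore_index=True,
    )
    return runs, stats


def cap_time_courses(group_maps: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Spatial correlation of each CAP map with every timeframe.

    ``group_maps`` is (k x R), ``frames`` is (R x T); returns (k x T) Pearson
    correlations. Frames with zero spatial variance yield NaN (recorded as
    missing, not an error).
    """
    M = np.atleast_2d(np.asarray(group_maps, dtype=float))
    F = np.atleast_2d(np.asarray(frames, dtype=float)).T  # (T, R)
    Mc = M - M.mean(axis=1, keepdims=True)
    Fc = F - F.mean(axis=1, keepdims=True)
    Mn = np.linalg.norm(Mc, axis=1, keepdims=True)
    Fn = np.linalg.norm(Fc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc / Mn) @ (Fc / Fn[:, None]).T
    return np.clip(r, -1.0, 1.0)


def temporal_group_tests(
    metrics: pd.DataFrame,
    value_col: str = "occurrence_rate_hz",
    alpha: float = 0.05,
) -> dict:
    """ANOVA plus Bonferroni-corrected pairwise t-tests across caps.

    Values are natural-log transformed first; non-positive values are
    excluded with a warning (log undefined). The Bonferroni factor is the
    number of cap pairs, k(k-1)/2.
    """
    df = metrics[["participant", "cap_id", value_col]].dropna()
    n_bad = int((df[value_col] <= 0).sum())
    if n_bad:
        logger.warning("%d non-positive values excluded from log tests", n_bad)
        df = df[df[value_col] > 0]
    df = df.assign(logval=np.log(df[value_col]))
    caps = sorted(df["cap_id"].unique())
    groups = [df.loc[df["cap_id"] == c, "logval"].to_numpy() for c in caps]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 participants per cap for group tests")
    F, p = scipy.stats.f_oneway(*groups)
    n_pairs = len(caps) * (len(caps) - 1) // 2
    rows = []
    for (i, a), (j, b) in combinations(enumerate(caps), 2):
        if np.allclose(np.concatenate([groups[i], groups[j]]),
                       np.concatenate([groups[i], groups[j]])[0]):
            t, praw = 0.0, 1.0
        else:
            t, praw = scipy.stats.ttest_ind(groups[i], groups[j])
        rows.append(
            {
                "cap_a": a,
                "cap_b": b,
                "t": t,
                "p_raw": praw,
                "p_corrected": min(1.0, praw * n_pairs),
                "significant": praw * n_pairs < alpha,
            }
        )
    return {
        "anova_F": float(F),
        "anova_p": float(p),
        "n_pairs": n_pairs,
        "pairwise": pd.DataFrame(rows),
    }
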