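"""Clustering reruns across k and across seeds: overlap graph, stability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from ._util import pearson_rows
from .clustering import CapSet, cluster_cohort, kmeans_correlation


@dataclass
class OverlapGraph:
    """Directed frame-overlap edges between clusterings at consecutive k.

    Edge weight = fraction of the source cluster's frames that land in the
    target cluster at the next-higher k; outgoing weights from each node sum
    to 1 before any display filtering.
    """

    edges: pd.DataFrame  # columns: k_from, cap_from, k_to, cap_to, weight
    k_values: list

    def filtered(self, threshold: float = 0.1) -> pd.DataFrame:
        """Display view: only edges with weight >= threshold."""
        return self.edges[self.edges["weight"] >= threshold].reset_index(drop=True)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for row in self.edges.itertuples():
            g.add_edge(
                (row.k_from, row.cap_from), (row.k_to, row.cap_to), weight=row.weight
            )
        return g


def sweep_k(
    frame_sets: dict,
    k_values=range(10, 21),
    seed=0,
    n_init: int = 10,
    max_iter: int = 300,
    map_frame_sets: dict | None = None,
) -> dict:
    """Independent clustering of the same frames at each requested k."""
    k_values = list(k_values)
    if k_values != sorted(k_values):
        raise ValueError("k_values must be sorted ascending")
    rng = np.random.default_rng(seed)
    out = {}
    for k in k_values:
        out[k] = cluster_cohort(
            frame_sets, k, n_init=n_init, max_iter=max_iter,
            seed=int(rng.integers(2**63)), map_frame_sets=map_frame_sets,
        )
    return out


def overlap_graph(labelings_by_k: dict) -> OverlapGraph:
    """Frame-overlap graph between clusterings at consecutive k values.

    ``labelings_by_k`` maps k -> 1-based label array over the same frames
    (or CapSet, whose labels are used).
    """
    ks = sorted(labelings_by_k)
    labels = {}
    for k in ks:
        v = labelings_by_k[k]
        labels[k] = np.asarray(v.labels if isinstance(v, CapSet) else v, dtype=int)
    sizes = {k: labels[k].size for k in ks}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"labelings cover different frame counts: {sizes}")
    rows = []
    for ka, kb in zip(ks[:-1], ks[1:]):
        tab = pd.crosstab(labels[ka], labels[kb])
        frac = tab.div(tab.sum(axis=1), axis=0)
        for cap_a in frac.index:
            for cap_b in frac.columns:
                w = float(frac.loc[cap_a, cap_b])
                if w > 0:
                    rows.append(
                        {"k_from": ka, "cap_from": int(cap_a), "k_to": kb,
                         "cap_to": int(cap_b), "weight": w}
                    )
    return OverlapGraph(pd.DataFrame(rows), ks)


def seed_stability(
    frames: np.ndarray,
    k: int,
    n_runs: int = 5,
    seeds=None,
    n_init: int = 10,
    max_iter: int = 300,
) -> pd.DataFrame:
    """Cross-run map stability at fixed k under different seed initializations.

    Runs are matched to the first run's clusters by optimal assignment on
    centroid correlation; reports, per cluster, the min and mean |r| across
    runs. Duplicate seeds reproduce identical clusterings exactly.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    cents = []
    for s in seeds:
        _, C, _ = kmeans_correlation(frames, k, n_init=n_init, max_iter=max_iter, seed=s)
        cents.append(C)
    ref = cents[0]
    per_cap = {j: [] for j in range(k)}
    for C in cents[1:]:
        r = pearson_rows(ref, C)
        rows, cols = scipy.optimize.linear_sum_assignment(-np.abs(r))
        for i, j in zip(rows, cols):
            per_cap[i].append(abs(r[i, j]))
    return pd.DataFrame(
        {
            "cap_id": np.arange(1, k + 1),
            "min_corr": [min(per_cap[j]) for j in range(k)],
            "mean_corr": [float(np.mean(per_cap[j])) for j in range(k)],
        }
    )
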