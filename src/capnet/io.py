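"""Plain-text table and sidecar plumbing shared by the CLI stages."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_membership(path, node_to_roi) -> None:
    """Write a node->ROI atlas membership table (TSV: node_id, roi_id)."""
    df = pd.DataFrame(
        {"node_id": np.arange(len(node_to_roi)), "roi_id": np.asarray(node_to_roi)}
    )
    df.to_csv(path, sep="\t", index=False)


def read_membership(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["node_id", "roi_id"]:
        raise ValueError("membership table must have columns node_id, roi_id")
    return df


def write_mirror_pairs(path, pairs: np.ndarray) -> None:
    """Write hemisphere mirror pairs (TSV: roi_left, roi_right)."""
    pd.DataFrame(np.asarray(pairs, dtype=int), columns=["roi_left", "roi_right"]).to_csv(
        path, sep="\t", index=False
    )


def read_mirror_pairs(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["roi_left", "roi_right"]:
        raise ValueError("mirror table must have columns roi_left, roi_right")
    return df.iloc[:, :2].to_numpy(dtype=int)


def write_lambda_series(path, lam_series) -> None:
    """Two-column text export: frame_index, lambda."""
    vals = np.asarray(getattr(lam_series, "values", lam_series), dtype=float)
    pd.DataFrame({"frame_index": np.arange(vals.size), "lambda": vals}).to_csv(
        path, sep="\t", index=False
    )


def write_labels(path, labels) -> None:
    """Per-participant label export (TSV: frame_index, cap_id)."""
    labels = np.asarray(labels, dtype=int)
    pd.DataFrame({"frame_index": np.arange(labels.size), "cap_id": labels}).to_csv(
        path, sep="\t", index=False
    )


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_sidecar(path, config: dict, extra: dict | None = None) -> None:
    """JSON provenance sidecar: config (verbatim), its hash, extras."""
    payload = {"config": config, "config_hash": config_hash(config)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def write_edge_list(path, edges: pd.DataFrame) -> None:
    edges.to_csv(path, sep="\t", index=False)
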