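"""End-to-end orchestration from a single validated configuration."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, compare, envelope, io, metrics, rsn, synthetic, sweep
from ._util import check_rng

logger = logging.getLogger(__name__)

_ALLOWED = {
    "seed": None,
    "out": None,
    "simulate": {
        "mode", "n_roi", "k_true", "n_participants", "duration_s", "fs", "snr",
        "mean_dwell_ms", "occ_rates", "participant_sigma_by_group",
        "hierarchy_depth", "n_sensors", "nodes_per_roi", "a_min",
    },
    "cluster": {"enabled", "k", "n_init", "max_iter"},
    "rsn": {"enabled", "n_components", "method"},
    "metrics": {"enabled", "min_run"},
    "compare": {"enabled", "n_perm"},
    "sweep": {"enabled", "k_list", "n_init"},
    "envelope": {"band", "edge_trim_s", "zscore_mode"},
}


def validate_config(config: dict) -> dict:
    """Schema check: unknown keys are rejected by name; defaults filled in."""
    for key, val in config.items():
        if key not in _ALLOWED:
            raise ValueError(f"unknown config key: {key!r}")
        allowed = _ALLOWED[key]
        if allowed is not None and isinstance(val, dict):
            for sub in val:
                if sub not in allowed:
                    raise ValueError(f"unknown config key: {key}.{sub!r}")
    cfg = {
        "seed": config.get("seed", 0),
        "out": config.get("out", "capnet_run"),
        "simulate": {
            "mode": "envelope", "n_roi": 100, "k_true": 6, "n_participants": 4,
            "duration_s": 120.0, "fs": 250.0, "snr": 0.5, "mean_dwell_ms": 80.0,
            "occ_rates": None, "participant_sigma_by_group": None,
            "hierarchy_depth": 1, "n_sensors": 32, "nodes_per_roi": 2,
            "a_min": 0.35,
        },
        "cluster": {"enabled": True, "k": None, "n_init": 5, "max_iter": 300},
        "rsn": {"enabled": False, "n_components": 8, "method": "complex"},
        "metrics": {"enabled": True, "min_run": 1},
        "compare": {"enabled": True, "n_perm": 1000},
        "sweep": {"enabled": False, "k_list": [4, 6], "n_init": 3},
        "envelope": {"band": [8.0, 12.0], "edge_trim_s": 0.0, "zscore_mode": "roi"},
    }
    for key in cfg:
        if key in config:
            if isinstance(cfg[key], dict):
                cfg[key].update(config[key])
            else:
                cfg[key] = config[key]
    return cfg


def run_pipeline(config: dict) -> dict:
    """Execute simulate -> [inverse/envelope] -> cluster (+rsn) -> metrics ->
    compare -> sweep per the config toggles; persist results under `out`.

    Returns a dict of in-memory results keyed by stage. Every output
    directory carries a JSON provenance sidecar with the verbatim config and
    its hash; reruns with the same config are numerically identical.
    """
    cfg = validate_config(config)
    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    rng = check_rng(cfg["seed"])
    sub_seeds = {name: int(rng.integers(2**63))
                 for name in ("simulate", "cluster", "rsn", "compare", "sweep")}
    results: dict = {"config": cfg, "sub_seeds": sub_seeds}

    sim = cfg["simulate"]
    templates = synthetic.make_templates(
        sim["n_roi"], sim["k_true"], hierarchy_depth=sim["hierarchy_depth"],
        seed=sub_seeds["simulate"],
    )
    stage = "simulate"
    try:
        if sim["mode"] == "envelope":
            cohort = synthetic.simulate_roi_envelopes(
                templates,
                snr=sim["snr"],
                participant_sigma_by_group=sim["participant_sigma_by_group"],
                n_participants=sim["n_participants"],
                duration_s=sim["duration_s"],
                fs=sim["fs"],
                occ_rates=sim["occ_rates"],
                mean_dwell_ms=sim["mean_dwell_ms"],
                a_min=sim["a_min"],
                seed=sub_seeds["simulate"] + 1,
            )
            frame_sets = {
                p: envelope.zscore_rois(
                    cohort.roi_env[p], cohort.fs, participant=str(p),
                    mode=cfg["envelope"]["zscore_mode"],
                ).Z
                for p in range(cohort.n_participants)
            }
            # maps are built from per-frame-normalized data (finer-fidelity
            # analog of using normalized source data instead of ROI z-scores)
            results["map_frame_sets"] = {
                p: envelope.zscore_rois(cohort.roi_env[p], cohort.fs, mode="frame").Z
                for p in range(cohort.n_participants)
            }
        else:
            cohort, frame_sets = _oscillation_branch(cfg, templates, sub_seeds, results)
        results["cohort"] = cohort
        results["frame_sets"] = frame_sets
        io.write_mirror_pairs(out / "mirror_pairs.tsv", templates.mirror_pairs)

        if cfg["cluster"]["enabled"]:
            stage = "cluster"
            k = cfg["cluster"]["k"] or templates.k_true
            caps = clustering.cluster_cohort(
                frame_sets, k, n_init=cfg["cluster"]["n_init"],
                max_iter=cfg["cluster"]["max_iter"], seed=sub_seeds["cluster"],
                map_frame_sets=results.get("map_frame_sets"),
            )
            results["caps"] = caps
            for pid in frame_sets:
                io.write_labels(out / f"labels_p{pid}.tsv", caps.labels_for(pid))

        if cfg["metrics"]["enabled"] and "caps" in results:
            stage = "metrics"
            caps = results["caps"]
            labels_by_p = {pid: caps.labels_for(pid) for pid in frame_sets}
            runs, stats = metrics.cohort_run_table(
                labels_by_p, cohort.fs, min_run=cfg["metrics"]["min_run"]
            )
            results["runs"], results["occurrence_stats"] = runs, stats
            runs.to_csv(out / "run_table.tsv", sep="\t", index=False)
            stats.to_csv(out / "occurrence_stats.tsv", sep="\t", index=False)
            if stats.groupby("cap_id")["participant"].count().min() >= 2:
                tests = metrics.temporal_group_tests(stats)
                results["temporal_tests"] = tests
                tests["pairwise"].to_csv(out / "pairwise_tests.tsv", sep="\t", index=False)

        if cfg["compare"]["enabled"] and "caps" in results:
            stage = "compare"
            caps = results["caps"]
            ref_maps = results.get("rsn_group_betas", templates.templates)
            sims = compare.similarity_confusion(caps.group_maps, ref_maps)
            sims["fisher_z"] = compare.permutation_match_test(
                sims["fisher_z"], n_perm=cfg["compare"]["n_perm"],
                seed=sub_seeds["compare"],
            )
            results["similarity"] = sims
            sym = [
                compare.symmetry_index(caps.group_maps[j], templates.mirror_pairs)
                for j in range(caps.k)
            ]
            results["symmetry"] = np.array(sym)
            stack = np.stack([caps.participant_maps[p] for p in frame_sets])
            loo = np.array(
                [compare.loo_consistency(stack[:, j, :]) for j in range(caps.k)]
            )
            results["loo_consistency"] = loo
            pd.DataFrame(
                {"cap_id": np.arange(1, caps.k + 1), "symmetry_index": sym,
                 "mean_loo_r": np.nanmean(loo, axis=1)}
            ).to_csv(out / "cap_spatial_stats.tsv", sep="\t", index=False)

        if cfg["sweep"]["enabled"]:
            stage = "sweep"
            by_k = sweep.sweep_k(
                frame_sets, cfg["sweep"]["k_list"], seed=sub_seeds["sweep"],
                n_init=cfg["sweep"]["n_init"],
            )
            graph = sweep.overlap_graph(by_k)
            results["sweep"] = by_k
            results["overlap_graph"] = graph
            io.write_edge_list(out / "overlap_edges.tsv", graph.edges)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    io.write_sidecar(out / "provenance.json", cfg, {"sub_seeds": sub_seeds})
    return results


def _oscillation_branch(cfg, templates, sub_seeds, results):
    """Sensor-level simulation, inverse imaging, envelope + RSN estimation."""
    from . import inverse as inv

    sim = cfg["simulate"]
    n_sources = sim["n_roi"] * sim["nodes_per_roi"]
    lf = synthetic.make_lead_field(sim["n_sensors"], n_sources,
                                   seed=sub_seeds["simulate"] + 2)
    rng = check_rng(sub_seeds["simulate"] + 3)
    frame_sets, roi_env, states, alpha_series, sensor_data = {}, [], [], [], []
    k = templates.k_true
    occ = sim["occ_rates"] or np.linspace(0.5, 0.9, k)
    for p in range(sim["n_participants"]):
        seq = synthetic.simulate_state_sequence(
            sim["duration_s"], sim["fs"], occ, sim["mean_dwell_ms"],
            seed=int(rng.integers(2**63)),
        )
        sensors, _, _, membership = synthetic.simulate_sensor_eeg(
            lf, templates, seq, snr=sim["snr"], seed=int(rng.integers(2**63)),
            a_min=sim["a_min"],
        )
        src, _ = inv.inverse_series(lf, sensors)
        env = envelope.envelope_pipeline(
            src.S, sim["fs"], membership=membership,
            band=tuple(cfg["envelope"]["band"]),
            edge_trim_s=cfg["envelope"]["edge_trim_s"],
            zscore_mode=cfg["envelope"]["zscore_mode"], participant=str(p),
        )
        frame_sets[p] = env.Z
        roi_env.append(env.Z)
        states.append(seq)
        sensor_data.append(sensors)
        spec = rsn.stft_spectral_series(sensors.phi, sim["fs"])
        alpha_series.append(rsn.alpha_band_average(spec))
    if cfg["rsn"]["enabled"]:
        model = rsn.group_temporal_ica(
            alpha_series, n_components=cfg["rsn"]["n_components"],
            seed=sub_seeds["rsn"], method=cfg["rsn"]["method"],
        )
        for p, sensors in enumerate(sensor_data):
            alpha_ts = envelope.bandpass_alpha(sensors.phi, sim["fs"],
                                               tuple(cfg["envelope"]["band"]))
            courses = rsn.ic_time_courses(alpha_ts, model)
            ic_env = rsn.ic_envelopes(courses)
            model.participant_betas[p] = rsn.regress_rsn_maps(frame_sets[p], ic_env)
        model.group_betas = rsn.group_average(model.participant_betas)
        results["rsn_model"] = model
        results["rsn_group_betas"] = model.group_betas
    cohort = synthetic.SyntheticCohort(
        templates=templates, roi_env=roi_env, states=states,
        participant_templates=[templates.templates] * sim["n_participants"],
        fs=sim["fs"], config=dict(sim),
    )
    return cohort, frame_sets
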