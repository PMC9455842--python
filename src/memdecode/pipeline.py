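"""End-to-end orchestration: simulate → preprocess → localize →
classify → statistics → report.

One JSON/YAML-style config drives every stage; its defaults are the
study constants (250 encoding words, 1000 Hz acquisition downsampled
to 250 Hz, 0.5–40 Hz fifth-order zero-phase Butterworth, ±200 µV
rejection, 62-channel cap, four canonical bands, 5-fold CV with SMOTE,
shrinkage LDA and the compact CNN).  A run directory receives a config
snapshot with its hash and master seed, per-subject behavior tables,
the AUC tables, ANOVA/post-hoc summaries and permutation-null bands;
re-running with the same config + seed reproduces every numeric output
bit-for-bit.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, preprocess, sourceloc, stats, synthgen
from ._cnn import CNNConfig
from .io_formats import default_montage, write_behavior, write_epochs, write_report
from .spectral import SpectralConfig, band_average, tf_power, window_mean

__all__ = ["default_config", "demo_config", "null_config", "build_scenario", "simulate_subject", "run_all"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    """Full-scale defaults mirroring the study constants."""
    return {
        "n_subjects": 13,
        "behavior": {
            "n_encoding": 250,
            "n_new": 150,
            "p_remember": 0.8,
            "p_false_remember": 0.2,
        },
        "simulate": {
            "fs": 1000.0,
            "snr_db": 0.0,
            "noise_exponent": 1.0,
            "artifact_rate": 0.05,
            "effects": [
                # pre-stimulus alpha decrease, beta/gamma increase for
                # later-remembered trials over medial parietal/prefrontal
                # sources; analogous on-going effects
                {"region": "medial_parietal", "band": "alpha", "gain_remembered": 0.45, "gain_forgotten": 1.55, "window": "pre", "n_sources": 2},
                {"region": "medial_prefrontal", "band": "alpha", "gain_remembered": 0.45, "gain_forgotten": 1.55, "window": "pre", "n_sources": 2},
                {"region": "medial_parietal", "band": "beta", "gain_remembered": 1.55, "gain_forgotten": 0.45, "window": "pre", "n_sources": 2},
                {"region": "medial_prefrontal", "band": "beta", "gain_remembered": 1.55, "gain_forgotten": 0.45, "window": "pre", "n_sources": 2},
                {"region": "medial_parietal", "band": "gamma", "gain_remembered": 1.55, "gain_forgotten": 0.45, "window": "pre", "n_sources": 2},
                {"region": "medial_prefrontal", "band": "gamma", "gain_remembered": 1.55, "gain_forgotten": 0.45, "window": "pre", "n_sources": 2},
                {"region": "medial_parietal", "band": "alpha", "gain_remembered": 0.45, "gain_forgotten": 1.55, "window": "ongoing", "n_sources": 2},
                {"region": "medial_prefrontal", "band": "beta", "gain_remembered": 1.55, "gain_forgotten": 0.45, "window": "ongoing", "n_sources": 2},
                {"region": "medial_parietal", "band": "gamma", "gain_remembered": 1.55, "gain_forgotten": 0.45, "window": "ongoing", "n_sources": 2},
            ],
        },
        "preprocess": {
            "target_fs": 250.0,
            "band": [0.5, 40.0],
            "filter_order": 5,
            "window_ms": [-1000.0, 1000.0],
            "baseline": "whole",
            "reject_uv": 200.0,
        },
        "sourceloc": {
            "n_sources": 642,
            "n_terms": 60,
            "snr": 3.0,
            "noise_reg": 0.1,
            "noise_window_ms": [-1000.0, 0.0],
        },
        "classify": {
            "bands": ["theta", "alpha", "beta", "gamma"],
            "windows": {"pre": [-300.0, 0.0], "ongoing": [400.0, 800.0]},
            "models": ["rlda", "cnn"],
            "gamma": 0.1,
            "decimate": 2,
            "filter_order": 4,
            "n_permutations": 200,
            "cnn": {"n_filters": 8, "epochs": 100, "lr": 0.005, "batch_size": 25, "dropout_p": 0.25},
        },
        "save_intermediates": True,
    }


def demo_config() -> dict:
    """Desk-scale shipped scenario: 13 synthetic subjects, reduced grid.

    Same planted effects and imbalance as the full-scale defaults, with
    the simulation at the analysis rate (250 Hz), 96 encoding words per
    subject, a 162-source grid and a 20-epoch CNN so the whole
    comparison runs in minutes on one CPU.
    """
    cfg = default_config()
    cfg["behavior"]["n_encoding"] = 96
    cfg["behavior"]["n_new"] = 58
    cfg["simulate"]["fs"] = 250.0
    cfg["preprocess"]["target_fs"] = None
    cfg["sourceloc"]["n_sources"] = 162
    cfg["classify"]["cnn"]["epochs"] = 20
    cfg["classify"]["cnn"]["n_filters"] = 4
    cfg["save_intermediates"] = False
    return cfg


def null_config() -> dict:
    """Reduced no-effect scenario (type-I checks over many seeds)."""
    cfg = demo_config()
    cfg["n_subjects"] = 8
    cfg["behavior"]["n_encoding"] = 48
    cfg["behavior"]["n_new"] = 30
    cfg["simulate"]["effects"] = []
    cfg["classify"]["windows"] = {"pre": [-300.0, 0.0]}
    cfg["classify"]["cnn"]["epochs"] = 8
    cfg["classify"]["cnn"]["n_filters"] = 2
    cfg["classify"]["decimate"] = 3
    cfg["classify"]["n_permutations"] = 200
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def build_scenario(leadfield: sourceloc.LeadField, sim_cfg: dict, seed: int) -> synthgen.SourceScenario:
    """Resolve region-level effect specs to concrete grid indices.

    Within each named region, ``n_sources`` grid points are picked at
    evenly spaced positions of the region's index list (deterministic
    for a given grid).
    """
    active = []
    for eff in sim_cfg.get("effects", []):
        idx = np.where(leadfield.grid.regions == eff["region"])[0]
        if len(idx) == 0:
            raise ValueError(f"region {eff['region']!r} empty on this grid")
        n = min(eff.get("n_sources", 1), len(idx))
        picks = idx[np.linspace(0, len(idx) - 1, n).astype(int)]
        for p in picks:
            active.append(
                (int(p), eff["band"], float(eff["gain_remembered"]), float(eff["gain_forgotten"]), eff["window"])
            )
    return synthgen.SourceScenario(
        active_sources=tuple(active),
        noise_exponent=sim_cfg.get("noise_exponent", 1.0),
        artifact_rate=sim_cfg.get("artifact_rate", 0.0),
        snr_db=sim_cfg.get("snr_db", 0.0),
        seed=seed,
    )


def simulate_subject(montage, leadfield, config: dict, subject_seed: int):
    """Behavior table plus raw encoding-task EEG for one subject."""
    beh_cfg = config["behavior"]
    behavior = synthgen.generate_behavior(
        n_encoding=beh_cfg["n_encoding"],
        n_new=beh_cfg["n_new"],
        p_remember=beh_cfg["p_remember"],
        p_false_remember=beh_cfg["p_false_remember"],
        seed=subject_seed,
    )
    scenario = build_scenario(leadfield, config["simulate"], subject_seed)
    raw = synthgen.generate_raw(
        montage, leadfield, behavior, scenario, fs=config["simulate"]["fs"]
    )
    return behavior, raw


def _band_power_features(es, windows: dict) -> np.ndarray:
    """Per-trial band-power means over the analysis windows, flattened."""
    bp = band_average(tf_power(es, SpectralConfig()))
    cols = []
    for wrange in windows.values():
        wm = window_mean(bp, tuple(wrange))
        for name in wm.bands:
            cols.append(wm.bands[name].reshape(es.n_trials, -1).mean(axis=1, keepdims=True))
    return np.hstack(cols)


def run_all(config: dict | None = None, seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns the in-memory results.

    Stages: per-subject simulation and preprocessing; shared lead field
    and inverse (noise covariance pooled over subjects' pre-stimulus
    baselines); the sensor-vs-source classification comparison with
    repeated-measures ANOVA, post-hocs and permutation nulls; the
    behavioral report; and a hierarchical-regression comparison of
    sensor vs sensor+source band-power features.
    """
    config = copy.deepcopy(config) if config else default_config()
    chash = config_hash(config)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=logging.INFO)
    montage = default_montage()
    sl_cfg = config["sourceloc"]
    leadfield = sourceloc.build_leadfield(
        montage, n_sources=sl_cfg["n_sources"], n_terms=sl_cfg["n_terms"]
    )

    behaviors, epoch_sets = [], []
    counts = []
    for si in range(config["n_subjects"]):
        subject_seed = seed * 1009 + si
        behavior, raw = simulate_subject(montage, leadfield, config, subject_seed)
        pp = config["preprocess"]
        es, rejected = preprocess.run_preprocess(
            raw,
            behavior,
            montage,
            target_fs=pp["target_fs"],
            band=tuple(pp["band"]),
            filter_order=pp["filter_order"],
            window_ms=tuple(pp["window_ms"]),
            baseline_mode=pp["baseline"],
            reject_uv=pp["reject_uv"],
        )
        behaviors.append(behavior)
        epoch_sets.append(es)
        counts.append(
            {
                "subject": si,
                "trials_kept": es.n_trials,
                "trials_rejected": len(rejected),
                "remembered": int(np.sum(es.labels == "remembered")),
                "forgotten": int(np.sum(es.labels == "forgotten")),
            }
        )
        logger.info("subject %d: %s", si, counts[-1])
        if out:
            write_behavior(behavior, out / f"behavior_s{si:02d}.tsv")
            if config.get("save_intermediates", True):
                write_epochs(es, out / f"epochs_s{si:02d}.npz")

    # pooled pre-stimulus noise covariance, one inverse for the shared montage
    covs = [
        sourceloc.estimate_noise_cov(
            es, tuple(sl_cfg["noise_window_ms"]), sl_cfg["noise_reg"]
        ).matrix
        for es in epoch_sets
    ]
    noise_cov = sourceloc.NoiseCovariance(
        matrix=np.mean(covs, axis=0),
        n_samples_used=sum(es.n_trials * int(es.time_mask(tuple(sl_cfg["noise_window_ms"])).sum()) for es in epoch_sets),
        regularization=sl_cfg["noise_reg"],
    )
    lambda2 = sourceloc.auto_lambda2(leadfield, noise_cov, snr=sl_cfg["snr"])
    inverse = sourceloc.make_inverse(leadfield, noise_cov, lambda2)

    cls_cfg = config["classify"]
    cnn_cfg = CNNConfig(
        n_filters=cls_cfg["cnn"]["n_filters"],
        epochs=cls_cfg["cnn"]["epochs"],
        lr=cls_cfg["cnn"]["lr"],
        batch_size=cls_cfg["cnn"]["batch_size"],
        dropout_p=cls_cfg["cnn"]["dropout_p"],
    )
    report = classify.run_comparison(
        epoch_sets,
        inverse,
        bands=tuple(cls_cfg["bands"]),
        windows={k: tuple(v) for k, v in cls_cfg["windows"].items()},
        models=tuple(cls_cfg["models"]),
        seed=seed,
        gamma=cls_cfg["gamma"],
        cnn_config=cnn_cfg,
        decimate=cls_cfg["decimate"],
        filter_order=cls_cfg["filter_order"],
        n_permutations=cls_cfg["n_permutations"],
    )

    behavior_report = stats.behavior_stats(behaviors) if len(behaviors) >= 2 else None

    # hierarchical regression: does adding source-space band power explain
    # outcome variance beyond sensor band power?
    hlr = None
    if len(epoch_sets) >= 2:
        windows = {k: tuple(v) for k, v in cls_cfg["windows"].items()}
        ys, xb, xa = [], [], []
        n_obs = min(
            int(np.sum(np.isin(es.labels, ["remembered", "forgotten"]))) for es in epoch_sets
        )
        for es in epoch_sets:
            keep = np.where(np.isin(es.labels, ["remembered", "forgotten"]))[0][:n_obs]
            sel = es.select_trials(keep)
            y = (sel.labels == "remembered").astype(float)
            src = sourceloc.parcellate(sourceloc.apply_inverse(sel, inverse), inverse.grid)
            ys.append(y)
            xb.append(_band_power_features(sel, windows))
            xa.append(_band_power_features(src, windows))
        hlr = stats.hlr_compare(np.stack(ys), np.stack(xb), np.stack(xa))

    results = {
        "config": config,
        "config_hash": chash,
        "seed": seed,
        "trial_counts": pd.DataFrame(counts),
        "comparison": report,
        "behavior": behavior_report,
        "hlr": hlr,
    }
    if out:
        _write_run(out, results)
    return results


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_run(out: Path, results: dict) -> None:
    provenance = {"config_hash": results["config_hash"], "seed": results["seed"]}
    (out / "config_snapshot.json").write_text(
        json.dumps({**provenance, "config": _json_safe(results["config"])}, indent=1)
    )
    rep: classify.ComparisonReport = results["comparison"]
    for name, df in [
        ("auc_table", rep.table),
        ("auc_summary", rep.summary),
        ("null_bands", rep.null95),
        ("trial_counts", results["trial_counts"]),
    ]:
        df = df.copy()
        df.attrs.update(provenance)
        write_report(df, out / name, units={"auc": "%", "amplitude": "uV", "time": "ms"})
    statblock = {
        **provenance,
        "anova": {f"{w}/{m}": v for (w, m), v in rep.anova.items()},
        "posthoc": {f"{w}/{m}": v for (w, m), v in rep.posthoc.items()},
    }
    if results["behavior"] is not None:
        b = results["behavior"]
        statblock["behavior"] = {
            "rt_anova": b["rt_anova"],
            "rt_posthoc": b["rt_posthoc"],
            "judgment_t": b["judgment_t"],
        }
    if results["hlr"] is not None:
        h = results["hlr"]
        statblock["hlr"] = {
            "r2_base_mean": float(h.r2_base.mean()),
            "r2_full_mean": float(h.r2_full.mean()),
            "t_r2": h.t_r2,
            "p_r2": h.p_r2,
            "t_f": h.t_f,
            "p_f": h.p_f,
        }
    (out / "stats.json").write_text(json.dumps(_json_safe(statblock), indent=1, default=str))
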