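"""Configuration files and result logs.

Experiment configurations round-trip through YAML; weight snapshots and
per-trial series are written as CSV (one row per granular state for the
PF-PC matrix, one row per muscle for the DCN-afferent vectors); experiment
summaries are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arm import ArmModel
from .control import ExperimentConfig, ExperimentResult, IOEncodingSpec, TrajectorySpec
from .network import NetworkConfig, WeightSet
from .plasticity import PlasticityParams, SiteRates

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "save_weights",
    "load_weights",
    "save_result",
]


def _plain(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, tuple):
        return [_plain(v) for v in value]
    if isinstance(value, list):
        return [_plain(v) for v in value]
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {f.name: _plain(getattr(value, f.name)) for f in dataclasses.fields(value)}
    return value


def config_to_dict(cfg: ExperimentConfig) -> dict:
    return _plain(cfg)


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    if d.get("plasticity") is not None:
        p = dict(d["plasticity"])
        for site in ("pf_pc", "mf_dcn", "pc_dcn"):
            if p.get(site) is not None:
                p[site] = SiteRates(**p[site])
        d["plasticity"] = PlasticityParams(**p)
    if d.get("network") is not None:
        d["network"] = NetworkConfig(**d["network"])
    if d.get("trajectory") is not None:
        t = dict(d["trajectory"])
        if t.get("amplitudes") is not None:
            t["amplitudes"] = tuple(t["amplitudes"])
        d["trajectory"] = TrajectorySpec(**t)
    if d.get("io_encoding") is not None:
        d["io_encoding"] = IOEncodingSpec(**d["io_encoding"])
    if d.get("arm") is not None:
        d["arm"] = ArmModel(**d["arm"])
    if d.get("fixed_io_weights") is not None:
        d["fixed_io_weights"] = np.asarray(d["fixed_io_weights"], dtype=float)
    if d.get("payload_schedule") is not None:
        d["payload_schedule"] = tuple((float(p), int(n)) for p, n in d["payload_schedule"])
    return ExperimentConfig(**d)


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> ExperimentConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def save_weights(weights: WeightSet, out_dir) -> None:
    """PF-PC matrix (row per state) and DCN-afferent vectors (row per muscle)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = weights.w_pf_pc.shape[1]
    pf = pd.DataFrame(weights.w_pf_pc,
                      columns=[f"muscle_{i}" for i in range(m)])
    pf.insert(0, "state", np.arange(weights.w_pf_pc.shape[0]))
    pf.to_csv(out_dir / "w_pf_pc.csv", index=False)
    dcn = pd.DataFrame({
        "muscle": np.arange(m),
        "w_mf_dcn": weights.w_mf_dcn,
        "w_pc_dcn": weights.w_pc_dcn,
        "w_io_dcn": weights.w_io_dcn,
    })
    dcn.to_csv(out_dir / "w_dcn_afferents.csv", index=False)


def load_weights(out_dir) -> WeightSet:
    out_dir = Path(out_dir)
    pf = pd.read_csv(out_dir / "w_pf_pc.csv")
    dcn = pd.read_csv(out_dir / "w_dcn_afferents.csv")
    return WeightSet(
        w_pf_pc=pf.drop(columns="state").to_numpy(dtype=float),
        w_mf_dcn=dcn["w_mf_dcn"].to_numpy(dtype=float),
        w_pc_dcn=dcn["w_pc_dcn"].to_numpy(dtype=float),
        w_io_dcn=dcn["w_io_dcn"].to_numpy(dtype=float),
    )


def save_result(res: ExperimentResult, out_dir, summary_extra: dict | None = None) -> None:
    """Per-trial MAE CSV, weight-series CSV, JSON summary, resolved config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = res.mae.size
    mae = pd.DataFrame({"trial": np.arange(1, n + 1), "mae": res.mae,
                        "payload_kg": res.payload,
                        "unstable": res.unstable.astype(int)})
    for j in range(res.mae_per_joint.shape[1]):
        mae[f"mae_joint_{j + 1}"] = res.mae_per_joint[:, j]
    mae.to_csv(out_dir / "mae_per_trial.csv", index=False)

    frames = []
    for site, series in (("mf_dcn", res.w_mf), ("pc_dcn", res.w_pc),
                         ("io_dcn", res.w_io)):
        for i in range(series.shape[1]):
            frames.append(pd.DataFrame({
                "trial": np.arange(1, n + 1), "site": site, "muscle": i,
                "value": series[:, i],
            }))
    pd.concat(frames, ignore_index=True).to_csv(out_dir / "weights_per_trial.csv",
                                                index=False)
    save_weights(res.weights, out_dir / "final_weights")
    save_config(res.config, out_dir / "config.yaml")

    tail = max(1, n // 10)
    summary = {
        "n_trials": int(n),
        "mae_trial_1": float(res.mae[0]),
        "mae_final_avg": float(np.mean(res.mae[-tail:])),
        "any_unstable": bool(res.unstable.any()),
        "io_share_first_decile": float(np.mean(res.io_share[:tail])),
        "io_share_last_decile": float(np.mean(res.io_share[-tail:])),
    }
    if summary_extra:
        summary.update(summary_extra)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
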