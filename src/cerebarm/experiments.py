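"""Scenario presets and experiment-level drivers.

The presets reproduce, at a configurable trial count, the study's scenario
matrix: distributed DCN learning under a 2 kg or 10 kg payload, the same with
a fixed pre-calculated IO-DCN connection, the self-adaptive IO-DCN
connection, the MTP/MTD modulating-term sweep, and the external-force-field
task. Full-length runs use 5000 trials; scaled-down runs (>= 200 trials)
keep the same constants and reproduce the qualitative phenomena.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .control import ExperimentConfig, resolve_config, run_experiment
from .metrics import LearningCurve, convergence_samples, detect_windup
from .plasticity import PlasticityParams

__all__ = [
    "SCENARIOS",
    "preset",
    "precalculate_io_weights",
    "compare_convergence",
    "run_mt_sweep",
    "MT_SWEEP_VALUES",
]

#: Modulating-term base values of the sweep experiment.
MT_SWEEP_VALUES = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)

SCENARIOS = {
    "fig3_2kg": "2 kg payload; PF-PC, MF-DCN, PC-DCN plasticity; no IO-DCN",
    "fig3_10kg": "10 kg payload; PF-PC, MF-DCN, PC-DCN plasticity; no IO-DCN",
    "fig3_generalization": "2 kg then 10 kg without weight reset",
    "fig4_fixed": "2 kg; cortical plasticity plus fixed pre-calculated IO-DCN",
    "fig4_io_only": "2 kg; fixed IO-DCN connection alone, cortical sites frozen",
    "fig5_adaptive": "2 kg; all four sites adaptive (self-adaptive IO-DCN)",
    "fig5_adaptive_10kg": "10 kg; all four sites adaptive",
    "fig6_sweep": "2 kg; adaptive IO-DCN, MTP/MTD base swept 0.001..1000",
    "fig7_force": "external force field; all four sites; MTP/MTD base 10",
}


def preset(name: str, n_trials: int = 500, seed: int = 0) -> ExperimentConfig:
    """Fully resolved configuration for a named scenario.

    ``fig6_sweep`` returns the base configuration of the sweep; expand it
    with :func:`run_mt_sweep` over :data:`MT_SWEEP_VALUES`.
    """
    if name not in SCENARIOS:
        known = ", ".join(sorted(SCENARIOS))
        raise KeyError(f"unknown scenario {name!r}; known scenarios: {known}")

    base = ExperimentConfig(n_trials=n_trials, seed=seed)
    if name == "fig3_2kg":
        cfg = replace(base, payload_kg=2.0, io_dcn_mode="off")
    elif name == "fig3_10kg":
        cfg = replace(base, payload_kg=10.0, io_dcn_mode="off")
    elif name == "fig3_generalization":
        cfg = replace(base, payload_kg=2.0, io_dcn_mode="off",
                      payload_schedule=((2.0, n_trials), (10.0, n_trials)))
    elif name == "fig4_fixed":
        cfg = replace(base, payload_kg=2.0, io_dcn_mode="fixed")
    elif name == "fig4_io_only":
        cfg = replace(base, payload_kg=2.0, io_dcn_mode="fixed",
                      plasticity=PlasticityParams().with_sites(
                          pf_pc=False, mf_dcn=False, pc_dcn=False))
    elif name == "fig5_adaptive":
        cfg = replace(base, payload_kg=2.0, io_dcn_mode="adaptive")
    elif name == "fig5_adaptive_10kg":
        cfg = replace(base, payload_kg=10.0, io_dcn_mode="adaptive")
    elif name == "fig6_sweep":
        cfg = replace(base, payload_kg=2.0, io_dcn_mode="adaptive")
    elif name == "fig7_force":
        cfg = replace(base, payload_kg=0.0, force_field_enabled=True,
                      io_dcn_mode="adaptive",
                      plasticity=replace(PlasticityParams(), mt_base=10.0))
    cfg = resolve_config(cfg)
    if cfg.io_dcn_mode == "fixed" and cfg.fixed_io_weights is None:
        cfg = replace(cfg, fixed_io_weights=precalculate_io_weights(cfg))
    return cfg


def precalculate_io_weights(cfg: ExperimentConfig, n_ref_trials: int = 200) -> np.ndarray:
    """Pre-calculated (frozen) IO-DCN weights for the fixed-connection mode.

    Obtained by running the same scenario with a self-adaptive IO-DCN
    connection and time-averaging the per-step IO-DCN weight over the whole
    reference run. The average is dominated by the early phase in which the
    connection is active, which is exactly the operating range the frozen
    connection must reproduce.
    """
    ref = replace(cfg, io_dcn_mode="adaptive", fixed_io_weights=None,
                  n_trials=n_ref_trials, payload_schedule=None)
    res = run_experiment(ref)
    return res.w_io_mean.mean(axis=0)


def compare_convergence(preset_a: str | ExperimentConfig,
                        preset_b: str | ExperimentConfig,
                        n_trials: int = 500, seed: int = 0,
                        **conv_kw) -> dict:
    """Fold acceleration of scenario B relative to scenario A.

    Runs both scenarios and returns samples-to-convergence(A) divided by
    samples-to-convergence(B), together with the underlying counts and
    convergence flags.
    """
    def _cfg(x):
        return preset(x, n_trials=n_trials, seed=seed) if isinstance(x, str) else x

    out = {}
    counts = {}
    for key, scenario in (("a", _cfg(preset_a)), ("b", _cfg(preset_b))):
        res = run_experiment(scenario)
        curve = LearningCurve(res.mae, res.mae_per_joint, res.unstable)
        count, converged = convergence_samples(curve, **conv_kw)
        counts[key] = count
        out[f"samples_{key}"] = count
        out[f"converged_{key}"] = converged
        out[f"final_mae_{key}"] = float(np.mean(res.mae[-max(1, len(res.mae) // 10):]))
    out["fold_acceleration"] = counts["a"] / counts["b"]
    out["flagged"] = not (out["converged_a"] and out["converged_b"])
    return out


def run_mt_sweep(n_trials: int = 400, seed: int = 0,
                 values=MT_SWEEP_VALUES) -> dict:
    """MTP/MTD modulating-term sweep (2 kg payload, adaptive IO-DCN).

    Returns, per base value: samples to convergence, converged flag, windup
    flag and onset, and final MAE.
    """
    rows = {}
    for v in values:
        cfg = preset("fig6_sweep", n_trials=n_trials, seed=seed)
        cfg = replace(cfg, plasticity=replace(cfg.plasticity, mt_base=float(v)))
        res = run_experiment(cfg)
        curve = LearningCurve(res.mae, res.mae_per_joint, res.unstable)
        count, converged = convergence_samples(curve)
        windup, onset = detect_windup(curve, res.w_io)
        rows[v] = {
            "samples": count,
            "converged": converged,
            "windup": windup,
            "windup_onset": onset,
            "final_mae": float(np.mean(res.mae[-max(1, n_trials // 10):])),
        }
    return rows
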