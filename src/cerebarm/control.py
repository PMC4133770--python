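"""Closed feedforward control loop.

Each 1 s trial tracks the "eight-shape" joint-space benchmark::

    Q_n(t) = A_n * sin(-4*pi*t^3 + 6*pi*t^2 + C_n),   C_n = n*pi/4

whose cubic phase polynomial advances by exactly 2*pi over the trial with
zero endpoint rate, so every trial starts and ends at the same pose with zero
velocity. A crude inverse-dynamics model of the *nominal* arm (no payload, no
force field) supplies the feedforward torque; the mismatch introduced by the
manipulated mass or the force field is the learning problem. The cerebellar
network adds a corrective torque per joint from its agonist/antagonist DCN
pair, the joint position error is translated into the inferior-olive teaching
signal, and the enabled plasticity rules update the weights once per 2 ms
step.

The per-step loop is executed by a fused numba kernel for speed;
:func:`run_trial_reference` is the pure-Python modular path built from the
public network/plasticity/plant operations, and the two are asserted
equivalent in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _fast
from .arm import (ArmModel, ArmState, ForceFieldSpec, default_arm,
                  force_field, inverse_dynamics, step)
from .network import NetworkConfig, NetworkSignals, WeightSet, dcn_rate, encode_state, pc_rate
from .plasticity import PlasticityParams, apply_updates

__all__ = [
    "TrajectorySpec",
    "IOEncodingSpec",
    "ExperimentConfig",
    "TrialLog",
    "ExperimentResult",
    "desired_trajectory",
    "crude_command",
    "encode_io",
    "corrective_torque",
    "run_trial",
    "run_trial_reference",
    "run_experiment",
    "calibrate_output_gain",
    "calibrate_e_sat",
    "resolve_config",
]


@dataclass
class TrajectorySpec:
    """Eight-shape benchmark trajectory in joint coordinates."""

    amplitudes: tuple[float, float, float] = (0.2, 0.2, 0.2)  # rad
    duration: float = 1.0  # s

    def phases(self) -> np.ndarray:
        """C_n = n*pi/4 for joints n = 1..3."""
        return np.array([1.0, 2.0, 3.0]) * np.pi / 4.0


@dataclass
class IOEncodingSpec:
    """Joint position error -> normalized IO (climbing-fiber) rate.

    ``e_sat`` is the error (rad) that saturates the IO rate at 1; each
    joint's signed error drives its agonist channel when positive and its
    antagonist channel when negative, so at most one of the pair is active.

    One IO signal serves both the DCN collateral drive and every learning
    rule; two latencies shape its timing:

    ``sensor_delay_steps`` is the proprioceptive/olivary latency: the error
    measured at control step k reaches the network (DCN drive and plasticity)
    at step k + 1 + sensor_delay_steps. Default 0: the DCN output equation
    drives the nuclei with the instantaneous IO rate; a nonzero value models
    a proprioceptive/olivary loop latency.

    ``delay_steps`` is the teaching alignment: the error measured at step k
    credits the granular state active at step k - delay_steps. The
    climbing-fiber signal teaches parallel-fiber synapses active tens of
    milliseconds earlier (the eligibility window), and the plant's
    position-error response to a torque change is smeared over a comparable
    time, so the default (25 steps = 50 ms) pairs each state with the error
    its own motor action produced.
    """

    e_sat: float = 0.3       # rad
    delay_steps: int = 25
    sensor_delay_steps: int = 0

    def __post_init__(self) -> None:
        if self.e_sat <= 0:
            raise ValueError("e_sat must be positive")
        if self.delay_steps < 0 or self.sensor_delay_steps < 0:
            raise ValueError("latencies must be non-negative")


@dataclass
class ExperimentConfig:
    """One learning scenario (payload, force field, plasticity sites, trials)."""

    payload_kg: float = 2.0
    force_field_enabled: bool = False
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    io_dcn_mode: str = "off"              # off | fixed | adaptive
    fixed_io_weights: np.ndarray | None = None
    n_trials: int = 500
    output_gain: float | None = None      # N*m per unit DCN rate difference
    io_encoding: IOEncodingSpec | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    arm: ArmModel | None = None           # nominal arm; default_arm() if None
    initial_weights: str = "operating"    # operating | zeros
    qd_bound: float = 100.0               # rad/s instability bound
    qerr_bound: float = float(np.pi)      # rad instability bound
    abort_on_instability: bool = False
    payload_schedule: tuple[tuple[float, int], ...] | None = None  # (payload_kg, n_trials) blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.payload_kg < 0:
            raise ValueError("payload_kg must be non-negative")
        if self.io_dcn_mode not in ("off", "fixed", "adaptive"):
            raise ValueError("io_dcn_mode must be off, fixed or adaptive")
        if self.initial_weights not in ("operating", "zeros"):
            raise ValueError("initial_weights must be 'operating' or 'zeros'")


@dataclass
class TrialLog:
    """Per-step record of one trial plus its summary metrics."""

    t: np.ndarray          # (n_steps,)
    q_des: np.ndarray      # (n_steps, 3) desired position at each step end
    q: np.ndarray          # (n_steps, 3)
    qd: np.ndarray         # (n_steps, 3)
    tau: np.ndarray        # (n_steps, 3) total commanded torque (saturated)
    err: np.ndarray        # (n_steps, 3) q_des - q
    io: np.ndarray         # (n_steps, 6) IO signal entering the network
    mae_per_joint: np.ndarray
    mae: float
    unstable: bool
    contrib_io: float      # summed |IO-DCN| drive over the trial
    contrib_ctx: float     # summed |MF-DCN - PC*PC-DCN| drive over the trial
    w_io_mean: np.ndarray  # time-averaged IO-DCN weight per muscle


@dataclass
class ExperimentResult:
    """Per-trial series of a learning run."""

    mae: np.ndarray             # (n_trials,)
    mae_per_joint: np.ndarray   # (n_trials, 3)
    unstable: np.ndarray        # (n_trials,) bool
    w_mf: np.ndarray            # (n_trials, 6) end-of-trial weights
    w_pc: np.ndarray
    w_io: np.ndarray
    w_io_mean: np.ndarray       # (n_trials, 6) within-trial time averages
    contrib_io: np.ndarray      # (n_trials,)
    contrib_ctx: np.ndarray
    payload: np.ndarray         # (n_trials,) payload in effect each trial
    weights: WeightSet          # final weights
    config: ExperimentConfig

    @property
    def io_share(self) -> np.ndarray:
        """Per-trial share of the DCN drive contributed by the IO-DCN path."""
        tot = self.contrib_io + self.contrib_ctx
        return np.divide(self.contrib_io, tot, out=np.zeros_like(tot),
                         where=tot > 0)


def desired_trajectory(spec: TrajectorySpec, t):
    """Desired (q, qd, qdd) at time ``t`` (scalar or array).

    Velocity and acceleration come from analytic differentiation: the phase
    rate is 12*pi*t*(1 - t) (for a 1 s trial), zero at both endpoints.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > spec.duration):
        raise ValueError("t outside [0, duration]")
    s = t / spec.duration
    A = np.asarray(spec.amplitudes, dtype=float)
    C = spec.phases()
    tt = s[..., None] if s.ndim else s
    phi = -4.0 * np.pi * tt**3 + 6.0 * np.pi * tt**2
    dphi = (12.0 * np.pi * tt * (1.0 - tt)) / spec.duration
    ddphi = (12.0 * np.pi * (1.0 - 2.0 * tt)) / spec.duration**2
    q = A * np.sin(phi + C)
    qd = A * np.cos(phi + C) * dphi
    qdd = -A * np.sin(phi + C) * dphi**2 + A * np.cos(phi + C) * ddphi
    return q, qd, qdd


def crude_command(nominal_model: ArmModel, q_d, qd_d, qdd_d) -> np.ndarray:
    """Feedforward torque from the crude (payload-free) inverse model."""
    if nominal_model.payload_mass != 0.0:
        raise ValueError("the crude inverse model must carry no payload")
    return inverse_dynamics(nominal_model, ArmState(q=q_d, qd=qd_d, qdd=qdd_d))


def encode_io(e: np.ndarray, spec: IOEncodingSpec) -> np.ndarray:
    """Per-joint signed error -> 6-channel IO rate in [0, 1].

    Positive error drives the agonist channel, negative the antagonist, each
    clipped at the saturation error; at most one of the pair is nonzero.
    """
    e = np.asarray(e, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("error vector must be finite")
    io = np.zeros(2 * e.shape[0])
    x = e / spec.e_sat
    io[0::2] = np.clip(x, 0.0, 1.0)
    io[1::2] = np.clip(-x, 0.0, 1.0)
    return io


def corrective_torque(dcn: np.ndarray, gain: float) -> np.ndarray:
    """Net corrective torque per joint: gain * (agonist - antagonist DCN)."""
    dcn = np.asarray(dcn, dtype=float)
    if np.any(dcn < 0):
        raise ValueError("DCN rates must be non-negative")
    return gain * (dcn[0::2] - dcn[1::2])


# ---------------------------------------------------------------------------
# calibration procedures (documented design decisions, exposed in config)
# ---------------------------------------------------------------------------

def calibrate_output_gain(nominal_model: ArmModel, traj: TrajectorySpec,
                          network: NetworkConfig, heavy_payload_kg: float = 10.0) -> float:
    """Torque per unit DCN rate difference.

    Set so that a full-scale DCN difference of 1 can supply the peak torque
    deficit introduced by the heavy (10 kg) payload along the desired
    trajectory, i.e. the cerebellar output range spans the worst-case
    correction the experiments demand.
    """
    heavy = nominal_model.with_payload(heavy_payload_kg)
    ts = np.arange(network.n_states) * network.dt
    peak = 0.0
    for t in ts:
        q, qd, qdd = desired_trajectory(traj, float(t))
        st = ArmState(q=q, qd=qd, qdd=qdd)
        deficit = inverse_dynamics(heavy, st) - inverse_dynamics(nominal_model, st)
        peak = max(peak, float(np.max(np.abs(deficit))))
    return peak


def calibrate_e_sat(cfg: ExperimentConfig, reference_payload_kg: float = 2.0,
                    quantile: float = 0.95) -> float:
    """IO saturation error from a single no-learning reference trial.

    Runs one trial with the light payload and all plasticity off and returns
    the 95th percentile of the absolute per-step joint errors, so the IO
    signal spans (0, 1] early in learning and is small once errors shrink.
    """
    frozen = replace(
        cfg,
        payload_kg=reference_payload_kg,
        n_trials=1,
        io_dcn_mode="off",
        plasticity=cfg.plasticity.with_sites(pf_pc=False, mf_dcn=False,
                                             pc_dcn=False, io_dcn=False),
        io_encoding=IOEncodingSpec(e_sat=1.0),
        output_gain=0.0,
        payload_schedule=None,
    )
    log, _ = run_trial(frozen, WeightSet.zeros(cfg.network),
                       _plant_model(frozen).with_payload(reference_payload_kg))
    return float(np.quantile(np.abs(log.err), quantile))


def resolve_config(cfg: ExperimentConfig) -> ExperimentConfig:
    """Fill in calibrated defaults (output gain, IO saturation error)."""
    out = cfg
    if out.arm is None:
        out = replace(out, arm=default_arm())
    if out.output_gain is None:
        gain = calibrate_output_gain(out.arm, out.trajectory, out.network)
        out = replace(out, output_gain=gain)
    if out.io_encoding is None:
        out = replace(out, io_encoding=IOEncodingSpec(e_sat=1.0))
        e_sat = calibrate_e_sat(out)
        out = replace(out, io_encoding=IOEncodingSpec(e_sat=e_sat))
    return out


# ---------------------------------------------------------------------------
# trial drivers
# ---------------------------------------------------------------------------

def _plant_model(cfg: ExperimentConfig) -> ArmModel:
    return cfg.arm if cfg.arm is not None else default_arm()


def _effective_plasticity(cfg: ExperimentConfig) -> PlasticityParams:
    """Apply the io_dcn_mode contract to the plasticity flags."""
    p = cfg.plasticity
    if cfg.io_dcn_mode == "adaptive":
        return p.with_sites(io_dcn=True)
    return p.with_sites(io_dcn=False)


def _initial_io_weights(cfg: ExperimentConfig, weights: WeightSet) -> np.ndarray:
    if cfg.io_dcn_mode == "fixed":
        if cfg.fixed_io_weights is None:
            raise ValueError("io_dcn_mode='fixed' requires fixed_io_weights")
        return np.asarray(cfg.fixed_io_weights, dtype=float).copy()
    if cfg.io_dcn_mode == "off":
        return np.zeros_like(weights.w_io_dcn)
    return weights.w_io_dcn.copy()


def _trajectory_tables(cfg: ExperimentConfig):
    """Desired positions at step boundaries and the crude torque per step.

    The feedforward torque is held constant over each 2 ms step, so it is
    sampled at the step midpoint: this removes the first-order zero-order-
    hold bias and lets the crude model track the nominal plant to ~1e-5 rad.
    """
    net = cfg.network
    nominal = _plant_model(cfg).with_payload(0.0)
    n = net.n_states
    t_edges = np.arange(n + 1) * net.dt
    q_des = np.empty((n + 1, 3))
    tau_crude = np.empty((n, 3))
    for k, t in enumerate(t_edges):
        q_des[k] = desired_trajectory(cfg.trajectory, float(t))[0]
        if k < n:
            qm, qdm, qddm = desired_trajectory(cfg.trajectory, float(t) + 0.5 * net.dt)
            tau_crude[k] = crude_command(nominal, qm, qdm, qddm)
    return t_edges, q_des, tau_crude


def _kernel_args(cfg: ExperimentConfig, plant: ArmModel):
    axes, offs, coms, masses, inert, grav, ee, visc = plant.composite_params()
    ff = ForceFieldSpec(enabled=cfg.force_field_enabled)
    p = _effective_plasticity(cfg)
    net = cfg.network
    enc = cfg.io_encoding
    return dict(
        axes=axes, offs=offs, coms=coms, masses=masses, inert=inert,
        grav=grav, ee=ee, visc=visc,
        ff_on=ff.enabled, ff_amp=np.asarray(ff.amplitude, dtype=float),
        ff_omega=ff.omega, ff_phase=np.asarray(ff.phases, dtype=float),
        mf_baseline=net.mf_baseline,
        dcn_cap=-1.0 if net.dcn_cap is None else float(net.dcn_cap),
        gain=float(cfg.output_gain), e_sat=float(enc.e_sat), dt=net.dt,
        torque_limit=plant.torque_limit,
        pf_ltp=p.pf_pc.ltp_max, pf_ltd=p.pf_pc.ltd_max,
        mf_ltp=p.mf_dcn.ltp_max, mf_ltd=p.mf_dcn.ltd_max,
        pcd_ltp=p.pc_dcn.ltp_max, pcd_ltd=p.pc_dcn.ltd_max,
        mtp=p.mtp, mtd=p.mtd, alpha=p.alpha, w_max=p.w_max,
        en_pf=p.enabled_pf_pc, en_mf=p.enabled_mf_dcn,
        en_pcd=p.enabled_pc_dcn, en_io=p.enabled_io_dcn,
        pcd_linear=p.pc_dcn_linear_alpha,
        qd_bound=cfg.qd_bound, qerr_bound=cfg.qerr_bound,
        abort_on_instability=cfg.abort_on_instability,
    )


def run_trial(cfg: ExperimentConfig, weights: WeightSet, plant: ArmModel,
              _tables=None, _kargs=None) -> tuple[TrialLog, WeightSet]:
    """Run one closed-loop trial; returns the log and the post-trial weights.

    The plant is reset to the desired start pose (zero velocity): the
    benchmark trajectory is periodic with zero endpoint velocity, so trials
    are independent repetitions of the same movement.
    """
    cfg = resolve_config(cfg)
    net = cfg.network
    t_edges, q_des, tau_crude = _tables if _tables is not None else _trajectory_tables(cfg)
    kargs = _kargs if _kargs is not None else _kernel_args(cfg, plant)

    out = weights.copy()
    out.w_io_dcn = _initial_io_weights(cfg, weights)
    n = net.n_states

    log_q = np.empty((n, 3))
    log_qd = np.empty((n, 3))
    log_tau = np.empty((n, 3))
    log_err = np.empty((n, 3))
    log_io = np.empty((n, 6))

    q0, qd0, _ = desired_trajectory(cfg.trajectory, 0.0)
    p = _effective_plasticity(cfg)
    # in fixed mode the IO-DCN weights drive the DCN but must not adapt
    en_io = kargs["en_io"] and cfg.io_dcn_mode == "adaptive"

    abs_err, c_io, c_ctx, w_io_sum, steps_done, unstable = _fast.trial_kernel(
        kargs["axes"], kargs["offs"], kargs["coms"], kargs["masses"],
        kargs["inert"], kargs["grav"], kargs["ee"], kargs["visc"],
        kargs["ff_on"], kargs["ff_amp"], kargs["ff_omega"], kargs["ff_phase"],
        tau_crude, q_des,
        out.w_pf_pc, out.w_mf_dcn, out.w_pc_dcn, out.w_io_dcn,
        kargs["mf_baseline"], kargs["dcn_cap"], kargs["gain"], kargs["e_sat"],
        kargs["dt"], kargs["torque_limit"],
        kargs["pf_ltp"], kargs["pf_ltd"], kargs["mf_ltp"], kargs["mf_ltd"],
        kargs["pcd_ltp"], kargs["pcd_ltd"], kargs["mtp"], kargs["mtd"],
        kargs["alpha"], kargs["w_max"],
        kargs["en_pf"], kargs["en_mf"], kargs["en_pcd"], en_io,
        kargs["pcd_linear"],
        cfg.io_encoding.sensor_delay_steps,
        1 + cfg.io_encoding.sensor_delay_steps + cfg.io_encoding.delay_steps,
        np.zeros((cfg.io_encoding.sensor_delay_steps + 1, net.n_muscles)),
        np.asarray(q0, dtype=float), np.asarray(qd0, dtype=float),
        kargs["qd_bound"], kargs["qerr_bound"], kargs["abort_on_instability"],
        log_q, log_qd, log_tau, log_err, log_io,
    )

    m = max(steps_done, 1)
    mae_j = abs_err / m
    log = TrialLog(
        t=t_edges[1:steps_done + 1],
        q_des=q_des[1:steps_done + 1],
        q=log_q[:steps_done], qd=log_qd[:steps_done],
        tau=log_tau[:steps_done], err=log_err[:steps_done],
        io=log_io[:steps_done],
        mae_per_joint=mae_j, mae=float(np.mean(mae_j)),
        unstable=bool(unstable),
        contrib_io=float(c_io), contrib_ctx=float(c_ctx),
        w_io_mean=w_io_sum / m,
    )
    return log, out


def run_trial_reference(cfg: ExperimentConfig, weights: WeightSet,
                        plant: ArmModel) -> tuple[TrialLog, WeightSet]:
    """Pure-Python trial built from the public modular operations.

    Slow; exists as the readable statement of the per-step loop and as the
    cross-check for the fused kernel.
    """
    cfg = resolve_config(cfg)
    net = cfg.network
    enc = cfg.io_encoding
    p = _effective_plasticity(cfg)
    if cfg.io_dcn_mode == "fixed":
        p = p.with_sites(io_dcn=False)
    ff = ForceFieldSpec(enabled=cfg.force_field_enabled)
    nominal = _plant_model(cfg).with_payload(0.0)

    w = weights.copy()
    w.w_io_dcn = _initial_io_weights(cfg, weights)
    q0, qd0, _ = desired_trajectory(cfg.trajectory, 0.0)
    state = ArmState(q=q0, qd=qd0)
    n = net.n_states

    rows = {k: [] for k in ("t", "q_des", "q", "qd", "tau", "err", "io")}
    abs_err = np.zeros(3)
    c_io = c_ctx = 0.0
    w_io_sum = np.zeros(net.n_muscles)
    unstable = False
    # IO arrival pipeline: the error of step k surfaces at k+1+sensor_delay
    pipe = [np.zeros(net.n_muscles) for _ in range(enc.sensor_delay_steps + 1)]

    for k in range(n):
        t = k * net.dt
        s = encode_state(t, net)
        io = pipe[0]
        pc = pc_rate(w, s)
        dcn = dcn_rate(w, pc, io, net.mf_baseline, net.dcn_cap)
        c_io += float(np.sum(io * w.w_io_dcn))
        c_ctx += float(np.sum(np.abs(net.mf_baseline * w.w_mf_dcn - pc * w.w_pc_dcn)))
        w_io_sum += w.w_io_dcn

        # feedforward sampled at the step midpoint (zero-order-hold match)
        q_d, qd_d, qdd_d = desired_trajectory(cfg.trajectory, t + 0.5 * net.dt)
        tau = crude_command(nominal, q_d, qd_d, qdd_d) + corrective_torque(dcn, cfg.output_gain)
        state = step(plant, state, tau, t, net.dt, ff)

        t_next = (k + 1) * net.dt
        q_des_next = desired_trajectory(cfg.trajectory, min(t_next, cfg.trajectory.duration))[0]
        err = q_des_next - state.q
        abs_err += np.abs(err)
        if np.any(np.abs(err) > cfg.qerr_bound) or np.any(np.abs(state.qd) > cfg.qd_bound):
            unstable = True

        rows["t"].append(t_next)
        rows["q_des"].append(q_des_next)
        rows["q"].append(state.q.copy())
        rows["qd"].append(state.qd.copy())
        rows["tau"].append(np.clip(tau, -plant.torque_limit, plant.torque_limit))
        rows["err"].append(err)
        rows["io"].append(io.copy())

        # the arriving IO signal teaches; the PF-PC rule credits the state
        # whose action the (sensor-delayed) error reflects
        kc = k - 1 - enc.sensor_delay_steps - enc.delay_steps
        w = apply_updates(w, NetworkSignals(state_index=kc, pc=pc, io=io,
                                            dcn=dcn, mf=net.mf_baseline),
                          p if kc >= 0 else p.with_sites(pf_pc=False))
        pipe = pipe[1:] + [encode_io(err, enc)]
        if unstable and cfg.abort_on_instability:
            break

    m = len(rows["t"])
    mae_j = abs_err / m
    log = TrialLog(
        t=np.array(rows["t"]), q_des=np.array(rows["q_des"]),
        q=np.array(rows["q"]), qd=np.array(rows["qd"]),
        tau=np.array(rows["tau"]), err=np.array(rows["err"]),
        io=np.array(rows["io"]),
        mae_per_joint=mae_j, mae=float(np.mean(mae_j)), unstable=unstable,
        contrib_io=c_io, contrib_ctx=c_ctx, w_io_mean=w_io_sum / m,
    )
    return log, w


def run_experiment(cfg: ExperimentConfig,
                   weights: WeightSet | None = None) -> ExperimentResult:
    """Run ``n_trials`` sequential trials carrying the weights forward.

    Deterministic given the configuration. ``payload_schedule`` (if set)
    switches the plant payload between blocks of trials without resetting
    the weights — the generalization protocol.
    """
    cfg = resolve_config(cfg)
    net = cfg.network
    if weights is not None:
        weights = weights.copy()
    elif cfg.initial_weights == "operating":
        weights = WeightSet.operating_point(net)
    else:
        weights = WeightSet.zeros(net)
    if cfg.io_dcn_mode in ("fixed", "off"):
        weights.w_io_dcn = _initial_io_weights(cfg, weights)
    schedule = cfg.payload_schedule or ((cfg.payload_kg, cfg.n_trials),)
    n_total = sum(nt for _, nt in schedule)

    tables = _trajectory_tables(cfg)
    mae = np.empty(n_total)
    mae_j = np.empty((n_total, 3))
    unstable = np.zeros(n_total, dtype=bool)
    w_mf = np.empty((n_total, net.n_muscles))
    w_pc = np.empty((n_total, net.n_muscles))
    w_io = np.empty((n_total, net.n_muscles))
    w_io_mean = np.empty((n_total, net.n_muscles))
    c_io = np.empty(n_total)
    c_ctx = np.empty(n_total)
    payload = np.empty(n_total)

    # once resolved, freeze io weights for fixed mode so that run_trial's
    # per-trial re-initialization is the identity
    trial_cfg = replace(cfg, payload_schedule=None)

    i = 0
    for payload_kg, nt in schedule:
        plant = _plant_model(cfg).with_payload(payload_kg)
        kargs = _kernel_args(cfg, plant)
        for _ in range(nt):
            log, weights = run_trial(trial_cfg, weights, plant,
                                     _tables=tables, _kargs=kargs)
            mae[i] = log.mae
            mae_j[i] = log.mae_per_joint
            unstable[i] = log.unstable
            w_mf[i] = weights.w_mf_dcn
            w_pc[i] = weights.w_pc_dcn
            w_io[i] = weights.w_io_dcn
            w_io_mean[i] = log.w_io_mean
            c_io[i] = log.contrib_io
            c_ctx[i] = log.contrib_ctx
            payload[i] = payload_kg
            i += 1

    return ExperimentResult(
        mae=mae, mae_per_joint=mae_j, unstable=unstable,
        w_mf=w_mf, w_pc=w_pc, w_io=w_io, w_io_mean=w_io_mean,
        contrib_io=c_io, contrib_ctx=c_ctx, payload=payload,
        weights=weights, config=cfg,
    )
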