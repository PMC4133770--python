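"""Rate-based cerebellar micro-circuit.

The network follows the classical Marr-Albus organization reduced to analog
(firing-rate) units. The granular layer acts as a clock: it unfolds a 1 s
movement into a sequence of one-hot "time stamp" states, one per 2 ms control
step, each state standing for one parallel fiber (PF). Purkinje cells (PCs)
read the active PF through a learned per-state weight, mossy fibers (MFs)
supply a constant baseline drive, and the deep cerebellar nuclei (DCN) combine
MF excitation, PC inhibition and an inferior-olive (IO) collateral excitation
into the output rate per muscle channel::

    DCN_i = max(0, mf_baseline * w_mf[i] - PC_i * w_pc[i] + IO_i * w_io[i])

Muscles are organized as agonist/antagonist pairs, two per joint: channel
``2*j`` is the agonist of joint ``j`` (drives positive torque), ``2*j + 1``
the antagonist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkConfig",
    "WeightSet",
    "NetworkSignals",
    "encode_state",
    "pc_rate",
    "dcn_rate",
]


@dataclass
class NetworkConfig:
    """Static sizes and rates of the cerebellar network.

    The number of granular states is tied to the movement: it equals the
    trial duration divided by the control time step, so each state is the
    unambiguous time stamp of one control step.
    """

    dt: float = 0.002            # control step, s
    trial_duration: float = 1.0  # s
    n_joints: int = 3
    mf_baseline: float = 1.0     # normalized MF rate in [0, 1]
    dcn_cap: float | None = None  # optional upper bound on the DCN rate

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.trial_duration <= 0:
            raise ValueError("dt and trial_duration must be positive")
        if not 0.0 <= self.mf_baseline <= 1.0:
            raise ValueError("mf_baseline must lie in [0, 1]")
        n = self.trial_duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration must be an integer multiple of dt")

    @property
    def n_states(self) -> int:
        """Number of granular time-stamp states (500 at 1 s / 2 ms)."""
        return int(round(self.trial_duration / self.dt))

    @property
    def n_muscles(self) -> int:
        """Two muscle channels (agonist/antagonist) per joint."""
        return 2 * self.n_joints


@dataclass
class WeightSet:
    """All adaptive synaptic strengths of the circuit.

    ``w_pf_pc`` is the per-state PC transfer table (one row per granular
    state, one column per muscle); the three DCN-afferent sites are one
    scalar weight per muscle. All weights are non-negative firing-rate
    synaptic strengths.
    """

    w_pf_pc: np.ndarray   # (n_states, n_muscles)
    w_mf_dcn: np.ndarray  # (n_muscles,)
    w_pc_dcn: np.ndarray  # (n_muscles,)
    w_io_dcn: np.ndarray  # (n_muscles,)

    @classmethod
    def zeros(cls, cfg: NetworkConfig) -> "WeightSet":
        m = cfg.n_muscles
        return cls(
            w_pf_pc=np.zeros((cfg.n_states, m)),
            w_mf_dcn=np.zeros(m),
            w_pc_dcn=np.zeros(m),
            w_io_dcn=np.zeros(m),
        )

    @classmethod
    def operating_point(cls, cfg: NetworkConfig, drive: float = 1.0) -> "WeightSet":
        """Pre-trained no-payload operating point.

        PCs sit mid-range (rate 0.5 at every state) and the DCN output is
        exactly nulled (``w_pc = 2 * w_mf``), so each muscle can push its DCN
        rate up to ``drive`` (PC silenced) or hold it at zero (PC saturated)
        from the very first trial. This is the state a circuit trained on
        the bare arm settles into: no correction delivered, full
        bidirectional headroom.
        """
        m = cfg.n_muscles
        return cls(
            w_pf_pc=np.full((cfg.n_states, m), 0.5),
            w_mf_dcn=np.full(m, drive),
            w_pc_dcn=np.full(m, 2.0 * drive),
            w_io_dcn=np.zeros(m),
        )

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.w_pf_pc.copy(),
            self.w_mf_dcn.copy(),
            self.w_pc_dcn.copy(),
            self.w_io_dcn.copy(),
        )

    def validate(self) -> None:
        for name in ("w_pf_pc", "w_mf_dcn", "w_pc_dcn", "w_io_dcn"):
            w = getattr(self, name)
            if not np.all(np.isfinite(w)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(w < 0):
                raise ValueError(f"{name} contains negative synaptic strengths")


@dataclass
class NetworkSignals:
    """One control step's firing rates (normalized units)."""

    state_index: int
    pc: np.ndarray            # (n_muscles,) in [0, 1]
    io: np.ndarray            # (n_muscles,) in [0, 1]
    dcn: np.ndarray           # (n_muscles,) >= 0
    mf: float = 1.0


def encode_state(t: float, cfg: NetworkConfig) -> int:
    """Map trial time ``t`` to the index of the active granular state.

    The same ``t`` maps to the same state on every trial, which is what lets
    PF-PC learning associate a correction with each point of the movement.
    """
    if not 0.0 <= t < cfg.trial_duration:
        raise ValueError(
            f"t={t} outside the trial interval [0, {cfg.trial_duration})"
        )
    # the 1e-9 guard absorbs round-off in t = k*dt grid times without
    # disturbing true floor semantics for off-grid t
    idx = int(t / cfg.dt + 1e-9)
    return min(idx, cfg.n_states - 1)


def pc_rate(weights: WeightSet, state_index: int) -> np.ndarray:
    """PC rate per muscle for the active state.

    The PC transfer function is realized as a lookup: the PC rate equals the
    active PF's synaptic weight, clipped to the normalized range [0, 1].
    """
    n_states = weights.w_pf_pc.shape[0]
    if not 0 <= state_index < n_states:
        raise IndexError(f"state_index {state_index} out of range [0, {n_states})")
    return np.clip(weights.w_pf_pc[state_index], 0.0, 1.0)


def dcn_rate(
    weights: WeightSet,
    pc: np.ndarray,
    io: np.ndarray,
    mf_baseline: float = 1.0,
    dcn_cap: float | None = None,
) -> np.ndarray:
    """DCN output rate per muscle.

    MF excitation (baseline times its weight) minus PC inhibition plus IO
    collateral excitation, floored at zero because a firing rate cannot be
    negative. The DCN rate is not capped at 1 by default: it is the
    torque-driving output whose physical gain is set outside the network
    (``dcn_cap`` provides an optional ceiling).
    """
    pc = np.asarray(pc, dtype=float)
    io = np.asarray(io, dtype=float)
    m = weights.w_mf_dcn.shape[0]
    if pc.shape != (m,) or io.shape != (m,):
        raise ValueError(
            f"pc/io must have shape ({m},), got {pc.shape} and {io.shape}"
        )
    rate = mf_baseline * weights.w_mf_dcn - pc * weights.w_pc_dcn + io * weights.w_io_dcn
    rate = np.maximum(rate, 0.0)
    if dcn_cap is not None:
        rate = np.minimum(rate, dcn_cap)
    return rate
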