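"""Three-link serial-arm plant.

A generic rigid 3-link arm stands in for the three active joints of a
light-weight manipulator: joint 1 rotates about the vertical axis, joints 2
and 3 about horizontal axes, an anthropomorphic shoulder/elbow arrangement.
Inverse dynamics follow the recursive Newton-Euler algorithm (outward
velocity/acceleration recursion, inward force recursion); forward dynamics
invert the joint-space inertia matrix extracted column-by-column from the
same recursion. A manipulated object (payload) is a point mass rigidly
attached at the end effector and is folded into the last link as a composite
rigid body, which is exact for a point mass.

The external force field of the perturbation experiments is a sinusoid per
Cartesian axis applied at the end effector::

    F_xyz(t) = 100 * cos(2*pi*10*t + C_xyz),   C = (pi/4, pi/2, 3*pi/4)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _fast

__all__ = [
    "ArmModel",
    "ArmState",
    "ForceFieldSpec",
    "default_arm",
    "force_field",
    "inverse_dynamics",
    "mass_matrix",
    "forward_dynamics",
    "step",
    "forward_kinematics",
    "total_energy",
]

_ZERO3 = np.zeros(3)


@dataclass
class ArmState:
    """Joint-space state (angles rad, velocities rad/s, accelerations rad/s^2)."""

    q: np.ndarray
    qd: np.ndarray
    qdd: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        self.qdd = np.asarray(self.qdd, dtype=float)

    def validate(self) -> None:
        for name in ("q", "qd", "qdd"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite entries in {name}")


@dataclass
class ForceFieldSpec:
    """Sinusoidal Cartesian force at the end effector.

    Defaults are the experiment's printed values: 100 N amplitude per axis,
    10 Hz, phases (pi/4, pi/2, 3*pi/4).
    """

    amplitude: tuple[float, float, float] = (100.0, 100.0, 100.0)  # N
    frequency_hz: float = 10.0
    phases: tuple[float, float, float] = (np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    enabled: bool = False

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency_hz


@dataclass
class ArmModel:
    """Kinematic and dynamic parameters of the 3-link serial arm.

    Per link: ``axes[i]`` is the joint axis in the parent frame, ``offsets[i]``
    the joint position in the parent frame, ``coms[i]`` the centre of mass and
    ``inertias[i]`` the inertia tensor about the COM, both in the link's own
    frame. ``payload_mass`` is a point mass at ``ee_offset`` (last link frame).
    """

    lengths: np.ndarray          # (3,) m, informational / used by default_arm
    axes: np.ndarray             # (3,3)
    offsets: np.ndarray          # (3,3)
    coms: np.ndarray             # (3,3)
    masses: np.ndarray           # (3,) kg
    inertias: np.ndarray         # (3,3,3) kg m^2
    ee_offset: np.ndarray        # (3,) end-effector point, last link frame
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -9.81]))
    payload_mass: float = 0.0    # kg, point mass at the end effector
    torque_limit: np.ndarray = field(default_factory=lambda: np.full(3, 250.0))
    viscous: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("lengths", "axes", "offsets", "coms", "masses", "inertias",
                     "ee_offset", "gravity", "torque_limit", "viscous"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.masses <= 0):
            raise ValueError("link masses must be positive")
        if np.any(self.lengths <= 0):
            raise ValueError("link lengths must be positive")
        if self.payload_mass < 0:
            raise ValueError("payload_mass must be non-negative")
        for i in range(3):
            I = self.inertias[i]
            if not np.allclose(I, I.T, atol=1e-12):
                raise ValueError(f"inertia tensor of link {i} is not symmetric")
            if np.any(np.linalg.eigvalsh(I) < -1e-12):
                raise ValueError(f"inertia tensor of link {i} is not PSD")

    def with_payload(self, payload_kg: float) -> "ArmModel":
        return replace(self, payload_mass=float(payload_kg))

    def composite_params(self):
        """Pack link parameters for the kernels, folding the payload into the
        last link (exact composite-rigid-body treatment of a point mass)."""
        masses = self.masses.copy()
        coms = self.coms.copy()
        inert = self.inertias.copy()
        mp = self.payload_mass
        if mp > 0.0:
            m = masses[2]
            c_new = (m * coms[2] + mp * self.ee_offset) / (m + mp)

            def shift(d, mass):
                # parallel-axis term for a displacement d of the reference point
                return mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))

            inert[2] = (inert[2] + shift(coms[2] - c_new, m)
                        + shift(self.ee_offset - c_new, mp))
            coms[2] = c_new
            masses[2] = m + mp
        return (self.axes, self.offsets, coms, masses, inert,
                self.gravity, self.ee_offset, self.viscous)


def default_arm(payload_kg: float = 0.0,
                lengths=(0.31, 0.40, 0.39),
                masses=(5.0, 4.0, 3.0)) -> ArmModel:
    """Anthropomorphic light-weight-robot-class default.

    A vertical base joint atop a short column and two horizontal-axis links,
    ~12 kg in total, so that the 2 kg and 10 kg payloads of the manipulation
    experiments are a significant fraction of the arm's own dynamics, and the
    payload's gravitational and inertial torque deficits along the benchmark
    trajectory are of comparable size. Joints carry a moderate viscous
    friction (5 N m s/rad), the dominant damping of a geared light-weight
    actuator.
    """
    lengths = np.asarray(lengths, dtype=float)
    masses = np.asarray(masses, dtype=float)

    def rod_x(m, L):
        return np.diag([1e-2, m * L**2 / 12.0, m * L**2 / 12.0])

    def rod_z(m, L):
        return np.diag([m * L**2 / 12.0, m * L**2 / 12.0, 1e-2])

    return ArmModel(
        lengths=lengths,
        axes=np.array([[0.0, 0.0, 1.0],   # base yaw, vertical
                       [0.0, 1.0, 0.0],   # shoulder pitch
                       [0.0, 1.0, 0.0]]),  # elbow pitch
        offsets=np.array([[0.0, 0.0, 0.0],
                          [0.0, 0.0, lengths[0]],
                          [lengths[1], 0.0, 0.0]]),
        coms=np.array([[0.0, 0.0, lengths[0] / 2.0],
                       [lengths[1] / 2.0, 0.0, 0.0],
                       [lengths[2] / 2.0, 0.0, 0.0]]),
        masses=masses,
        inertias=np.array([rod_z(masses[0], lengths[0]),
                           rod_x(masses[1], lengths[1]),
                           rod_x(masses[2], lengths[2])]),
        ee_offset=np.array([lengths[2], 0.0, 0.0]),
        payload_mass=payload_kg,
        viscous=np.full(3, 5.0),
    )


def force_field(t: float, spec: ForceFieldSpec) -> np.ndarray:
    """External Cartesian force at time ``t``; zero vector when disabled."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if not spec.enabled:
        return np.zeros(3)
    amp = np.asarray(spec.amplitude, dtype=float)
    ph = np.asarray(spec.phases, dtype=float)
    return amp * np.cos(spec.omega * t + ph)


def inverse_dynamics(model: ArmModel, state: ArmState, ee_force: np.ndarray | None = None) -> np.ndarray:
    """Joint torques realizing ``state`` under gravity, payload and an
    optional external force (base frame) applied at the end effector."""
    state.validate()
    fext = _ZERO3 if ee_force is None else np.asarray(ee_force, dtype=float)
    axes, offs, coms, masses, inert, grav, ee, visc = model.composite_params()
    tau = _fast.rne(state.q, state.qd, state.qdd, axes, offs, coms, masses,
                    inert, grav, ee, fext)
    return tau + visc * state.qd


def mass_matrix(model: ArmModel, q: np.ndarray) -> np.ndarray:
    """Joint-space inertia matrix M(q) (symmetric positive definite)."""
    q = np.asarray(q, dtype=float)
    axes, offs, coms, masses, inert, _, _, _ = model.composite_params()
    M = _fast.mass_matrix(q, axes, offs, coms, masses, inert)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("mass matrix is singular or ill-conditioned")
    return M


def forward_dynamics(model: ArmModel, state: ArmState, tau: np.ndarray,
                     ee_force: np.ndarray | None = None) -> np.ndarray:
    """Joint accelerations solving M(q) qdd = tau - bias(q, qd, F_ext)."""
    state.validate()
    tau = np.asarray(tau, dtype=float)
    fext = _ZERO3 if ee_force is None else np.asarray(ee_force, dtype=float)
    axes, offs, coms, masses, inert, grav, ee, visc = model.composite_params()
    mass_matrix(model, state.q)  # conditioning check
    return _fast.forward_dynamics(state.q, state.qd, tau, axes, offs, coms,
                                  masses, inert, grav, ee, fext, visc)


def step(model: ArmModel, state: ArmState, tau_total: np.ndarray, t: float,
         dt: float, ff: ForceFieldSpec | None = None) -> ArmState:
    """Advance the plant one control step with fixed-step RK4.

    The commanded torque is saturated at the actuator limits before
    integration; the force field (if any) is evaluated at the RK4 sub-step
    times. Deterministic.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate()
    tau = np.clip(np.asarray(tau_total, dtype=float),
                  -model.torque_limit, model.torque_limit)
    ff = ff or ForceFieldSpec(enabled=False)
    axes, offs, coms, masses, inert, grav, ee, visc = model.composite_params()
    q, qd = _fast.rk4_step(
        state.q, state.qd, tau, t, dt, axes, offs, coms, masses, inert, grav,
        ee, visc, ff.enabled, np.asarray(ff.amplitude, dtype=float), ff.omega,
        np.asarray(ff.phases, dtype=float),
    )
    return ArmState(q=q, qd=qd)


def forward_kinematics(model: ArmModel, q: np.ndarray):
    """World positions of the joint origins, link COMs and the end effector."""
    q = np.asarray(q, dtype=float)
    axes, offs, coms, masses, inert, _, ee, _ = model.composite_params()
    R = np.eye(3)
    o = np.zeros(3)
    origins, com_pos = [], []
    for i in range(3):
        o = o + R @ offs[i]
        origins.append(o)
        c, s = np.cos(q[i]), np.sin(q[i])
        ax = axes[i]
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
        R = R @ (np.eye(3) + s * K + (1 - c) * (K @ K))
        com_pos.append(o + R @ coms[i])
    ee_pos = origins[2] + R @ ee
    return np.array(origins), np.array(com_pos), ee_pos


def total_energy(model: ArmModel, state: ArmState) -> float:
    """Kinetic plus gravitational potential energy (payload included)."""
    _, _, _, masses, _, grav, _, _ = model.composite_params()
    M = mass_matrix(model, state.q)
    kin = 0.5 * state.qd @ M @ state.qd
    _, com_pos, _ = forward_kinematics(model, state.q)
    pot = -sum(masses[i] * grav @ com_pos[i] for i in range(3))
    return float(kin + pot)
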