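import dataclasses

import numpy as np
import pytest

from cerebarm.arm import (ArmState, ForceFieldSpec, default_arm, force_field,
                          forward_dynamics, inverse_dynamics, mass_matrix,
                          step, total_energy)

from _oracles import lagrangian_torque_fn

TINY = 1e-12  # effectively massless distal links for short-chain fixtures


def _chain_arm(n_links, payload=0.0):
    """Default arm with links beyond ``n_links`` made dynamically negligible."""
    arm = default_arm(payload)
    masses = arm.masses.copy()
    inert = arm.inertias.copy()
    for i in range(n_links, 3):
        masses[i] = TINY
        inert[i] = TINY * np.eye(3)
    return dataclasses.replace(arm, masses=masses, inertias=inert,
                               viscous=np.zeros(3))


@pytest.fixture(scope="module", params=[1, 2, 3], ids=["1link", "2link", "3link"])
def chain(request):
    n = request.param
    arm = _chain_arm(n, payload=2.0 if n == 3 else 0.0)
    packed = arm.composite_params()
    axes, offs, coms, masses, inert, grav, ee, _ = packed
    oracle = lagrangian_torque_fn(axes, offs, coms, masses, inert, grav, ee)
    return n, arm, oracle


class TestInverseDynamics:
    def test_matches_lagrangian_oracle(self, chain, rng):
        """RNE torques equal the independent Euler-Lagrange derivation."""
        n, arm, oracle = chain
        for _ in range(100):
            q = rng.normal(size=3)
            qd = rng.normal(size=3)
            qdd = rng.normal(size=3)
            q[n:] = qd[n:] = qdd[n:] = 0.0
            f = rng.normal(size=3) * 50.0
            tau = inverse_dynamics(arm, ArmState(q, qd, qdd), f)
            ref = oracle(q, qd, qdd, f)
            scale = max(1.0, np.abs(ref[:n]).max())
            assert np.abs(tau[:n] - ref[:n]).max() / scale < 1e-8

    def test_static_horizontal_gravity_torque(self):
        """Closed-form statics: |tau_2| = g * sum(m_i * lever_i) at reach."""
        arm = default_arm(payload_kg=5.0)
        tau = inverse_dynamics(arm, ArmState(np.zeros(3), np.zeros(3), np.zeros(3)))
        L1, L2, L3 = arm.lengths
        expected = 9.81 * (arm.masses[1] * L2 / 2
                           + arm.masses[2] * (L2 + L3 / 2)
                           + 5.0 * (L2 + L3))
        assert abs(tau[1]) == pytest.approx(expected, rel=1e-12)
        assert tau[0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_gravity_zero_motion_zero_torque(self):
        arm = dataclasses.replace(default_arm(), gravity=np.zeros(3))
        tau = inverse_dynamics(arm, ArmState(np.ones(3), np.zeros(3), np.zeros(3)))
        assert np.abs(tau).max() < 1e-12

    def test_nonfinite_state_rejected(self, arm):
        with pytest.raises(ValueError):
            inverse_dynamics(arm, ArmState(np.array([np.nan, 0, 0]),
                                           np.zeros(3), np.zeros(3)))


class TestMassMatrix:
    def test_symmetric_positive_definite(self, arm, rng):
        for _ in range(20):
            M = mass_matrix(arm, rng.normal(size=3))
            assert np.abs(M - M.T).max() < 1e-10
            assert np.all(np.linalg.eigvalsh(M) > 0)

    def test_matches_unit_acceleration_columns(self, rng):
        """The composite-body recursion equals the defining construction:
        column k = inverse dynamics at qdd = e_k with gravity off, qd = 0."""
        arm = dataclasses.replace(default_arm(2.0), gravity=np.zeros(3))
        for _ in range(5):
            q = rng.normal(size=3)
            M = mass_matrix(arm, q)
            cols = np.empty((3, 3))
            for k in range(3):
                e = np.zeros(3)
                e[k] = 1.0
                cols[:, k] = inverse_dynamics(arm, ArmState(q, np.zeros(3), e))
            assert np.abs(M - cols).max() < 1e-10

    def test_payload_increases_inertia(self, rng):
        q = np.array([0.3, 0.4, -0.2])
        M0 = mass_matrix(default_arm(0.0), q)
        M10 = mass_matrix(default_arm(10.0), q)
        assert np.all(np.linalg.eigvalsh(M10 - M0) > -1e-12)


class TestForwardDynamics:
    def test_roundtrip_identity(self, arm, rng):
        for _ in range(20):
            q, qd, qdd = rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
            f = rng.normal(size=3) * 30.0
            tau = inverse_dynamics(arm, ArmState(q, qd, qdd), f)
            back = forward_dynamics(arm, ArmState(q, qd), tau, f)
            assert np.abs(back - qdd).max() < 1e-8

    def test_gravity_compensation_holds_still(self, arm):
        st = ArmState(np.array([0.2, 0.5, -0.3]), np.zeros(3), np.zeros(3))
        tau = inverse_dynamics(arm, st)
        assert np.abs(forward_dynamics(arm, st, tau)).max() < 1e-9

    def test_free_space_rest_stays_at_rest(self):
        arm = dataclasses.replace(default_arm(), gravity=np.zeros(3))
        qdd = forward_dynamics(arm, ArmState(np.ones(3), np.zeros(3)), np.zeros(3))
        assert np.abs(qdd).max() < 1e-12


class TestStep:
    def test_uniform_motion_advances_linearly(self):
        """With gravity off and the velocity-product torques cancelled, a
        coasting arm advances by qd*dt per control step."""
        arm = dataclasses.replace(default_arm(), gravity=np.zeros(3),
                                  viscous=np.zeros(3))
        qd = np.array([0.3, -0.2, 0.1])
        st0 = ArmState(np.zeros(3), qd)
        st1 = step(arm, st0, _coriolis_free_torque(arm, st0), 0.0, 0.002)
        assert st1.q == pytest.approx(qd * 0.002, rel=1e-6)

    def test_energy_conserved_in_free_swing(self):
        """Unforced, frictionless arm: RK4 at the 2 ms control step keeps the
        relative energy drift below 1e-6 over one 1 s trial, and the drift
        shrinks by far more than 2x when the step is halved (4th order)."""
        arm = dataclasses.replace(default_arm(2.0), viscous=np.zeros(3))

        def drift(dt, n):
            st = ArmState(np.array([0.3, 0.4, 0.2]), np.zeros(3))
            e0 = total_energy(arm, st)
            for k in range(n):
                st = step(arm, st, np.zeros(3), k * dt, dt)
            return abs(total_energy(arm, st) - e0) / abs(e0)

        d2 = drift(0.002, 500)
        assert d2 < 1e-6
        assert drift(0.001, 1000) < d2 / 2

    def test_torque_saturated_at_actuator_limit(self, arm):
        st0 = ArmState(np.zeros(3), np.zeros(3))
        huge = step(arm, st0, np.array([1e9, -1e9, 1e9]), 0.0, 0.002)
        lim = arm.torque_limit * np.array([1.0, -1.0, 1.0])
        clipped = step(arm, st0, lim, 0.0, 0.002)
        assert huge.q == pytest.approx(clipped.q)
        assert huge.qd == pytest.approx(clipped.qd)

    def test_payload_increases_static_holding_torque(self, rng):
        for _ in range(10):
            q = rng.uniform(-0.5, 0.5, size=3)
            st = ArmState(q, np.zeros(3), np.zeros(3))
            t0 = inverse_dynamics(default_arm(0.0), st)
            t2 = inverse_dynamics(default_arm(2.0), st)
            assert abs(t2[1]) > abs(t0[1])


def _coriolis_free_torque(arm, st):
    """Torque that exactly cancels velocity-product terms (zero gravity)."""
    return inverse_dynamics(arm, ArmState(st.q, st.qd, np.zeros(3)))


class TestForceField:
    def test_printed_values_at_t0(self):
        f = force_field(0.0, ForceFieldSpec(enabled=True))
        assert f == pytest.approx([100 * np.cos(np.pi / 4), 0.0,
                                   100 * np.cos(3 * np.pi / 4)], abs=1e-9)

    def test_amplitude_bound_and_period(self):
        spec = ForceFieldSpec(enabled=True)
        ts = np.linspace(0, 1, 2001)
        vals = np.array([force_field(t, spec) for t in ts])
        assert np.all(np.abs(vals) <= 100.0 + 1e-9)
        f0 = force_field(0.123, spec)
        assert force_field(0.123 + 0.1, spec) == pytest.approx(f0, abs=1e-9)

    def test_disabled_field_is_zero(self):
        assert np.all(force_field(0.5, ForceFieldSpec(enabled=False)) == 0.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            force_field(-0.1, ForceFieldSpec(enabled=True))
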