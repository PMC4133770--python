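# Methods

`cerebarm` simulates a rate-based cerebellar micro-circuit controlling a
3-link robot arm through a closed feedforward loop, and studies how four
distributed synaptic plasticity rules — in particular an adaptive connection
from the inferior olive (IO) to the deep cerebellar nuclei (DCN) — shape the
speed and stability of motor learning during payload manipulation.

## Network model

All neurons are analog rate units, normalized to [0, 1] for the cortical
layers. The granular layer is a state generator: the 1 s movement is cut
into 2 ms control steps, and each step activates exactly one of 500 one-hot
parallel-fiber (PF) lines, the same line at the same time on every trial.
Purkinje cells (PCs) — one pooled unit per muscle channel — read the active
PF through a learned weight table, clipped to [0, 1]:

    PC_i(t) = clip(w_pf[state(t), i], 0, 1)

Mossy fibers supply a constant baseline drive (rate 1). The DCN output per
muscle is

    DCN_i = max(0, mf * w_mf_i - PC_i * w_pc_i + IO_i * w_io_i)

floored at zero because a firing rate cannot be negative, and *not* capped
at 1: the DCN is the torque-driving output whose physical gain is set
outside the network (a cap is available via `NetworkConfig.dcn_cap`).

Muscles come in agonist/antagonist pairs, two per joint (six total). The net
corrective torque on joint j is `gain * (DCN_agonist_j - DCN_antagonist_j)`.

## Plasticity rules

Four sites adapt every 2 ms step, all built from the sharp saturating kernel
`1/(x+1)^a` with decay exponent a = 1000 (evaluated as `exp(-a*log1p(x))` in
log space; naive evaluation under/overflows):

| site   | rule (per step) | driven by |
|--------|-----------------|-----------|
| PF-PC  | `LTP/(IO+1)^a - LTD*IO`, active PF only | IO error signal |
| MF-DCN | `LTP/(PC+1)^a - LTD*PC` | PC rate |
| PC-DCN | `LTP*PC^a*(1 - 1/(DCN+1)^a) - LTD*(1-PC)` | PC and DCN rates |
| IO-DCN | `MTP*IO - MTD/(IO+1)^a` | IO error signal |

Weights are clipped to [0, w_max] (default 5, comfortably above the range
any site needs; PC rates saturate at 1 regardless).

The PF-PC site sees each granular state once per trial, so its increments
act on a per-trial scale; the DCN sites accumulate 500 increments per trial,
so their constants are ~3 orders of magnitude smaller for comparable
dynamics. The MTP/MTD pair ("modulating term") is deliberately enormous
compared to the LTP/LTD constants: it adapts the IO-DCN weight within tens
of control steps, and depresses it just as fast once the error vanishes —
what is quickly learnt is quickly forgotten.

The PC-DCN rule's potentiation gate is read as `PC^a` (companion to the
`(DCN+1)^a` term); the typographically possible `PC*a` reading is available
via `PlasticityParams.pc_dcn_linear_alpha`.

### Default constants

The source work defers its LTP/LTD values to earlier material, so the
defaults here were calibrated on the reference scenario (2 kg payload,
distributed plasticity, no IO-DCN) to the stated behavior — DCN-site weights
stabilizing over hundreds of trials:

* PF-PC: LTP 5e-4, LTD 5e-3 per visit. The LTD/LTP ratio (10) fixes the
  per-state equilibrium error at IO* ~ 0.0034 (solving `LTP/(x+1)^a =
  LTD*x`), deliberately *below* the IO-DCN potentiation/depression
  break-even IO ~ 0.0052 (mtp = mtd): once cortical learning has driven the
  error under that point, the IO-DCN weight experiences net depression and
  the connection disengages — this ordering is what makes the late-phase
  transfer of control structurally possible.
* MF-DCN: LTP 5e-7, LTD 5e-8 per step. LTP acts only where PCs are nearly
  silent, i.e. exactly at the states whose muscle calls for output, so the
  baseline tracks demand; the weak LTD leaks it back when demand disappears.
* PC-DCN: LTP 5e-7, LTD 5e-9 per step. Potentiates only where the PC
  saturates while its DCN target still fires, learning to cancel unused
  baseline.
* MTP/MTD: the dimensionless base value swept in the experiments
  (0.001 ... 1000) maps to per-step increments through a fixed unit of 0.1,
  chosen so that base 10 adapts the IO-DCN weight to its operating range
  within ~100 control steps (0.2 s), well inside the first trial.

### Initial state

Runs start from the *operating point* of a circuit already trained on the
bare (no-payload) arm: PCs mid-range (every PF-PC weight 0.5), MF-DCN drive
1.0, PC-DCN 2.0 — so the DCN output is exactly nulled with full
bidirectional headroom — and the IO-DCN weight at 0. Starting instead from
all-zero weights leaves the PC layer pinned at its floor, with no
state-specific pathway until the slow DCN sites bootstrap; the pre-trained
operating point is both the biologically sensible initial condition (the
paper's protocol perturbs a calibrated system with an unexpected mass) and
the one under which the reported phenomena emerge. `initial_weights="zeros"`
remains available.

## Plant

A generic rigid 3-link serial arm (base yaw about the vertical, shoulder and
elbow pitch about horizontal axes) stands in for the three active joints of
a light-weight manipulator: link lengths (0.31, 0.40, 0.39) m, masses
(5, 4, 3) kg, rod-like inertias, 5 N m s/rad viscous joint friction, 250 N m
actuator saturation per joint. At this scale the 2 kg and 10 kg point-mass
payloads (attached at the end effector, folded into the last link as an
exact composite rigid body) are a significant fraction of the arm's own
dynamics, and their gravitational and inertial torque deficits along the
benchmark are comparable — the regime the manipulation experiments depict.
All parameters are configuration data; any published arm can be dropped in.

Inverse dynamics use the recursive Newton-Euler algorithm (outward
velocity/acceleration recursion, inward force recursion; gravity via base
acceleration; external end-effector force as a wrench on the last link).
The joint-space inertia matrix is assembled by the composite-rigid-body
recursion and is verified in the tests against its defining construction
(unit-acceleration RNE columns) and, together with the full inverse
dynamics, against an independent symbolic Euler-Lagrange derivation.
Integration is fixed-step RK4 at the 2 ms control step, force field
evaluated at sub-step times; an unforced frictionless swing conserves
energy to better than 1e-6 per trial.

The hot loop (RNE, RK4, and the fused per-step trial kernel) is numba-jitted
with explicit scalar arithmetic; a pure-Python reference trial built from
the public modular operations is kept and the two paths are asserted
equivalent in the tests.

## Control loop

The benchmark is the eight-shape joint trajectory
`Q_n = A_n sin(-4 pi t^3 + 6 pi t^2 + C_n)` with `C_n = n pi/4`, duration
1 s; the phase advances by exactly 2 pi with zero endpoint rate, so trials
are independent repetitions from the same start pose. Default amplitudes
are 0.2 rad per joint: large enough that the movement is fast and the
payload's inertial torques matter, small enough that the required
corrective profile stays inside the normalized DCN range at the calibrated
output gain.

Per step: the crude inverse-dynamics model of the *nominal* arm (no payload,
no field) supplies the feedforward torque, sampled at the step midpoint
(zero-order-hold matching; the crude model then tracks the nominal plant to
~1e-5 rad); the cerebellar corrective torque is added; the sum is saturated
at the actuator limits and the plant integrated; the joint position error
against the desired pose is encoded into the IO rate
(`clip(|e|/e_sat, 0, 1)` on the agonist channel for positive error, the
antagonist for negative); the enabled rules update.

Two calibrations, both exposed in the configuration and computed by
documented procedures:

* `output_gain`: set so a full-scale DCN difference of 1 supplies the peak
  torque deficit of the heavy (10 kg) payload along the trajectory (~159 N m
  with the defaults) — the cerebellar range spans the worst-case correction.
* `e_sat`: the 95th percentile of the per-step absolute error in a single
  no-learning 2 kg trial (~0.84 rad), so the IO spans (0, 1] early in
  learning and sits near zero late.

### IO timing

One IO signal serves the DCN collateral drive and all learning rules. The
DCN equation is driven with the instantaneous IO rate (sensor latency 0 by
default, configurable). The teaching alignment is separate: the error
measured at step k credits the granular state active 25 steps (50 ms)
earlier — the climbing-fiber eligibility window, matched to the plant's
smeared position response to a torque change. Without this alignment the
per-state updates pair a state with an error its action could not have
produced, and the sign-alternating (inertial) components of the required
correction profile destabilize across trials.

## Metrics

* Per-trial MAE: mean over steps of |q_desired - q| per joint, averaged
  across joints.
* Samples to convergence: the final error average is the mean MAE over the
  last 10% of trials; the run converges at the first trial whose trailing
  10-trial moving average falls to 1.05x that value and stays there for 10
  trials. A run that ends no better than it began is flagged non-converged.
  Normalized convergence divides by the count of the no-IO-DCN reference
  (defined as 1).
* Windup: flagged when a trial trips the plant instability bounds
  (|error| > pi or |qd| > 100 rad/s), or when the MAE series sustains an
  oscillation — peak-to-peak amplitude above half the final error average,
  neither shrinking nor accompanied by decreasing window means over three
  consecutive 10-trial windows. The two-sided rule avoids flagging smooth
  descents while catching non-decaying oscillation.

## What the experiments show (and their limits)

With the defaults, the reference scenario (2 kg, distributed DCN plasticity,
no IO-DCN) stabilizes after roughly six hundred trials; the 10 kg payload
takes about 2.5x longer, since the required MF-DCN growth scales with the
deficit. Enabling the self-adaptive IO-DCN connection cuts the first-trial
error by ~5x and the samples-to-convergence by one to two orders of
magnitude; its share of the DCN drive starts near 70% and fades below 5% as
the cortical pathways take over. Payload switching (2 kg to 10 kg) re-
converges without weight reset. In the modulating-term sweep, convergence
speed improves steeply with the base value up to ~10 and saturates; beyond
that, accuracy degrades instead of improving.

Known limitations:

* The learning curves are not monotone: after converging, the slow
  interaction of PF-PC potentiation drift with the DCN gain sites produces a
  shallow re-equilibration (final hover around MAE 0.05 rad rather than the
  transient best of ~0.012). Quantities tied to "final error" therefore
  depend mildly on the evaluation horizon; the tests state theirs.
* With the instantaneous-IO drive, the top of the modulating-term sweep
  degrades accuracy but does not destabilize the plant: the 2 ms loop and
  the damped arm tolerate the relay-like adaptation. Adding a realistic
  proprioceptive latency (`sensor_delay_steps` ~ 25, i.e. 50 ms) reproduces
  the classic windup failure — over-correction faster than the delayed error
  can report, saturation, oscillatory divergence — which the test suite
  demonstrates; but the same latency also degrades the nominal adaptive
  scenarios, so it is not part of the default conditions.
* Exact published trial counts depend on learning constants the source work
  does not print; the package reproduces the phenomena and their scaling,
  not those figures digit for digit.
* The simulator is deterministic: no sensory or motor noise, identical
  trials apart from learning. Conclusions about robustness to noise are out
  of scope.
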