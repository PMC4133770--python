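"""Distributed synaptic plasticity rules.

Four sites adapt:

* PF-PC (cortical): ``dw = LTP_max / (IO + 1)^alpha - LTD_max * IO`` applied
  to the currently active PF only. With alpha ~ 1000 the LTP term collapses
  as soon as the teaching signal IO departs from zero, so the rule potentiates
  at silent-error states and depresses in proportion to the error elsewhere.
* MF-DCN: same functional form driven by the PC rate (MF is always active as
  a baseline), which grows the DCN excitatory drive exactly where PCs are
  silent, i.e. where the cortex calls for output.
* PC-DCN: ``dw = LTP_max * PC^alpha * (1 - 1/(DCN + 1)^alpha)
  - LTD_max * (1 - PC)`` -- potentiates only when the PC saturates while its
  DCN target is still active, learning to cancel the baseline.
* IO-DCN (modulating term): ``dw = MTP_max * IO - MTD_max / (IO + 1)^alpha``.
  MTP/MTD are orders of magnitude larger than the LTP/LTD constants: the
  weight potentiates within a few control steps under high error and is
  depressed back as fast once the error vanishes -- what is quickly learnt is
  quickly forgotten.

All ``(x + 1)^alpha`` and ``x^alpha`` terms are evaluated in log space so
that alpha = 1000 underflows smoothly to zero instead of overflowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import NetworkSignals, WeightSet

__all__ = [
    "SiteRates",
    "PlasticityParams",
    "decay_pow",
    "pow_safe",
    "pf_pc_update",
    "mf_dcn_update",
    "pc_dcn_update",
    "io_dcn_update",
    "apply_updates",
]

#: Dimensionless MTP/MTD base value -> per-step weight increment. Chosen so
#: that a base value of 10 adapts the IO-DCN weight to its operating range
#: within ~100 control steps (0.2 s), i.e. well inside the first trial.
MT_UNIT = 1.0e-1


@dataclass
class SiteRates:
    """Maximum per-application LTP/LTD increments for one synaptic site."""

    ltp_max: float
    ltd_max: float

    def __post_init__(self) -> None:
        if self.ltp_max < 0 or self.ltd_max < 0:
            raise ValueError("LTP/LTD maxima must be non-negative")


@dataclass
class PlasticityParams:
    """Constants of the four learning rules.

    The PF-PC site sees each granular state once per trial, so its rates act
    on a per-trial time scale; the DCN sites update every 2 ms step, so their
    rates are ~3 orders of magnitude smaller for comparable trial-scale
    dynamics. ``mt_base`` is the dimensionless modulating-term factor swept in
    the experiments (0.001 ... 1000); the per-step MTP/MTD increments are
    ``mt_base * MT_UNIT`` unless overridden explicitly.
    """

    pf_pc: SiteRates = field(default_factory=lambda: SiteRates(5.0e-4, 5.0e-3))
    mf_dcn: SiteRates = field(default_factory=lambda: SiteRates(5.0e-7, 5.0e-8))
    pc_dcn: SiteRates = field(default_factory=lambda: SiteRates(5.0e-7, 5.0e-9))
    mt_base: float = 10.0
    mtp_max: float | None = None  # per-step override; default mt_base * MT_UNIT
    mtd_max: float | None = None
    alpha: float = 1000.0
    w_max: float = 5.0
    enabled_pf_pc: bool = True
    enabled_mf_dcn: bool = True
    enabled_pc_dcn: bool = True
    enabled_io_dcn: bool = False
    pc_dcn_linear_alpha: bool = False  # alternative PC*alpha reading of the rule

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.mt_base < 0:
            raise ValueError("mt_base must be non-negative")

    @property
    def mtp(self) -> float:
        return self.mt_base * MT_UNIT if self.mtp_max is None else self.mtp_max

    @property
    def mtd(self) -> float:
        return self.mt_base * MT_UNIT if self.mtd_max is None else self.mtd_max

    def with_sites(self, pf_pc=None, mf_dcn=None, pc_dcn=None, io_dcn=None) -> "PlasticityParams":
        """Copy with some per-site enable flags replaced."""
        kw = {}
        if pf_pc is not None:
            kw["enabled_pf_pc"] = pf_pc
        if mf_dcn is not None:
            kw["enabled_mf_dcn"] = mf_dcn
        if pc_dcn is not None:
            kw["enabled_pc_dcn"] = pc_dcn
        if io_dcn is not None:
            kw["enabled_io_dcn"] = io_dcn
        return replace(self, **kw)


def decay_pow(x, alpha: float):
    """``1 / (x + 1)^alpha`` evaluated as ``exp(-alpha*log1p(x))``.

    Exact 1.0 at x = 0; underflows smoothly to 0 for x of order 1 when
    alpha ~ 1000. Accepts scalars or arrays; x must be non-negative.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("decay_pow requires x >= 0")
    out = np.exp(-alpha * np.log1p(x))
    return float(out) if out.ndim == 0 else out


def pow_safe(x, alpha: float):
    """``x^alpha`` for x in [0, 1] computed in log space (0^alpha = 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("pow_safe requires x >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(x > 0.0, np.exp(alpha * np.log(np.maximum(x, 1e-300))), 0.0)
    return float(out) if out.ndim == 0 else out


def pf_pc_update(io_i, active: bool, ltp_max: float, ltd_max: float, alpha: float = 1000.0):
    """PF-PC weight change for one muscle; zero when the PF is not active."""
    if not active:
        return 0.0 if np.ndim(io_i) == 0 else np.zeros(np.shape(io_i))
    return ltp_max * decay_pow(io_i, alpha) - ltd_max * np.asarray(io_i, dtype=float)


def mf_dcn_update(pc_i, ltp_max: float, ltd_max: float, alpha: float = 1000.0):
    """MF-DCN weight change, applied every step (MF baseline always active)."""
    return ltp_max * decay_pow(pc_i, alpha) - ltd_max * np.asarray(pc_i, dtype=float)


def pc_dcn_update(
    pc_i,
    dcn_i,
    ltp_max: float,
    ltd_max: float,
    alpha: float = 1000.0,
    linear_alpha: bool = False,
):
    """PC-DCN weight change.

    The potentiating factor is PC^alpha by default (companion to the
    (DCN+1)^alpha term); ``linear_alpha`` switches to the PC*alpha reading.
    """
    pc_i = np.asarray(pc_i, dtype=float)
    gate = pc_i * alpha if linear_alpha else pow_safe(pc_i, alpha)
    out = ltp_max * gate * (1.0 - decay_pow(dcn_i, alpha)) - ltd_max * (1.0 - pc_i)
    return float(out) if np.ndim(out) == 0 else out


def io_dcn_update(io_i, mtp_max: float, mtd_max: float, alpha: float = 1000.0):
    """IO-DCN (modulating term) weight change.

    High error: the potentiation term dominates and the weight adapts within
    a few steps. Near-zero error: the depression term dominates and the
    weight is pulled back just as fast.
    """
    out = mtp_max * np.asarray(io_i, dtype=float) - mtd_max * decay_pow(io_i, alpha)
    return float(out) if np.ndim(out) == 0 else out


def apply_updates(weights: WeightSet, signals: NetworkSignals, p: PlasticityParams) -> WeightSet:
    """Apply one control step of every enabled rule; pure function.

    The PF-PC update touches only the active state's row; the three DCN
    afferent sites update for every muscle. All weights are clipped to
    [0, w_max] afterwards.
    """
    out = weights.copy()
    a = p.alpha
    if p.enabled_pf_pc:
        dw = pf_pc_update(signals.io, True, p.pf_pc.ltp_max, p.pf_pc.ltd_max, a)
        out.w_pf_pc[signals.state_index] += dw
        np.clip(out.w_pf_pc[signals.state_index], 0.0, p.w_max,
                out=out.w_pf_pc[signals.state_index])
    if p.enabled_mf_dcn:
        out.w_mf_dcn += mf_dcn_update(signals.pc, p.mf_dcn.ltp_max, p.mf_dcn.ltd_max, a)
        np.clip(out.w_mf_dcn, 0.0, p.w_max, out=out.w_mf_dcn)
    if p.enabled_pc_dcn:
        out.w_pc_dcn += pc_dcn_update(
            signals.pc, signals.dcn, p.pc_dcn.ltp_max, p.pc_dcn.ltd_max, a,
            linear_alpha=p.pc_dcn_linear_alpha,
        )
        np.clip(out.w_pc_dcn, 0.0, p.w_max, out=out.w_pc_dcn)
    if p.enabled_io_dcn:
        out.w_io_dcn += io_dcn_update(signals.io, p.mtp, p.mtd, a)
        np.clip(out.w_io_dcn, 0.0, p.w_max, out=out.w_io_dcn)
    return out
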