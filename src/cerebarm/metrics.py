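"""Movement-accuracy and learning-speed metrics.

The accuracy measure is the mean absolute error (MAE) between desired and
actual joint angles over a trial, per joint and averaged across joints. The
learning-speed measure is the number of movement repetitions needed to reach
the final error average; it is reported normalized so that the configuration
without the IO-DCN corrective action — the slowest converging one — scores
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LearningCurve",
    "trial_mae",
    "convergence_samples",
    "normalized_convergence",
    "detect_windup",
]


@dataclass
class LearningCurve:
    """Per-trial MAE series of one learning run."""

    mae: np.ndarray                      # (n_trials,) rad
    mae_per_joint: np.ndarray | None = None
    unstable: np.ndarray | None = None   # (n_trials,) bool

    def __post_init__(self) -> None:
        self.mae = np.asarray(self.mae, dtype=float)
        if self.mae.ndim != 1 or self.mae.size == 0:
            raise ValueError("mae must be a non-empty 1-D series")
        if np.any(self.mae < 0):
            raise ValueError("MAE values cannot be negative")
        if self.unstable is None:
            self.unstable = np.zeros(self.mae.shape, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.mae.size


def trial_mae(log) -> tuple[np.ndarray, float]:
    """Per-joint and joint-averaged MAE of one trial log.

    Accepts any object with an ``err`` array of shape (n_steps, n_joints).
    """
    err = np.asarray(log.err, dtype=float)
    if err.size == 0:
        raise ValueError("empty trial log")
    per_joint = np.mean(np.abs(err), axis=0)
    return per_joint, float(np.mean(per_joint))


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving average (window shrinks at the start of the series)."""
    if window <= 1:
        return x.astype(float)
    c = np.cumsum(np.insert(x.astype(float), 0, 0.0))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - window + 1, 0)
    return (c[idx + 1] - c[lo]) / (idx - lo + 1)


def convergence_samples(curve: LearningCurve, tail_frac: float = 0.1,
                        tol_factor: float = 1.05,
                        smooth_window: int = 10) -> tuple[int, bool]:
    """Trials needed to reach the final error average.

    The final error average is the mean MAE over the last ``tail_frac`` of
    trials; the run has converged at the first trial whose smoothed MAE
    falls to ``tol_factor`` times that average and stays there for
    ``smooth_window`` consecutive trials. Returns (1-based trial index,
    converged flag); a curve that never meets the criterion — including one
    that ends no better than it began, where "reaching the final error
    average" is vacuous — returns (n_trials, False).
    """
    n = curve.n_trials
    if n < int(np.ceil(2.0 / tail_frac)):
        raise ValueError("curve too short for the requested tail fraction")
    tail = max(1, int(round(tail_frac * n)))
    final_avg = float(np.mean(curve.mae[-tail:]))
    if final_avg > curve.mae[0]:
        return n, False
    thresh = tol_factor * final_avg
    sm = _smooth(curve.mae, smooth_window)
    below = sm <= thresh
    span = min(smooth_window, n)
    for t in range(n):
        stop = min(t + span, n)
        if np.all(below[t:stop]):
            return t + 1, True
    return n, False


def normalized_convergence(speeds: dict, reference: str) -> dict:
    """Convergence counts normalized by the no-IO-DCN reference count.

    The reference configuration (learning without the IO-DCN corrective
    action, the slowest scenario) maps to exactly 1.0.
    """
    if reference not in speeds:
        raise KeyError(f"reference configuration {reference!r} missing")
    ref = float(speeds[reference])
    if ref <= 0:
        raise ValueError("reference convergence count must be positive")
    return {k: float(v) / ref for k, v in speeds.items()}


def detect_windup(curve: LearningCurve, weight_series: np.ndarray | None = None,
                  window: int = 10, shrink_factor: float = 0.95,
                  amp_floor_factor: float = 0.5) -> tuple[bool, int | None]:
    """Flag the windup failure mode; returns (flag, 1-based onset trial).

    Windup is flagged when (a) any trial tripped the plant instability
    bound, or (b) the MAE series sustains an oscillation: across three
    consecutive windows the peak-to-peak amplitude neither shrinks nor
    falls below ``amp_floor_factor`` times the final error average, while
    the window means do not decrease (so a smooth descent or a converged
    curve with small residual jitter is not a windup, but a large
    non-decaying oscillation is).
    """
    if np.any(curve.unstable):
        return True, int(np.argmax(curve.unstable)) + 1

    mae = curve.mae
    n = mae.size
    if n < 3 * window:
        return False, None
    n_win = n // window
    p2p = np.empty(n_win)
    means = np.empty(n_win)
    for w in range(n_win):
        seg = mae[w * window:(w + 1) * window]
        p2p[w] = seg.max() - seg.min()
        means[w] = seg.mean()
    tail = max(1, n // 10)
    floor = amp_floor_factor * float(np.mean(mae[-tail:]))
    for w in range(n_win - 2):
        ok = (p2p[w] > floor and p2p[w + 1] > floor and p2p[w + 2] > floor
              and p2p[w + 1] >= shrink_factor * p2p[w]
              and p2p[w + 2] >= shrink_factor * p2p[w + 1]
              and means[w + 1] >= shrink_factor * means[w]
              and means[w + 2] >= shrink_factor * means[w + 1])
        if ok:
            return True, w * window + 1
    return False, None
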