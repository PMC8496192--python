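"""Gait-phase reconstruction from force-plate or trunk-accelerometer traces.

One full gait cycle (lift -> strike -> next lift of the same foot) is mapped
onto ``[-pi, pi)``: the heel strike (foot loading onset) carries phase 0 and
the foot lift carries phase ``-pi`` when it opens a cycle and ``+pi`` when it
closes it, so phase increases strictly within a cycle.  Between anchors the
phase is linearly interpolated, i.e. phase is proportional to elapsed time
within each half-cycle.

Force-based reconstruction uses the zero crossings of the 0.5-5 Hz bandpassed
force trace (rising crossing = strike, falling crossing = lift).
Accelerometer-based reconstruction has a single anchor per cycle (the x-axis
acceleration minimum with rising y-axis acceleration) and no observable
strike, which is flagged in the result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "PhaseSeries",
    "GaitCycleTable",
    "RegularitySplit",
    "phase_from_force",
    "phase_from_accel",
    "cycle_variability",
    "split_regularity",
    "wrap_phase",
    "circular_rms_error",
]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into ``[-pi, pi)``."""
    return np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi


def circular_rms_error(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square of the wrapped angular difference between two phase series."""
    d = wrap_phase(np.asarray(a) - np.asarray(b))
    return float(np.sqrt(np.mean(d**2)))


@dataclass
class PhaseSeries:
    """Per-sample gait phase in ``[-pi, pi)`` with a validity mask.

    ``valid`` is False outside detected (or generated) complete cycles.
    ``strike_anchored`` records whether phase 0 corresponds to an observed
    heel strike (force-based) or only to the midpoint between lift anchors
    (accelerometer-based, where the strike is not observable).
    """

    phase: np.ndarray
    valid: np.ndarray
    fs: float
    strike_anchored: bool = True

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.phase.shape != self.valid.shape:
            raise ValueError("phase and valid must have the same shape")
        p = self.phase[self.valid]
        if p.size and (p.min() < -np.pi or p.max() >= np.pi):
            raise ValueError("valid phase samples must lie in [-pi, pi)")

    def decimate(self, factor: int) -> "PhaseSeries":
        """Subsample the series (keeps every ``factor``-th sample)."""
        return PhaseSeries(
            self.phase[::factor],
            self.valid[::factor],
            self.fs / factor,
            self.strike_anchored,
        )


@dataclass
class GaitCycleTable:
    """One row per complete gait cycle.

    ``lift_sample`` / ``strike_sample`` / ``next_lift_sample`` are the anchor
    sample indices (strike is NaN when reconstructed from accelerometers);
    ``duration_s`` is lift-to-next-lift and ``lift_duration_s`` the swing
    period lift-to-strike (the period the foot is off the plate).
    """

    lift_sample: np.ndarray
    strike_sample: np.ndarray
    next_lift_sample: np.ndarray
    duration_s: np.ndarray
    lift_duration_s: np.ndarray
    fs: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("lift_sample", "strike_sample", "next_lift_sample",
                     "duration_s", "lift_duration_s"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.lift_sample) == len(self.strike_sample)
                == len(self.next_lift_sample) == len(self.duration_s)
                == len(self.lift_duration_s)):
            raise ValueError("cycle table columns must have equal length")
        if np.any(self.duration_s <= 0) or np.any(self.lift_duration_s <= 0):
            raise ValueError("cycle durations must be positive")
        if np.any(self.next_lift_sample <= self.lift_sample):
            raise ValueError("cycle anchors must be ordered lift < next_lift")

    def __len__(self) -> int:
        return len(self.lift_sample)

    @property
    def n_cycles(self) -> int:
        return len(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lift_sample": self.lift_sample,
                "strike_sample": self.strike_sample,
                "next_lift_sample": self.next_lift_sample,
                "duration_s": self.duration_s,
                "lift_duration_s": self.lift_duration_s,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RegularitySplit:
    """25%/25% split of cycles by absolute deviation from the mean duration."""

    deviation_s: np.ndarray
    label: np.ndarray  # 'regular' | 'less_regular' | 'unlabeled'
    fraction: float = 0.25

    regular_idx: np.ndarray = field(default=None)
    less_regular_idx: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# zero-crossing machinery

def _zero_crossings(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sample zero-crossing positions and directions (+1 rising, -1 falling).

    Crossing position is linearly interpolated between the two straddling
    samples; samples exactly at zero count with the sign of the following
    excursion.
    """
    s = np.sign(x)
    # propagate the previous sign through exact zeros so each sign change
    # yields exactly one crossing
    nz = s != 0
    if not nz.any():
        return np.array([]), np.array([])
    idx = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    s_ff = s[idx]
    change = np.where(np.diff(s_ff) != 0)[0]
    pos = []
    direction = []
    for i in change:
        x0, x1 = x[i], x[i + 1]
        frac = 0.0 if x1 == x0 else x0 / (x0 - x1)
        pos.append(i + frac)
        direction.append(1.0 if x1 > x0 else -1.0)
    return np.asarray(pos), np.asarray(direction)


def _debounce(pos: np.ndarray, direction: np.ndarray, min_gap: float):
    """Drop crossings closer than ``min_gap`` samples to the last kept one,
    then enforce rising/falling alternation (first of a same-type run wins)."""
    keep_pos, keep_dir = [], []
    for p, d in zip(pos, direction):
        if keep_pos and p - keep_pos[-1] < min_gap:
            continue
        if keep_dir and d == keep_dir[-1]:
            continue
        keep_pos.append(p)
        keep_dir.append(d)
    return np.asarray(keep_pos), np.asarray(keep_dir)


def _phase_from_cycles(n: int, cycle_anchors: list, fs: float,
                       strike_anchored: bool) -> PhaseSeries:
    """Piecewise-linear phase per cycle.

    ``cycle_anchors`` holds, per cycle, a list of (position, phase) pairs
    covering [-pi .. pi]; samples between a cycle's first and last anchor are
    interpolated and marked valid (exclusive of the closing anchor, which
    opens the next cycle at -pi).
    """
    phase = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for pairs in cycle_anchors:
        pos = np.array([p for p, _ in pairs])
        ph = np.array([q for _, q in pairs])
        lo = int(np.ceil(pos[0]))
        hi = min(n, int(np.ceil(pos[-1])))
        if hi <= lo:
            continue
        t = np.arange(lo, hi, dtype=float)
        phase[lo:hi] = wrap_phase(np.interp(t, pos, ph))
        valid[lo:hi] = True
    return PhaseSeries(phase, valid, fs, strike_anchored)


def phase_from_force(force: np.ndarray, fs: float, debounce_s: float = 0.25
                     ) -> tuple[PhaseSeries, GaitCycleTable]:
    """Reconstruct gait phase from a bandpassed (0.5-5 Hz) force trace.

    Rising zero crossings are heel strikes (phase 0), falling crossings are
    foot lifts (phase ``-pi`` opening a cycle, ``+pi`` closing it); all other
    samples are linearly interpolated between their surrounding anchors.

    Returns the per-sample :class:`PhaseSeries` and the per-cycle
    :class:`GaitCycleTable`.
    """
    force = np.asarray(force, dtype=float)
    pos, direction = _zero_crossings(force)
    if pos.size == 0:
        raise ValueError("no gait cycles detected: force trace has no zero crossings")
    pos, direction = _debounce(pos, direction, debounce_s * fs)

    # cycles: falling (lift) -> rising (strike) -> falling (next lift)
    falls = np.where(direction < 0)[0]
    cycles = []
    for j, k in zip(falls[:-1], falls[1:]):
        if k == j + 2 and direction[j + 1] > 0:
            cycles.append((pos[j], pos[j + 1], pos[k]))
    if not cycles:
        raise ValueError("no gait cycles detected: need lift-strike-lift sequences")

    lifts = np.array([c[0] for c in cycles])
    strikes = np.array([c[1] for c in cycles])
    next_lifts = np.array([c[2] for c in cycles])

    cycle_anchors = [
        [(a, -np.pi), (b, 0.0), (c, np.pi)] for a, b, c in cycles
    ]
    series = _phase_from_cycles(len(force), cycle_anchors, fs, True)

    table = GaitCycleTable(
        lift_sample=np.round(lifts),
        strike_sample=np.round(strikes),
        next_lift_sample=np.round(next_lifts),
        duration_s=(next_lifts - lifts) / fs,
        lift_duration_s=(strikes - lifts) / fs,
        fs=fs,
    )
    return series, table


def phase_from_accel(acc_x: np.ndarray, acc_y: np.ndarray, fs: float,
                     min_separation_s: float = 0.5
                     ) -> tuple[PhaseSeries, GaitCycleTable]:
    """Reconstruct gait phase from bandpassed trunk-accelerometer traces.

    Anchors (phase ``-pi``/``pi``) are the local minima of the x-axis
    acceleration where the y-axis acceleration is increasing; phase runs
    linearly from ``-pi`` to ``pi`` between consecutive anchors.  There is no
    phase-0 anchor — heel strike is not observable from the trunk — so the
    returned series carries ``strike_anchored=False`` and the cycle table's
    ``strike_sample`` is NaN (the nominal strike is the inter-anchor
    midpoint, used for ``lift_duration_s``).
    """
    acc_x = np.asarray(acc_x, dtype=float)
    acc_y = np.asarray(acc_y, dtype=float)
    if acc_x.shape != acc_y.shape:
        raise ValueError("acc_x and acc_y must have the same length")
    minima, _ = find_peaks(-acc_x, distance=max(1, int(min_separation_s * fs)))
    dy = np.gradient(acc_y)
    anchors = minima[dy[minima] > 0]
    if anchors.size < 2:
        raise ValueError(
            f"need at least 2 accelerometer anchors, found {anchors.size}"
        )
    anchors = anchors.astype(float)
    cycle_anchors = [
        [(a, -np.pi), (c, np.pi)] for a, c in zip(anchors[:-1], anchors[1:])
    ]
    series = _phase_from_cycles(len(acc_x), cycle_anchors, fs, False)

    lifts = anchors[:-1]
    next_lifts = anchors[1:]
    mid = (lifts + next_lifts) / 2.0
    table = GaitCycleTable(
        lift_sample=np.round(lifts),
        strike_sample=np.full(len(lifts), np.nan),
        next_lift_sample=np.round(next_lifts),
        duration_s=(next_lifts - lifts) / fs,
        lift_duration_s=(mid - lifts) / fs,
        fs=fs,
    )
    return series, table


def cycle_variability(table: GaitCycleTable) -> float:
    """SD (ddof=1) of the per-cycle swing duration (foot-lifted period), seconds."""
    if len(table) < 2:
        raise ValueError("need at least 2 cycles to estimate variability")
    return float(np.std(table.lift_duration_s, ddof=1))


def split_regularity(table: GaitCycleTable, fraction: float = 0.25
                     ) -> RegularitySplit:
    """Label the ``fraction`` most/least regular cycles.

    Regularity of a cycle is the absolute deviation of its duration from the
    mean duration over all cycles; the ``fraction`` (floor-rounded count)
    smallest deviations are labeled ``regular``, the same count of largest
    deviations ``less_regular``.  Ties are broken deterministically by cycle
    order (earlier cycles sort first).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    n = len(table)
    if n < 8:
        raise ValueError(f"need at least 8 cycles to split, got {n}")
    dev = np.abs(table.duration_s - table.duration_s.mean())
    n_lab = int(np.floor(n * fraction))
    order = np.argsort(dev, kind="stable")
    regular = order[:n_lab]
    less_regular = order[n - n_lab:]
    label = np.full(n, "unlabeled", dtype=object)
    label[regular] = "regular"
    label[less_regular] = "less_regular"
    return RegularitySplit(
        deviation_s=dev,
        label=label,
        fraction=fraction,
        regular_idx=np.sort(regular),
        less_regular_idx=np.sort(less_regular),
    )
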