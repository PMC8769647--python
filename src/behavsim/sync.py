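"""Sync-pulse trains and clock alignment between acquisition systems.

A pulse train with *random* inter-pulse intervals is recorded by every system
(behaviour box, camera, physiology rig) in its own time frame.  Because the
interval sequence is effectively a fingerprint, the correspondence between
the two recorded sequences is unique even when one system missed the start of
the session, and a confident match certifies that two files belong to the
same recording.

Matching slides one interval sequence along the other and scores the number
of agreeing intervals (after snapping the median interval ratio to the
nearest power of ten, so ms vs s files still match).  The best lag must beat the runner-up by a margin, otherwise a
:class:`MatchError` is raised rather than returning a guess.  The fitted time
conversion is an affine map ``t_B = a * t_A + b`` (least squares over the
matched pulses); a piecewise-linear variant interpolating through matched
pulses is available for non-constant drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np


class MatchError(ValueError):
    """No unique correspondence between the two pulse sequences."""


@dataclass(frozen=True)
class PulseTrainSpec:
    """Uniform random-interval pulse train: gaps i.i.d. in
    [min_interval, max_interval] ms; first pulse at a random offset in
    [0, max_interval)."""

    min_interval: float = 500.0
    max_interval: float = 1500.0
    duration_ms: Optional[float] = None
    n_pulses: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_interval < self.max_interval):
            raise ValueError("need 0 < min_interval < max_interval "
                             "(equal intervals would not identify pulses uniquely)")
        if (self.duration_ms is None) == (self.n_pulses is None):
            raise ValueError("specify exactly one of duration_ms or n_pulses")


def generate_sync_train(spec: PulseTrainSpec) -> np.ndarray:
    """Pulse times (ms) for ``spec``; reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    start = rng.uniform(0.0, spec.max_interval)
    if spec.n_pulses is not None:
        gaps = rng.uniform(spec.min_interval, spec.max_interval, size=spec.n_pulses - 1)
        return start + np.concatenate(([0.0], np.cumsum(gaps)))
    times = [start]
    while times[-1] <= spec.duration_ms:
        times.append(times[-1] + rng.uniform(spec.min_interval, spec.max_interval))
    return np.array(times[:-1]) if times[-1] > spec.duration_ms else np.array(times)


def match_pulse_trains(times_a: Sequence[float], times_b: Sequence[float],
                       tol: float = 2.0, uniqueness_margin: int = 3
                       ) -> List[Tuple[int, int]]:
    """Match pulse indices between two recordings of the same train.

    Parameters
    ----------
    times_a, times_b:
        Sorted pulse times, each length >= 3, in each system's own units.
    tol:
        Interval agreement tolerance in the units of ``times_b`` (after
        rescaling ``times_a`` intervals by the median interval ratio).
    uniqueness_margin:
        The best lag's score must exceed the runner-up's by at least this
        many agreeing intervals.

    Returns
    -------
    list of (i, j) index pairs, strictly increasing in both coordinates.

    Raises
    ------
    MatchError
        If no lag wins by the required margin (unrelated trains, or trains
        too short to identify).
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    for name, arr in (("A", a), ("B", b)):
        if arr.size < 3:
            raise ValueError(f"train {name} has fewer than 3 pulses")
        if np.any(np.diff(arr) <= 0):
            raise ValueError(f"train {name} is not strictly sorted")
    da, db = np.diff(a), np.diff(b)
    # Unit conversion A -> B: snap the median interval ratio to the nearest
    # power of ten (ms vs s files); residual drift is absorbed by `tol`.
    import math

    scale = 10.0 ** round(math.log10(np.median(db) / np.median(da)))
    das = da * scale

    # score every lag: alignment pairs interval das[i] with db[i + lag]
    lags = range(-(len(das) - 1), len(db))
    scores = np.empty(len(das) + len(db) - 1, dtype=int)
    for idx, lag in enumerate(lags):
        lo = max(0, -lag)
        hi = min(len(das), len(db) - lag)
        if hi <= lo:
            scores[idx] = 0
            continue
        scores[idx] = int(np.sum(np.abs(das[lo:hi] - db[lo + lag:hi + lag]) < tol))
    order = np.argsort(scores)
    best_idx = int(order[-1])
    best, runner_up = int(scores[best_idx]), int(scores[order[-2]]) if scores.size > 1 else 0
    if best < 2 or best - runner_up < uniqueness_margin:
        raise MatchError(
            f"no unique match between pulse trains (best score {best}, "
            f"runner-up {runner_up}, margin required {uniqueness_margin})")
    lag = best_idx - (len(das) - 1)
    lo = max(0, -lag)
    hi = min(len(a), len(b) - lag)
    return [(i, i + lag) for i in range(lo, hi)]


@dataclass
class AlignmentModel:
    """Fitted time conversion ``t_B = slope * t_A + intercept``."""

    pairs: List[Tuple[int, int]]
    slope: float
    intercept: float
    residual_std: float
    range_a: Tuple[float, float]
    method: str = "linear"
    _knots_a: Optional[np.ndarray] = field(default=None, repr=False)
    _knots_b: Optional[np.ndarray] = field(default=None, repr=False)

    def convert(self, t, direction: str = "a_to_b"):
        """Elementwise conversion (``direction`` 'a_to_b' or 'b_to_a')."""
        t = np.asarray(t, dtype=float)
        if direction == "a_to_b":
            if self.method == "piecewise":
                out = np.interp(t, self._knots_a, self._knots_b)
                lo, hi = self._knots_a[0], self._knots_a[-1]
                out = np.where(t < lo, self._knots_b[0] + (t - lo) * self.slope, out)
                out = np.where(t > hi, self._knots_b[-1] + (t - hi) * self.slope, out)
                return out
            return self.slope * t + self.intercept
        if direction == "b_to_a":
            if self.method == "piecewise":
                out = np.interp(t, self._knots_b, self._knots_a)
                lo, hi = self._knots_b[0], self._knots_b[-1]
                out = np.where(t < lo, self._knots_a[0] + (t - lo) / self.slope, out)
                out = np.where(t > hi, self._knots_a[-1] + (t - hi) / self.slope, out)
                return out
            return (t - self.intercept) / self.slope
        raise ValueError(f"unknown direction {direction!r}")

    def extrapolates(self, t, direction: str = "a_to_b"):
        """Boolean mask: True where ``t`` lies outside the matched range."""
        t = np.asarray(t, dtype=float)
        if direction == "a_to_b":
            lo, hi = self.range_a
        else:
            lo, hi = self.convert(np.array(self.range_a))
        return (t < lo) | (t > hi)


def fit_time_conversion(pairs: Sequence[Tuple[int, int]],
                        times_a: Sequence[float], times_b: Sequence[float],
                        method: str = "linear") -> AlignmentModel:
    """Least-squares affine fit of B times on A times over matched pulses."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs to fit a time conversion")
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    x, y = a[ia], b[ib]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    model = AlignmentModel(
        pairs=list(pairs),
        slope=float(slope),
        intercept=float(intercept),
        residual_std=float(np.std(resid)),
        range_a=(float(x.min()), float(x.max())),
        method=method,
    )
    if method == "piecewise":
        model._knots_a = x
        model._knots_b = y
    elif method != "linear":
        raise ValueError(f"unknown method {method!r}")
    return model


def convert_times(model: AlignmentModel, times, direction: str = "a_to_b") -> np.ndarray:
    """Elementwise application of a fitted conversion (or its inverse)."""
    return model.convert(times, direction=direction)


def align_trains(times_a, times_b, tol: float = 2.0, method: str = "linear",
                 uniqueness_margin: int = 3) -> AlignmentModel:
    """Convenience: match then fit in one call."""
    pairs = match_pulse_trains(times_a, times_b, tol=tol,
                               uniqueness_margin=uniqueness_margin)
    return fit_time_conversion(pairs, times_a, times_b, method=method)
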