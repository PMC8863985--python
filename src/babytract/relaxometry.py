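"""Inversion-recovery T1 relaxometry.

The magnitude signal of an inversion-recovery acquisition at inversion time
t is |S(t)| = |a (1 - b exp(-t / T1))|: ``a`` is proportional to the initial
magnetisation of the voxel, ``b`` is the effective inversion coefficient
(b = 2 for perfect inversion), and T1 is the longitudinal relaxation time.
Because only magnitude images are available the model is fitted through the
absolute value, which introduces a non-differentiable null point at
t = T1 ln(b) and local minima; fits therefore use multi-start nonlinear
least squares over a T1 grid.  R1 = 1/T1 is reported in s^-1 (T1 in ms).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .io import BinaryMask, ScalarVolume

__all__ = ["TISchedule", "T1Fit", "default_schedule", "ir_signal_forward",
           "fit_ir_voxel", "fit_ir_volume"]

# Multi-start T1 grid (ms): the absolute-value model has a local minimum on
# the wrong side of the null point, so a single start is not reliable.
T1_STARTS_MS = (300.0, 800.0, 1500.0, 2500.0, 4000.0)
T1_BOUNDS_MS = (50.0, 10_000.0)
B_BOUNDS = (1.0, 2.2)


@dataclasses.dataclass(frozen=True)
class TISchedule:
    """Strictly increasing inversion times in ms."""

    times_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("schedule must be a 1D sequence of inversion times")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        object.__setattr__(self, "times_ms", tuple(float(x) for x in t))

    def __len__(self) -> int:
        return len(self.times_ms)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.times_ms, dtype=float)


def default_schedule(first_ms: float = 50.0, step_ms: float = 150.0,
                     n: int = 20) -> TISchedule:
    """The default acquisition: 20 TIs, first 50 ms, spacing 150 ms."""
    return TISchedule(tuple(first_ms + step_ms * np.arange(n)))


@dataclasses.dataclass
class T1Fit:
    a: float
    b: float
    t1_ms: float
    rss: float
    converged: bool
    reason: str = ""

    @property
    def r1_s(self) -> float:
        """R1 = 1/T1, in s^-1 (T1 carried in ms)."""
        return 1000.0 / self.t1_ms


def ir_signal_forward(a: float, b: float, t1_ms: float,
                      schedule: TISchedule) -> np.ndarray:
    """Magnitude IR signal |a (1 - b exp(-t/T1))| at each inversion time."""
    if t1_ms <= 0:
        raise ValueError("T1 must be positive")
    if a <= 0:
        raise ValueError("a must be positive")
    t = schedule.array
    return np.abs(a * (1.0 - b * np.exp(-t / t1_ms)))


def _residuals(params: np.ndarray, t: np.ndarray, signal: np.ndarray) -> np.ndarray:
    a, b, t1 = params
    return np.abs(a * (1.0 - b * np.exp(-t / t1))) - signal


def fit_ir_voxel(signal: np.ndarray, schedule: TISchedule,
                 max_rel_rss: float = 0.05, xtol: float = 1e-12,
                 max_nfev: int = 500) -> T1Fit:
    """Fit (a, b, T1) to one voxel's magnitude IR series.

    Minimises the residual sum of squares with multi-start Levenberg-style
    trust-region least squares (starts over T1_STARTS_MS, b = 2,
    a = max(signal)).  ``converged`` is False for non-identifiable input
    (constant/zero signal, or a schedule too short to constrain 3
    parameters) and when the best fit leaves more than ``max_rel_rss`` of
    the signal energy unexplained.
    """
    signal = np.asarray(signal, dtype=float)
    t = schedule.array
    if signal.shape != t.shape:
        raise ValueError("signal length must match the TI schedule")
    if np.any(signal < 0):
        raise ValueError("magnitude signal must be non-negative")
    energy = float(np.sum(signal**2))
    if energy == 0 or np.ptp(signal) == 0:
        return T1Fit(np.nan, np.nan, np.nan, np.nan, False,
                     "non-identifiable: constant or all-zero signal")
    if len(t) < 3:
        return T1Fit(np.nan, np.nan, np.nan, np.nan, False,
                     "non-identifiable: fewer inversion times than parameters")

    a0 = float(signal.max())
    best = None
    for t1_start in T1_STARTS_MS:
        try:
            res = least_squares(
                _residuals, x0=[a0, 2.0, t1_start], args=(t, signal),
                bounds=([1e-12, B_BOUNDS[0], T1_BOUNDS_MS[0]],
                        [np.inf, B_BOUNDS[1], T1_BOUNDS_MS[1]]),
                xtol=xtol, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
        if rss <= 1e-20 * max(energy, 1.0):
            break  # numerically exact; later starts cannot improve
    if best is None:  # pragma: no cover
        return T1Fit(np.nan, np.nan, np.nan, np.nan, False, "optimizer failed")
    rss, res = best
    a, b, t1 = (float(v) for v in res.x)
    ok = rss <= max_rel_rss * energy
    return T1Fit(a, b, t1, rss, ok, "" if ok else "poor fit: rss above tolerance")


def fit_ir_volume(series: np.ndarray, affine: np.ndarray, schedule: TISchedule,
                  mask: BinaryMask | None = None,
                  **fit_kwargs) -> tuple[ScalarVolume, ScalarVolume]:
    """Voxel-wise IR fit of a 4D magnitude series -> (R1 [s^-1], T1 [ms]).

    Voxels outside ``mask`` or with non-converged fits are invalid in both
    outputs.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4D (x, y, z, TI)")
    if series.shape[3] != len(schedule):
        raise ValueError(
            f"series has {series.shape[3]} volumes but schedule has {len(schedule)}"
        )
    shape = series.shape[:3]
    if mask is not None and mask.grid.shape != shape:
        raise ValueError("mask shape does not match series")
    sel = mask.grid if mask is not None else np.ones(shape, dtype=bool)

    t1 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for ijk in np.argwhere(sel):
        fit = fit_ir_voxel(series[tuple(ijk)], schedule, **fit_kwargs)
        if fit.converged:
            t1[tuple(ijk)] = fit.t1_ms
            valid[tuple(ijk)] = True
    r1 = np.where(valid, 1000.0 / t1, np.nan)
    return (ScalarVolume(r1, affine, units="s^-1", valid=valid),
            ScalarVolume(t1, affine, units="ms", valid=valid))
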