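"""Arc-length utilities shared by segmentation and profiling."""

from __future__ import annotations

import numpy as np

__all__ = ["arc_lengths", "densify", "resample_to_nodes", "total_length"]


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex of a polyline (starts at 0)."""
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def total_length(points: np.ndarray) -> float:
    return float(arc_lengths(points)[-1])


def resample_to_nodes(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` equidistant points along its arc length.

    Points land at arc-length fractions k/(n-1), k = 0..n-1, by piecewise
    linear interpolation; endpoints are preserved exactly.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    points = np.asarray(points, dtype=float)
    s = arc_lengths(points)
    if s[-1] <= 0:
        raise ValueError("zero-length streamline cannot be resampled")
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, points[:, d]) for d in range(3)])


def densify(points: np.ndarray, max_step: float) -> np.ndarray:
    """Upsample a polyline so consecutive vertices are at most ``max_step`` apart."""
    points = np.asarray(points, dtype=float)
    length = total_length(points)
    if length <= 0:
        return points
    n = max(int(np.ceil(length / max_step)) + 1, len(points))
    return resample_to_nodes(points, n)
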