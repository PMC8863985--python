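"""Tract profiles: 100-node resampling, bundle cores and scalar statistics.

A cleaned bundle is summarised as a tract profile: every member streamline
is resampled to n equidistant nodes (default 100), traversal direction is
canonicalised so node 1 sits at the first-waypoint end, the per-node mean
position defines the bundle core, and the scalar map (R1 or MD) is sampled
at every member's node points and averaged per node.  The default average
is gaussian-weighted: a member's sample at node k is weighted by
exp(-d^2/2), where d is its Mahalanobis distance to the node's point
distribution, so stray trajectories contribute less to the profile.

Scalar sampling is trilinear and validity-aware.  In strict mode (the
default) a sample is missing when any of its 8 neighbouring voxels is
invalid — this is what makes the ventricle exclusion mask effective, since
CSF partial-volume voxels then never leak into a profile.  Lenient mode
renormalises the interpolation weights over the valid neighbours instead.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .geometry import resample_to_nodes
from .io import ScalarVolume, StreamlineSet, mm_to_voxel
from .segmentation import SegmentedBundle, _node_stats

__all__ = ["TractProfile", "canonicalize_orientation", "compute_core",
           "compute_profile", "node_coordinates_table", "resample_to_nodes",
           "sample_scalar"]


@dataclasses.dataclass
class TractProfile:
    """Per-node summary of one bundle in one session.

    Nodes are 0-indexed in the arrays but 1-based (1..n_nodes) in every
    table written to disk.  ``value_mean`` is NaN where no member
    contributed a valid sample (n_contrib == 0).
    """

    bundle: str
    n_nodes: int
    core_xyz: np.ndarray          # (n, 3) mm
    node_cov: np.ndarray          # (n, 3, 3) mm^2
    value_mean: np.ndarray        # (n,)
    value_se: np.ndarray          # (n,)
    n_contrib: np.ndarray         # (n,) int
    metric: str = "value"


def canonicalize_orientation(streamlines: StreamlineSet,
                             bundle: SegmentedBundle) -> list[np.ndarray]:
    """Member polylines with flips applied so node 1 ends coincide.

    Uses the orientation flags recorded at candidacy time (flip = waypoint
    order matched backwards), so after this every member starts nearest the
    order-1 waypoint.
    """
    out = []
    for i, flip in zip(bundle.member_indices, bundle.flipped):
        pts = streamlines[i]
        out.append(pts[::-1].copy() if flip else pts)
    return out


def compute_core(members: list[np.ndarray], n: int = 100,
                 cov_reg_mm2: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean position and regularised covariance of a bundle."""
    if not members:
        raise ValueError("cannot compute the core of an empty bundle")
    resampled = np.stack([resample_to_nodes(m, n) for m in members])
    return _node_stats(resampled, cov_reg_mm2)


def sample_scalar(vol: ScalarVolume, points: np.ndarray,
                  mode: str = "strict") -> np.ndarray:
    """Validity-aware trilinear sampling of RAS-mm points; NaN = missing."""
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vox = mm_to_voxel(vol.affine, pts)
    shape = np.asarray(vol.shape)

    base = np.floor(vox).astype(np.int64)
    frac = vox - base
    values = np.zeros(len(pts))
    weights = np.zeros(len(pts))
    any_invalid = np.zeros(len(pts), dtype=bool)
    oob = np.zeros(len(pts), dtype=bool)

    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = base + off
        w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        relevant = w > 0
        oob |= relevant & ~inside
        idx_c = np.clip(idx, 0, shape - 1)
        vvalid = vol.valid[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]] & inside
        vals = vol.grid[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]]
        usable = vvalid & relevant
        any_invalid |= relevant & ~vvalid
        values[usable] += (w * np.where(np.isfinite(vals), vals, 0.0))[usable]
        weights[usable] += w[usable]

    out = np.full(len(pts), np.nan)
    if mode == "strict":
        ok = ~any_invalid & ~oob & (weights > 0)
    else:
        ok = ~oob & (weights > 0)
    out[ok] = values[ok] / weights[ok]
    return out


def compute_profile(streamlines: StreamlineSet, bundle: SegmentedBundle,
                    vol: ScalarVolume, weighting: str = "gaussian",
                    n_nodes: int = 100, mode: str = "strict",
                    metric: str | None = None,
                    cov_reg_mm2: float = 0.01) -> TractProfile:
    """Per-node weighted scalar statistics of one bundle against one map."""
    if weighting not in ("gaussian", "uniform"):
        raise ValueError("weighting must be 'gaussian' or 'uniform'")
    members = canonicalize_orientation(streamlines, bundle)
    if not members:
        nan = np.full(n_nodes, np.nan)
        return TractProfile(bundle.name, n_nodes, np.full((n_nodes, 3), np.nan),
                            np.full((n_nodes, 3, 3), np.nan), nan, nan.copy(),
                            np.zeros(n_nodes, dtype=int),
                            metric or vol.units)
    resampled = np.stack([resample_to_nodes(m, n_nodes) for m in members])
    core, cov = _node_stats(resampled, cov_reg_mm2)

    samples = sample_scalar(vol, resampled.reshape(-1, 3), mode=mode)
    samples = samples.reshape(resampled.shape[:2])          # (m, n)

    if weighting == "gaussian":
        d = resampled - core[None]
        inv = np.linalg.inv(cov)
        q = np.einsum("mni,nij,mnj->mn", d, inv, d)
        w = np.exp(-0.5 * np.maximum(q, 0.0))
    else:
        w = np.ones(samples.shape)
    w = np.where(np.isfinite(samples), w, 0.0)

    wsum = w.sum(axis=0)
    n_contrib = np.isfinite(samples).sum(axis=0)
    mean = np.full(n_nodes, np.nan)
    se = np.full(n_nodes, np.nan)
    has = wsum > 0
    safe = np.where(np.isfinite(samples), samples, 0.0)
    mean[has] = (w * safe).sum(axis=0)[has] / wsum[has]
    # weighted SE with effective sample size n_eff = (sum w)^2 / sum w^2
    var = np.zeros(n_nodes)
    var[has] = (w * (safe - mean[None]) ** 2).sum(axis=0)[has] / wsum[has]
    w2 = (w**2).sum(axis=0)
    neff = np.where(w2 > 0, wsum**2 / np.where(w2 > 0, w2, 1.0), 0.0)
    pos = has & (neff > 1)
    se[pos] = np.sqrt(var[pos] / (neff[pos] - 1))
    se[has & (neff <= 1)] = 0.0

    return TractProfile(bundle.name, n_nodes, core, cov, mean, se,
                        n_contrib.astype(int), metric or vol.units)


def node_coordinates_table(profile_table: pd.DataFrame) -> pd.DataFrame:
    """Average (|x|, y, z) node coordinates across newborn sessions.

    Expects the long-format profile table (one row per subject/bundle/node)
    and uses only timepoint == '0m' rows; the |x| convention folds the two
    hemispheres onto one medial-to-lateral axis.
    """
    nb = profile_table[profile_table["timepoint"] == "0m"]
    if nb.empty:
        raise ValueError("no newborn (0m) sessions in the profile table")
    g = nb.assign(x_abs=nb["x"].abs()).groupby(["bundle", "node"], sort=True)
    out = g[["x_abs", "y", "z"]].mean().reset_index()
    return out
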