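"""Waypoint-based white-matter bundle segmentation (infant tractometry core).

A whole-brain streamline set is classified into up to 24 named bundles:

1. candidacy — a streamline is a candidate for a bundle only if it passes
   through all of the bundle's ordered include waypoint ROIs (in order,
   along either traversal direction) and through none of its exclude ROIs;
2. resolution — a streamline qualifying for several bundles is assigned to
   the one whose probability map has the highest mean value along the
   streamline (ties broken by bundle-name lexicographic order);
3. cleaning — members farther than 4 standard deviations of Mahalanobis
   (gaussian) distance from the bundle core are removed iteratively.

Dice-coefficient utilities support validation against reference bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from . import geometry
from .io import (BinaryMask, ScalarVolume, StreamlineSet, mm_to_voxel,
                 read_volume, validate_affine, write_volume)

logger = logging.getLogger(__name__)

__all__ = [
    "BundleAtlas", "BundleDefinition", "DiceResult", "SegmentedBundle",
    "WaypointROI", "bundle_to_mask", "clean_bundle", "dice_coefficient",
    "load_atlas_dir", "resolve_candidates", "save_atlas_dir", "segment_all",
    "streamline_passes_waypoints", "transform_rois_to_subject",
]

#: Bundle families; 11 are hemispheric (suffixed _L / _R), 2 cross-hemispheric.
HEMISPHERIC_FAMILIES = ("ATR", "CS", "pAF", "VOF", "AF", "UCI", "SLF", "CC",
                        "ILF", "IFOF", "MLF")
CROSS_HEMISPHERIC = ("FcMa", "FcMi")
BUNDLE_NAMES = tuple(sorted(
    [f"{f}_{h}" for f in HEMISPHERIC_FAMILIES for h in ("L", "R")]
    + list(CROSS_HEMISPHERIC)
))


@dataclasses.dataclass
class WaypointROI:
    mask: BinaryMask
    order: int
    role: str = "include"  # include | exclude
    space: str = "subject"

    def __post_init__(self) -> None:
        if self.role not in ("include", "exclude"):
            raise ValueError("waypoint role must be 'include' or 'exclude'")
        if self.role == "include" and self.order < 1:
            raise ValueError("include waypoint order must be >= 1")
        if self.mask.n_voxels == 0:
            raise ValueError("waypoint mask is empty")


@dataclasses.dataclass
class BundleDefinition:
    name: str
    waypoints: list[WaypointROI]
    probability_map: ScalarVolume | None = None

    def __post_init__(self) -> None:
        inc = self.includes
        if len(inc) < 2:
            raise ValueError(f"bundle {self.name}: needs >= 2 include waypoints")
        orders = [w.order for w in inc]
        if len(set(orders)) != len(orders):
            raise ValueError(f"bundle {self.name}: include orders must be unique")
        if self.probability_map is not None and np.any(self.probability_map.grid < 0):
            raise ValueError(f"bundle {self.name}: probability map must be >= 0")

    @property
    def includes(self) -> list[WaypointROI]:
        return sorted((w for w in self.waypoints if w.role == "include"),
                      key=lambda w: w.order)

    @property
    def excludes(self) -> list[WaypointROI]:
        return [w for w in self.waypoints if w.role == "exclude"]


@dataclasses.dataclass
class BundleAtlas:
    definitions: list[BundleDefinition]
    template_affine: np.ndarray

    def __post_init__(self) -> None:
        self.template_affine = validate_affine(self.template_affine)
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            raise ValueError("bundle names must be unique")

    def __getitem__(self, name: str) -> BundleDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]


@dataclasses.dataclass
class SegmentedBundle:
    """A named subset of a StreamlineSet with per-member orientation flags."""

    name: str
    member_indices: np.ndarray
    flipped: np.ndarray
    n_removed_cleaning: int = 0
    removed_indices: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        self.flipped = np.asarray(self.flipped, dtype=bool)
        if len(np.unique(self.member_indices)) != len(self.member_indices):
            raise ValueError("member indices must be unique")
        if self.flipped.shape != self.member_indices.shape:
            raise ValueError("flipped flags must align with member indices")

    def __len__(self) -> int:
        return len(self.member_indices)

    @property
    def is_empty(self) -> bool:
        return len(self.member_indices) == 0


@dataclasses.dataclass
class DiceResult:
    value: float
    n_A: int
    n_B: int
    n_intersection: int


# ---------------------------------------------------------------------------
# atlas-to-subject resampling

def transform_rois_to_subject(atlas: BundleAtlas, xfm: np.ndarray,
                              subject_shape: tuple[int, int, int],
                              subject_affine: np.ndarray) -> BundleAtlas:
    """Resample all atlas ROIs/probability maps onto a subject grid.

    ``xfm`` is the 4x4 affine mapping template RAS mm to subject RAS mm.
    Binary ROIs are resampled nearest-neighbour, probability maps trilinear.
    """
    if xfm is None:
        raise ValueError("template-to-subject transform is required")
    xfm = validate_affine(xfm)
    subject_affine = validate_affine(subject_affine)

    # subject voxel -> subject mm -> template mm -> template voxel
    inv = (np.linalg.inv(atlas.template_affine) @ np.linalg.inv(xfm)
           @ subject_affine)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in subject_shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    tvox = (inv @ vox)[:3]

    def _nn(grid: np.ndarray) -> np.ndarray:
        out = map_coordinates(grid.astype(np.float32), tvox, order=0,
                              mode="constant", cval=0.0)
        return out.reshape(subject_shape) > 0.5

    def _tri(grid: np.ndarray) -> np.ndarray:
        out = map_coordinates(grid, tvox, order=1, mode="constant", cval=0.0)
        return out.reshape(subject_shape)

    new_defs = []
    for d in atlas.definitions:
        wps = [WaypointROI(BinaryMask(_nn(w.mask.grid), subject_affine),
                           w.order, w.role, space="subject")
               for w in d.waypoints]
        prob = None
        if d.probability_map is not None:
            prob = ScalarVolume(_tri(d.probability_map.grid), subject_affine,
                                units="a.u.")
        new_defs.append(BundleDefinition(d.name, wps, prob))
    return BundleAtlas(new_defs, subject_affine)


# ---------------------------------------------------------------------------
# candidacy

def streamline_passes_waypoints(points: np.ndarray, bundle: BundleDefinition,
                                densify_step: float | None = None
                                ) -> tuple[bool, bool]:
    """Candidacy verdict for one streamline -> (is_candidate, flipped).

    The streamline is densified to at most half a voxel per step, the
    arc-length position of first contact with each include waypoint is
    recorded, and the contacts must respect waypoint order in one traversal
    direction.  ``flipped`` is True when the order is matched backwards.
    Any contact with an exclude ROI disqualifies.
    """
    includes = bundle.includes
    if densify_step is None:
        densify_step = 0.5 * float(_mask_voxel_sizes(includes[0].mask).min())
    dense = geometry.densify(np.asarray(points, dtype=float), densify_step)
    s = geometry.arc_lengths(dense)

    first_contact = []
    for w in includes:
        hits = w.mask.contains_points(dense)
        if not hits.any():
            return False, False
        first_contact.append((float(s[hits][0]), float(s[hits][-1])))
    for w in bundle.excludes:
        if w.mask.contains_points(dense).any():
            return False, False

    firsts = np.array([fc[0] for fc in first_contact])
    lasts = np.array([fc[1] for fc in first_contact])
    if np.all(np.diff(firsts) > 0):
        return True, False
    # reversed traversal: first contacts in reverse arc-length order; use the
    # last contact in forward parametrisation (= first contact when walking
    # backwards)
    if np.all(np.diff(lasts) < 0):
        return True, True
    return False, False


def _mask_voxel_sizes(mask: BinaryMask) -> np.ndarray:
    return np.sqrt((mask.affine[:3, :3] ** 2).sum(axis=0))


def _default_step(atlas: BundleAtlas) -> float:
    any_mask = atlas.definitions[0].includes[0].mask
    return 0.5 * float(_mask_voxel_sizes(any_mask).min())


# ---------------------------------------------------------------------------
# multi-candidate resolution

def _mean_probability(prob: ScalarVolume, points: np.ndarray) -> float:
    vox = mm_to_voxel(prob.affine, points)
    vals = map_coordinates(prob.grid, vox.T, order=1, mode="constant", cval=0.0)
    return float(vals.mean())


def resolve_candidates(candidacies: Sequence[Sequence[tuple[str, bool]]],
                       streamlines: StreamlineSet,
                       atlas: BundleAtlas) -> dict[str, SegmentedBundle]:
    """Assign each streamline to at most one bundle.

    ``candidacies[i]`` lists (bundle_name, flipped) verdicts for streamline
    i.  Conflicts are resolved by the highest mean probability sampled
    (trilinear) along the streamline vertices; exact ties go to the
    lexicographically first name (with a warning).
    """
    assigned: dict[str, list[tuple[int, bool]]] = {n: [] for n in atlas.names}
    for i, cands in enumerate(candidacies):
        if not cands:
            continue
        if len(cands) == 1:
            name, flip = cands[0]
        else:
            scores = []
            for name, flip in cands:
                prob = atlas[name].probability_map
                if prob is None:
                    raise ValueError(
                        f"bundle {name}: probability map required to resolve "
                        "a multi-bundle candidate")
                scores.append(_mean_probability(prob, streamlines[i]))
            scores = np.asarray(scores)
            best = scores.max()
            tied = [cands[j] for j in range(len(cands))
                    if scores[j] == best]
            if len(tied) > 1:
                logger.warning(
                    "streamline %d: exact probability tie between %s; "
                    "assigning lexicographically first", i,
                    sorted(n for n, _ in tied))
            name, flip = min(tied, key=lambda c: c[0])
        assigned[name].append((i, flip))

    out = {}
    for name, members in assigned.items():
        idx = np.array([m[0] for m in members], dtype=np.int64)
        flp = np.array([m[1] for m in members], dtype=bool)
        out[name] = SegmentedBundle(name, idx, flp)
    return out


# ---------------------------------------------------------------------------
# cleaning

def _node_stats(resampled: np.ndarray, cov_reg_mm2: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean and regularised covariance of (m, n, 3) node points."""
    mean = resampled.mean(axis=0)                    # (n, 3)
    centered = resampled - mean[None]
    m = resampled.shape[0]
    denom = max(m - 1, 1)
    cov = np.einsum("mni,mnj->nij", centered, centered) / denom
    cov += cov_reg_mm2 * np.eye(3)[None]
    return mean, cov


def _gaussian_distances(resampled: np.ndarray, mean: np.ndarray,
                        cov: np.ndarray) -> np.ndarray:
    """Mean-over-nodes Mahalanobis distance of each member, shape (m,)."""
    d = resampled - mean[None]                       # (m, n, 3)
    inv = np.linalg.inv(cov)                         # (n, 3, 3)
    q = np.einsum("mni,nij,mnj->mn", d, inv, d)
    return np.sqrt(np.maximum(q, 0.0)).mean(axis=1)


def clean_bundle(streamlines: StreamlineSet, bundle: SegmentedBundle,
                 n_nodes: int = 100, max_gauss_dist: float = 4.0,
                 max_iter: int = 5, cov_reg_mm2: float = 0.01,
                 min_members: int = 5) -> SegmentedBundle:
    """Iteratively remove members > ``max_gauss_dist`` SD from the core.

    Each member is resampled to ``n_nodes`` equidistant nodes; the per-node
    sample covariance is regularised by adding ``cov_reg_mm2`` (default
    (0.1 mm)^2) to the diagonal so near-parallel bundles never produce a
    singular matrix.  The member's gaussian distance is the mean over nodes
    of the Mahalanobis distance to the node distribution.  Iterates because
    removing outliers shifts the core (at most ``max_iter`` rounds).
    """
    if len(bundle) < min_members:
        if not bundle.is_empty:
            warnings.warn(f"bundle {bundle.name}: fewer than {min_members} "
                          "members, skipping cleaning")
        return bundle

    keep = bundle.member_indices.copy()
    flips = bundle.flipped.copy()
    removed: list[int] = []
    # orientation-consistent node points are required for a meaningful core
    resampled = np.stack([
        geometry.resample_to_nodes(
            streamlines[i][::-1] if f else streamlines[i], n_nodes)
        for i, f in zip(keep, flips)
    ])
    for _ in range(max_iter):
        mean, cov = _node_stats(resampled, cov_reg_mm2)
        dist = _gaussian_distances(resampled, mean, cov)
        out = dist > max_gauss_dist
        if not out.any() or (len(keep) - out.sum()) < 2:
            break
        removed.extend(keep[out].tolist())
        keep, flips, resampled = keep[~out], flips[~out], resampled[~out]
    return SegmentedBundle(
        bundle.name, keep, flips,
        n_removed_cleaning=bundle.n_removed_cleaning + len(removed),
        removed_indices=np.concatenate(
            [bundle.removed_indices, np.asarray(removed, dtype=np.int64)]),
    )


# ---------------------------------------------------------------------------
# end to end

def segment_all(streamlines: StreamlineSet, atlas: BundleAtlas,
                clean: bool = True, n_nodes: int = 100,
                max_gauss_dist: float = 4.0, max_iter: int = 5
                ) -> dict[str, SegmentedBundle]:
    """Candidacy -> probabilistic resolution -> cleaning for every bundle.

    Returns a dict name -> SegmentedBundle (empty bundles included).  The
    result is a partition: no streamline is a member of two bundles.
    """
    if len(streamlines) == 0:
        raise ValueError("streamline set is empty")
    step = _default_step(atlas)
    candidacies: list[list[tuple[str, bool]]] = [[] for _ in streamlines]
    for d in atlas.definitions:
        for i, pts in enumerate(streamlines):
            ok, flip = streamline_passes_waypoints(pts, d, densify_step=step)
            if ok:
                candidacies[i].append((d.name, flip))
    bundles = resolve_candidates(candidacies, streamlines, atlas)
    if clean:
        bundles = {name: clean_bundle(streamlines, b, n_nodes=n_nodes,
                                      max_gauss_dist=max_gauss_dist,
                                      max_iter=max_iter)
                   for name, b in bundles.items()}
    return bundles


def bundle_to_mask(streamlines: StreamlineSet, bundle: SegmentedBundle,
                   reference: ScalarVolume | BinaryMask) -> BinaryMask:
    """Voxelise a bundle: a voxel is set iff >= 1 densified vertex falls in it.

    Members are densified to steps of at most half the smallest voxel size
    so a streamline cannot skip a voxel it crosses diagonally.
    """
    affine = reference.affine
    shape = reference.grid.shape
    grid = np.zeros(shape, dtype=bool)
    step = 0.5 * float(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)).min())
    for i in bundle.member_indices:
        dense = geometry.densify(streamlines[i], step)
        vox = np.floor(mm_to_voxel(affine, dense) + 0.5).astype(np.int64)
        inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        vox = vox[inside]
        grid[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return BinaryMask(grid, affine)


def dice_coefficient(A: BinaryMask, B: BinaryMask) -> DiceResult:
    """DC = 2 |A ∩ B| / (|A| + |B|); defined as 0 for two empty masks."""
    if A.grid.shape != B.grid.shape or not np.allclose(A.affine, B.affine):
        raise ValueError("dice requires masks on the same grid and affine")
    n_a, n_b = A.n_voxels, B.n_voxels
    n_i = int((A.grid & B.grid).sum())
    if n_a + n_b == 0:
        warnings.warn("dice of two empty masks defined as 0")
        return DiceResult(0.0, 0, 0, 0)
    return DiceResult(2.0 * n_i / (n_a + n_b), n_a, n_b, n_i)


# ---------------------------------------------------------------------------
# atlas directory layout (CLI interchange format)

def save_atlas_dir(atlas: BundleAtlas, out_dir: str | Path) -> None:
    """Write an atlas as <bundle>/waypoint<k>.nii.gz + prob.nii.gz + atlas.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"template_affine": atlas.template_affine.tolist(), "bundles": {}}
    for d in atlas.definitions:
        bdir = out_dir / d.name
        bdir.mkdir(exist_ok=True)
        entries = []
        for w in d.waypoints:
            fname = (f"waypoint{w.order}.nii.gz" if w.role == "include"
                     else f"exclude{len(entries)}.nii.gz")
            write_volume(ScalarVolume(w.mask.grid.astype(float), w.mask.affine),
                         bdir / fname)
            entries.append({"file": fname, "order": w.order, "role": w.role})
        if d.probability_map is not None:
            write_volume(d.probability_map, bdir / "prob.nii.gz")
        meta["bundles"][d.name] = {"waypoints": entries,
                                   "has_prob": d.probability_map is not None}
    (out_dir / "atlas.json").write_text(json.dumps(meta, indent=1))


def load_atlas_dir(atlas_dir: str | Path) -> BundleAtlas:
    atlas_dir = Path(atlas_dir)
    meta = json.loads((atlas_dir / "atlas.json").read_text())
    defs = []
    for name, info in meta["bundles"].items():
        wps = []
        for e in info["waypoints"]:
            vol = read_volume(atlas_dir / name / e["file"])
            wps.append(WaypointROI(BinaryMask(vol.grid > 0.5, vol.affine),
                                   e["order"], e["role"]))
        prob = (read_volume(atlas_dir / name / "prob.nii.gz")
                if info.get("has_prob") else None)
        defs.append(BundleDefinition(name, wps, prob))
    return BundleAtlas(defs, np.asarray(meta["template_affine"], dtype=float))
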