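"""Domain containers and readers/writers for streamlines, volumes and tables.

Every spatial object in the package lives in one internal space: continuous
RAS millimetres (x increases to the right, y to anterior, z to superior),
with the origin at the anterior commissure when the input data are ACPC
aligned.  Voxel indices are 0-based and a continuous point belongs to voxel
(i, j, k) under the half-open center-of-voxel convention
[i - 0.5, i + 0.5).  TRK files are normalised to RAS mm on read; writing
emits TCK.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import TckFile, Tractogram

__all__ = [
    "BinaryMask",
    "ScalarVolume",
    "SessionMeta",
    "StreamlineSet",
    "apply_affine",
    "mm_to_voxel",
    "point_in_voxel_indices",
    "read_ir_series",
    "read_profile_table",
    "read_streamlines",
    "read_volume",
    "validate_affine",
    "voxel_to_mm",
    "write_profile_table",
    "write_streamlines",
    "write_volume",
]

# Timepoint labels and the age ranges (days) they must be consistent with.
TIMEPOINT_RANGES = {"0m": (0, 60), "3m": (61, 150), "6m": (151, 10_000)}


def validate_affine(affine: np.ndarray) -> np.ndarray:
    """Check a 4x4 voxel-to-RAS-mm affine: invertible, bottom row (0,0,0,1)."""
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.array_equal(affine[3], [0.0, 0.0, 0.0, 1.0]):
        raise ValueError("affine bottom row must be exactly (0, 0, 0, 1)")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    return nib.affines.apply_affine(affine, points)


def voxel_to_mm(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    return apply_affine(affine, ijk)


def mm_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Continuous voxel coordinates of RAS-mm points."""
    return apply_affine(np.linalg.inv(affine), xyz)


def point_in_voxel_indices(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Integer voxel indices containing each point (half-open boxes)."""
    vox = mm_to_voxel(affine, np.atleast_2d(xyz))
    return np.floor(vox + 0.5).astype(np.int64)


@dataclasses.dataclass
class ScalarVolume:
    """A 3D scalar grid with voxel-to-RAS-mm affine and per-voxel validity.

    ``units`` tags the physical meaning of the values: "s^-1" for R1,
    "mm^2/s" for mean diffusivity, "ms" for T1, "a.u." otherwise.  Voxels
    with ``valid == False`` (e.g. the ventricle exclusion mask, or
    non-converged relaxometry fits) are skipped by downstream sampling.
    """

    grid: np.ndarray
    affine: np.ndarray
    units: str = "a.u."
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"ScalarVolume grid must be 3D, got {self.grid.ndim}D")
        self.affine = validate_affine(self.affine)
        if self.valid is None:
            self.valid = np.isfinite(self.grid)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise ValueError("grid and valid must have identical shapes")
            self.valid = self.valid & np.isfinite(self.grid)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid.copy(), self.affine.copy(), self.units,
                            self.valid.copy())

    def mask_out(self, mask: "BinaryMask") -> "ScalarVolume":
        """Return a copy with voxels inside ``mask`` flagged invalid."""
        if mask.grid.shape != self.grid.shape:
            raise ValueError("exclusion mask grid does not match volume grid")
        out = self.copy()
        out.valid[mask.grid] = False
        return out


@dataclasses.dataclass
class BinaryMask:
    """A boolean grid sharing the volume conventions of ScalarVolume."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("BinaryMask grid must be 3D")
        self.affine = validate_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def contains_points(self, xyz: np.ndarray) -> np.ndarray:
        """Vectorised membership test for RAS-mm points (out of grid = False)."""
        ijk = point_in_voxel_indices(self.affine, xyz)
        shape = np.asarray(self.grid.shape)
        inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
        out = np.zeros(len(ijk), dtype=bool)
        if inside.any():
            sel = ijk[inside]
            out[inside] = self.grid[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out


@dataclasses.dataclass(frozen=True)
class SessionMeta:
    """One scan session: subject, age in days, and the timepoint label."""

    subject_id: str
    age_days: int
    timepoint: str

    def __post_init__(self) -> None:
        if self.age_days < 0:
            raise ValueError("age_days must be non-negative")
        if self.timepoint not in TIMEPOINT_RANGES:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        lo, hi = TIMEPOINT_RANGES[self.timepoint]
        if not lo <= self.age_days <= hi:
            raise ValueError(
                f"age {self.age_days} d inconsistent with timepoint {self.timepoint}"
            )


class StreamlineSet:
    """Streamline polylines in subject RAS mm.

    Each streamline is an (n_points, 3) float array with n_points >= 2,
    consecutive points distinct and positive total arc length.
    """

    def __init__(self, streamlines: Sequence[np.ndarray], space: str = "subject-RAS"):
        cleaned = []
        for i, s in enumerate(streamlines):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {i}: expected (>=2, 3) array")
            steps = np.linalg.norm(np.diff(s, axis=0), axis=1)
            if np.any(steps == 0):
                raise ValueError(f"streamline {i}: consecutive points must be distinct")
            cleaned.append(s)
        self.streamlines: list[np.ndarray] = cleaned
        self.space = space

    def __len__(self) -> int:
        return len(self.streamlines)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.streamlines[i]

    def __iter__(self):
        return iter(self.streamlines)


def read_streamlines(path: str | Path) -> StreamlineSet:
    """Read a TCK or TRK file; points are returned in subject RAS mm.

    TRK voxel-space storage is resolved through the header's voxel-to-RAS
    transform; a missing or degenerate header affine raises.
    """
    path = Path(path)
    try:
        tf = nib.streamlines.load(str(path))
    except ValueError as exc:
        raise ValueError(f"unknown streamline format: {path}") from exc
    aff = tf.tractogram.affine_to_rasmm
    if aff is None or abs(np.linalg.det(np.asarray(aff)[:3, :3])) < 1e-12:
        raise ValueError(f"degenerate header affine in {path}")
    sls = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    if not sls:
        raise ValueError(f"no streamlines in {path}")
    return StreamlineSet(sls)


def write_streamlines(sset: StreamlineSet, path: str | Path) -> None:
    """Write streamlines as TCK (always RAS mm, no header ambiguity)."""
    tgram = Tractogram(sset.streamlines, affine_to_rasmm=np.eye(4))
    TckFile(tgram).save(str(path))


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a single 3D NIfTI-1 image; NaN voxels become invalid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
    units = (img.header.get_intent()[2] or "a.u.") if hasattr(img, "header") else "a.u."
    return ScalarVolume(data, img.affine, units=units or "a.u.")


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a ScalarVolume as NIfTI-1; invalid voxels are stored as NaN."""
    data = vol.grid.copy()
    data[~vol.valid] = np.nan
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_sform(vol.affine, code=2)
    img.header.set_qform(vol.affine, code=2)
    img.header.set_intent("none", name=vol.units)
    nib.save(img, str(path))


def read_ir_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4D inversion-recovery magnitude series -> (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D IR series, got {data.ndim}D: {path}")
    return data, img.affine


PROFILE_COLUMNS = ["subject", "age_days", "timepoint", "bundle", "node",
                   "metric", "value", "x", "y", "z"]


def write_profile_table(profiles, meta: SessionMeta, path: str | Path,
                        append: bool = False) -> pd.DataFrame:
    """Write tract profiles for one session as a long-format CSV.

    One row per (bundle, node, metric); node is 1-based (1..n_nodes);
    deterministic row order (bundle name, then node).  Returns the frame.
    """
    n_nodes = {p.n_nodes for p in profiles}
    if len(n_nodes) > 1:
        raise ValueError("all profiles in a table must share the node count")
    rows = []
    for p in sorted(profiles, key=lambda p: p.bundle):
        for k in range(p.n_nodes):
            rows.append(
                (meta.subject_id, meta.age_days, meta.timepoint, p.bundle,
                 k + 1, p.metric, p.value_mean[k],
                 p.core_xyz[k, 0], p.core_xyz[k, 1], p.core_xyz[k, 2])
            )
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    path = Path(path)
    header = not (append and path.exists())
    df.to_csv(path, index=False, mode="a" if append else "w", header=header)
    return df


def read_profile_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    return df
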