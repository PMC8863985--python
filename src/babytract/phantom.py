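"""Synthetic longitudinal phantom with known ground truth.

The phantom emulates everything the pipeline consumes: 24 named bundles
(11 per hemisphere plus two cross-hemispheric) laid out as smooth arcs and
S-curves in distinct spatial sectors of an ACPC-like space (origin at the
anterior-commissure analog, x > 0 right), streamlines around each
centerline, waypoint boxes and probability maps, a ventricle-analog
exclusion blob, and longitudinal R1/MD volumes for a cohort of subjects
scanned at the newborn / 3-month / 6-month timepoints.

Development is generated from the same model family the analysis fits:

    rate(v) = gamma0 + gamma . z-scored(|x|, y, z, interactions)
              + lambda_speedup * (R1_newborn(v) - mean)

so recovery of every coefficient (and of the grand-mean trajectory) can be
checked against the exact generating values.  Interaction regressors are
mean-centred over the bundle node coordinates, which pins the grand-mean
development rate at exactly ``gamma0`` regardless of coordinate
correlations; without this the bundle-average trajectory would drift away
from the configured means.

Default calibration: per-bundle newborn R1 means average exactly
0.46 s^-1 over the 24 bundles (range 0.42-0.55, projection bundles highest
and FcMi/IFOF lowest); gamma0 = 0.16/180 s^-1 per day so the grand mean
gains 0.16 s^-1 over the 180-day mean age gap between the newborn and
6-month sessions; lambda_speedup = -0.003 per day; spatial coefficients as
in the fitted infant data (z 1.68e-4, y -1.10e-4, y*z 1.05e-4,
|x| 4.19e-5, |x|*y -4.74e-5 s^-1/day per z-scored coordinate).  MD mirrors
the construction with negative rates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import zoom as ndi_zoom
from scipy.spatial import cKDTree

from .io import BinaryMask, ScalarVolume, SessionMeta, StreamlineSet
from .relaxometry import TISchedule
from .segmentation import (BUNDLE_NAMES, BundleAtlas, BundleDefinition,
                           CROSS_HEMISPHERIC, HEMISPHERIC_FAMILIES,
                           WaypointROI)

__all__ = ["PhantomConfig", "PhantomData", "PhantomSession", "PhantomTruth",
           "SlopeModel", "default_sessions", "generate_ir_series",
           "generate_phantom"]

# ---------------------------------------------------------------------------
# bundle geometry: quadratic Bezier control points (right hemisphere; the
# left hemisphere mirrors x -> -x).  Curvy bundles get a third waypoint.

_FAMILY_GEOMETRY: dict[str, tuple[tuple, tuple, tuple, bool]] = {
    #        P0                C               P2          curvy
    "CS":   ((22, -12, -46), (26, -12, -1),  (22, -12, 44), False),
    "ATR":  ((16, 10, 18),   (23, 29, 28),   (26, 48, 30),  False),
    "pAF":  ((50, -52, -4),  (53, -49, 16),  (50, -52, 36), False),
    "VOF":  ((44, -66, -16), (46, -64, 4),   (44, -66, 24), False),
    "SLF":  ((40, -42, 28),  (40, -6, 34),   (40, 30, 28),  False),
    "CC":   ((8, -40, 34),   (8, -3, 39),    (8, 34, 34),   False),
    "ILF":  ((48, -58, -28), (50, -25, -31), (48, 8, -28),  False),
    "IFOF": ((8, -60, -26),  (8, -18, -22),  (8, 24, -26),  False),
    "MLF":  ((57, -44, -16), (59, -14, -14), (57, 16, -16), False),
    "AF":   ((42, 22, 10),   (48, -28, 28),  (42, -34, -16), True),
    "UCI":  ((30, 42, -12),  (38, 20, -30),  (32, -2, -36),  True),
}
_CROSS_GEOMETRY: dict[str, tuple[tuple, tuple, tuple, bool]] = {
    "FcMa": ((-30, -56, 8), (0, -34, 16), (30, -56, 8), True),
    "FcMi": ((-24, 46, 2),  (0, 24, 8),   (24, 46, 2),  True),
}

#: Per-family newborn R1 means (s^-1); the 24-bundle average is exactly
#: 0.46, the range [0.42, 0.55].
NEWBORN_R1_FAMILY_MEANS: dict[str, float] = {
    "CS": 0.55, "ATR": 0.52, "SLF": 0.46, "FcMa": 0.46, "pAF": 0.45,
    "AF": 0.45, "CC": 0.45, "VOF": 0.445, "UCI": 0.445, "ILF": 0.44,
    "MLF": 0.44, "IFOF": 0.43, "FcMi": 0.42,
}


def bundle_control_points(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Control points (P0, C, P2) and the curvy flag for one bundle name."""
    if name in _CROSS_GEOMETRY:
        p0, c, p2, curvy = _CROSS_GEOMETRY[name]
        sign = 1.0
    else:
        family, hemi = name.rsplit("_", 1)
        p0, c, p2, curvy = _FAMILY_GEOMETRY[family]
        sign = -1.0 if hemi == "L" else 1.0
    flip = np.array([sign, 1.0, 1.0])
    return (np.asarray(p0, float) * flip, np.asarray(c, float) * flip,
            np.asarray(p2, float) * flip, curvy)


def _bezier(p0: np.ndarray, c: np.ndarray, p2: np.ndarray,
            t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * c + t**2 * p2


def bundle_centerline(name: str, step_mm: float = 2.0) -> np.ndarray:
    """Arc-length resampled centerline polyline of one bundle."""
    from .geometry import densify
    p0, c, p2, _ = bundle_control_points(name)
    dense = _bezier(p0, c, p2, np.linspace(0.0, 1.0, 200))
    return densify(dense, step_mm)


# ---------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class SlopeModel:
    """Generating coefficients of the development-rate field.

    gammas are s^-1/day per z-scored coordinate; lambda_speedup couples the
    rate to the (centred) newborn R1 in 1/day.
    """

    gamma0: float = 0.16 / 180.0
    gamma_x: float = 4.19e-5
    gamma_y: float = -1.10e-4
    gamma_z: float = 1.68e-4
    gamma_xy: float = -4.74e-5
    gamma_xz: float = 0.0
    gamma_yz: float = 1.05e-4
    lambda_speedup: float = -0.003

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class MDModel:
    """MD mirror of the slope model (mm^2/s; rates negative)."""

    background: float = 1.6e-3
    family_means_scale: tuple[float, float] = (2.4e-3, -2.6e-3)  # a + b*R1mean
    gamma0: float = -1.1e-6
    gamma_x: float = -9.58e-8
    gamma_y: float = 9.78e-8
    gamma_z: float = -1.56e-7
    gamma_xy: float = 6.41e-8
    gamma_xz: float = 0.0
    gamma_yz: float = 0.0
    lambda_speedup: float = -0.002
    texture_sd: float = 2.0e-5
    noise_sd: float = 1.0e-5
    subject_intercept_sd: float = 2.0e-5


@dataclasses.dataclass
class PhantomConfig:
    """All knobs of the synthetic cohort; ``seed`` is mandatory."""

    seed: int
    grid_shape: tuple[int, int, int] = (80, 80, 80)
    voxel_mm: float = 2.0
    streamlines_per_bundle: int = 50
    n_distractors: int = 500
    jitter_sd_mm: float = 1.0
    wiggle_amp_mm: float = 0.3
    centerline_step_mm: float = 2.0
    tube_radius_mm: float = 6.0
    waypoint_halfwidth_mm: float = 6.0
    prob_kernel_mm: float = 4.0
    min_separation_mm: float = 13.0
    brain_radius_mm: float = 95.0
    ventricle_radius_mm: float = 8.0
    newborn_r1_bundle_means: dict[str, float] | None = None
    slope_model: SlopeModel = dataclasses.field(default_factory=SlopeModel)
    md_model: MDModel = dataclasses.field(default_factory=MDModel)
    texture_sd: float = 0.003
    noise_sd: float = 0.005
    subject_intercept_sd: float = 0.01
    sessions: list[SessionMeta] | None = None
    n_nodes: int = 100
    make_md: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for the phantom")
        for f in ("jitter_sd_mm", "texture_sd", "noise_sd",
                  "subject_intercept_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.newborn_r1_bundle_means is None:
            self.newborn_r1_bundle_means = {
                name: NEWBORN_R1_FAMILY_MEANS[
                    name if name in CROSS_HEMISPHERIC else name.rsplit("_", 1)[0]]
                for name in BUNDLE_NAMES
            }
        if set(self.newborn_r1_bundle_means) != set(BUNDLE_NAMES):
            raise ValueError("newborn means must cover exactly the 24 bundles")

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_mm] * 3 + [1.0])
        # voxel center (n/2) sits at the commissure-analog origin
        a[:3, 3] = -self.voxel_mm * np.asarray(self.grid_shape) / 2
        return a

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sessions"] = (None if self.sessions is None else
                         [dataclasses.asdict(s) for s in self.sessions])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("sessions"):
            d["sessions"] = [SessionMeta(**s) for s in d["sessions"]]
        if isinstance(d.get("slope_model"), dict):
            d["slope_model"] = SlopeModel(**d["slope_model"])
        if isinstance(d.get("md_model"), dict):
            md = d["md_model"]
            if isinstance(md.get("family_means_scale"), list):
                md["family_means_scale"] = tuple(md["family_means_scale"])
            d["md_model"] = MDModel(**md)
        if isinstance(d.get("grid_shape"), list):
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def default_sessions(rng: np.random.Generator) -> list[SessionMeta]:
    """The default cohort: 9 newborn, 10 three-month, 10 six-month sessions.

    Six subjects attend all three timepoints, three only the newborn one,
    four only the later two.  Ages are drawn from narrow windows (8-12,
    88-102, 185-195 days) whose newborn-to-6-month mean gap is 180 days.
    """
    sessions = []
    def age(lo, hi):
        return int(rng.integers(lo, hi + 1))
    for i in range(1, 7):
        sessions += [SessionMeta(f"s{i:02d}", age(8, 12), "0m"),
                     SessionMeta(f"s{i:02d}", age(88, 102), "3m"),
                     SessionMeta(f"s{i:02d}", age(185, 195), "6m")]
    for i in range(7, 10):
        sessions.append(SessionMeta(f"s{i:02d}", age(8, 12), "0m"))
    for i in range(10, 14):
        sessions += [SessionMeta(f"s{i:02d}", age(88, 102), "3m"),
                     SessionMeta(f"s{i:02d}", age(185, 195), "6m")]
    return sessions


# ---------------------------------------------------------------------------
# outputs

@dataclasses.dataclass
class PhantomSession:
    meta: SessionMeta
    r1: ScalarVolume
    md: ScalarVolume | None = None


@dataclasses.dataclass
class PhantomTruth:
    """Exact generating quantities for validation."""

    labels: list[str]                      # per streamline; "distractor" or name
    node_truth: pd.DataFrame               # bundle, node, x_abs, y, z,
                                           # newborn_r1, slope_r1 (, md cols)
    slope_betas: dict[str, float]
    md_betas: dict[str, float] | None
    newborn_ref_age_days: float
    subject_intercepts: dict[str, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclasses.dataclass
class PhantomData:
    config: PhantomConfig
    streamlines: StreamlineSet
    atlas: BundleAtlas
    sessions: list[PhantomSession]
    ventricle_mask: BinaryMask
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# generation helpers

def validate_separation(centerlines: dict[str, np.ndarray],
                        min_separation_mm: float) -> None:
    """Raise if any two bundle centerlines come closer than the threshold."""
    names = sorted(centerlines)
    trees = {n: cKDTree(centerlines[n]) for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d, _ = trees[b].query(centerlines[a], k=1)
            if d.min() < min_separation_mm:
                raise ValueError(
                    f"bundle centerlines {a} and {b} are only "
                    f"{d.min():.1f} mm apart (< {min_separation_mm} mm); "
                    "tubes would overlap")


def _voxel_center_coords(shape, affine) -> np.ndarray:
    """(nx, ny, nz, 3) array of voxel-center RAS coordinates."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).astype(float)
    return vox * np.diag(affine)[:3] + affine[:3, 3]


def _tube_distance_field(centerline: np.ndarray, coords: np.ndarray,
                         affine: np.ndarray, shape, margin_mm: float
                         ) -> tuple[tuple, np.ndarray]:
    """Distances to a densified centerline inside its bounding box.

    Returns (index slices of the box, distance array within the box).
    """
    from .geometry import densify
    dense = densify(centerline, 1.0)
    lo = dense.min(axis=0) - margin_mm
    hi = dense.max(axis=0) + margin_mm
    vox_lo = np.floor((lo - affine[:3, 3]) / np.diag(affine)[:3]).astype(int)
    vox_hi = np.ceil((hi - affine[:3, 3]) / np.diag(affine)[:3]).astype(int) + 1
    vox_lo = np.clip(vox_lo, 0, np.asarray(shape))
    vox_hi = np.clip(vox_hi, 0, np.asarray(shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(vox_lo, vox_hi))
    box = coords[sl].reshape(-1, 3)
    d, _ = cKDTree(dense).query(box, k=1)
    return sl, d.reshape(coords[sl].shape[:3])


def _smooth_texture(shape, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth random field with pointwise SD ``sd``."""
    coarse = rng.normal(size=(10, 10, 10))
    tex = ndi_zoom(coarse, np.asarray(shape) / 10.0, order=3)
    tex -= tex.mean()
    s = tex.std()
    return tex * (sd / s if s > 0 else 0.0)


def _rician(values: np.ndarray, sd: float, rng: np.random.Generator
            ) -> np.ndarray:
    if sd == 0:
        return values
    re = values + rng.normal(0.0, sd, size=values.shape)
    im = rng.normal(0.0, sd, size=values.shape)
    return np.sqrt(re**2 + im**2)


def _zscore_terms(coords_xyz: np.ndarray, ref: np.ndarray
                  ) -> dict[str, np.ndarray]:
    """z-scored |x|, y, z and mean-centred interactions.

    ``ref`` (m, 3) are the bundle node coordinates defining the reference
    mean/SD (|x| applied to both) and the interaction centring constants.
    """
    rx = np.abs(ref[:, 0])
    ry, rz = ref[:, 1], ref[:, 2]
    stats = {}
    for key, rv in (("x", rx), ("y", ry), ("z", rz)):
        stats[key] = (rv.mean(), rv.std(ddof=1))
    zr = {k: (v - stats[k][0]) / stats[k][1]
          for k, v in (("x", rx), ("y", ry), ("z", rz))}
    centre = {"xy": (zr["x"] * zr["y"]).mean(),
              "xz": (zr["x"] * zr["z"]).mean(),
              "yz": (zr["y"] * zr["z"]).mean()}

    vx = (np.abs(coords_xyz[..., 0]) - stats["x"][0]) / stats["x"][1]
    vy = (coords_xyz[..., 1] - stats["y"][0]) / stats["y"][1]
    vz = (coords_xyz[..., 2] - stats["z"][0]) / stats["z"][1]
    return {"x": vx, "y": vy, "z": vz,
            "xy": vx * vy - centre["xy"], "xz": vx * vz - centre["xz"],
            "yz": vy * vz - centre["yz"]}


def _rate_field(terms: dict[str, np.ndarray], newborn: np.ndarray,
                newborn_ref_mean: float, gamma0: float, gx: float, gy: float,
                gz: float, gxy: float, gxz: float, gyz: float,
                lam: float) -> np.ndarray:
    return (gamma0 + gx * terms["x"] + gy * terms["y"] + gz * terms["z"]
            + gxy * terms["xy"] + gxz * terms["xz"] + gyz * terms["yz"]
            + lam * (newborn - newborn_ref_mean))


# ---------------------------------------------------------------------------
# main generator

def generate_phantom(config: PhantomConfig) -> PhantomData:
    """Build the full synthetic cohort from one seeded configuration.

    Regenerating with the same config and seed is bitwise reproducible.
    """
    from .geometry import resample_to_nodes

    rng_master = np.random.SeedSequence(config.seed)
    (rng_sessions, rng_stream, rng_distract, rng_tex, rng_noise,
     rng_subj) = (np.random.default_rng(s) for s in rng_master.spawn(6))

    affine = config.affine
    shape = config.grid_shape
    coords = _voxel_center_coords(shape, affine)
    r = np.linalg.norm(coords, axis=-1)
    brain = r <= config.brain_radius_mm
    ventricle = r <= config.ventricle_radius_mm

    centerlines = {name: bundle_centerline(name, config.centerline_step_mm)
                   for name in BUNDLE_NAMES}
    validate_separation(centerlines, config.min_separation_mm)

    # --- streamlines ------------------------------------------------------
    streamlines: list[np.ndarray] = []
    labels: list[str] = []
    for name in BUNDLE_NAMES:
        cl = centerlines[name]
        s_norm = np.linspace(0.0, 1.0, len(cl))[:, None]
        for _ in range(config.streamlines_per_bundle):
            offset = rng_stream.normal(0.0, config.jitter_sd_mm, size=3)
            phase = rng_stream.uniform(0.0, 2 * np.pi, size=3)
            wiggle = config.wiggle_amp_mm * np.sin(
                2 * np.pi * 1.5 * s_norm + phase[None, :])
            pts = cl + offset[None, :] + wiggle
            if rng_stream.uniform() < 0.5:   # storage direction is arbitrary
                pts = pts[::-1]
            streamlines.append(pts)
            labels.append(name)
    lim = config.brain_radius_mm - 4.0
    for _ in range(config.n_distractors):
        while True:
            center = rng_distract.uniform(-60.0, 60.0, size=3)
            direction = rng_distract.normal(size=3)
            direction /= np.linalg.norm(direction)
            perp = np.cross(direction, rng_distract.normal(size=3))
            nrm = np.linalg.norm(perp)
            if nrm == 0:
                continue
            perp = perp / nrm * rng_distract.uniform(0.0, 6.0)
            p0 = center - 20.0 * direction
            p2 = center + 20.0 * direction
            pts = _bezier(p0, center + perp, p2, np.linspace(0, 1, 21))
            if np.all(np.linalg.norm(pts, axis=1) < lim):
                break
        streamlines.append(pts)
        labels.append("distractor")
    sset = StreamlineSet(streamlines)

    # --- atlas: waypoint boxes + probability maps -------------------------
    definitions = []
    for name in BUNDLE_NAMES:
        cl = centerlines[name]
        nodes = resample_to_nodes(cl, 101)
        _, _, _, curvy = bundle_control_points(name)
        fractions = (0.25, 0.5, 0.75) if curvy else (0.25, 0.75)
        wps = []
        for order, frac in enumerate(fractions, start=1):
            center = nodes[int(round(frac * 100))]
            inside = np.all(np.abs(coords - center) <=
                            config.waypoint_halfwidth_mm, axis=-1)
            wps.append(WaypointROI(BinaryMask(inside, affine), order, "include"))
        sl, dist = _tube_distance_field(cl, coords, affine, shape,
                                        margin_mm=3 * config.prob_kernel_mm)
        prob = np.zeros(shape)
        prob[sl] = np.exp(-dist**2 / (2 * config.prob_kernel_mm**2))
        definitions.append(BundleDefinition(
            name, wps, ScalarVolume(prob, affine, units="a.u.")))
    atlas = BundleAtlas(definitions, affine)

    # --- newborn R1 / MD fields ------------------------------------------
    tex = _smooth_texture(shape, config.texture_sd, rng_tex)
    md_cfg = config.md_model
    md_tex = _smooth_texture(shape, md_cfg.texture_sd, rng_tex) \
        if config.make_md else None

    r1_newborn = np.where(brain, 0.30, 0.0)
    md_newborn = np.where(brain, md_cfg.background, 0.0) if config.make_md else None
    tube_slices = {}
    for name in BUNDLE_NAMES:
        sl, dist = _tube_distance_field(centerlines[name], coords, affine,
                                        shape, margin_mm=config.tube_radius_mm + 2)
        inside = dist <= config.tube_radius_mm
        tube_slices[name] = (sl, inside)
        mean_b = config.newborn_r1_bundle_means[name]
        box = r1_newborn[sl]
        box[inside] = mean_b + tex[sl][inside] - tex[sl][inside].mean()
        r1_newborn[sl] = box
        if config.make_md:
            a_md, b_md = md_cfg.family_means_scale
            md_mean_b = a_md + b_md * mean_b
            mbox = md_newborn[sl]
            mbox[inside] = md_mean_b + md_tex[sl][inside] - md_tex[sl][inside].mean()
            md_newborn[sl] = mbox

    # --- truth at centerline nodes ---------------------------------------
    node_records = []
    ref_nodes = []
    for name in BUNDLE_NAMES:
        nodes = resample_to_nodes(centerlines[name], config.n_nodes)
        ref_nodes.append(nodes)
    ref_nodes_arr = np.concatenate(ref_nodes)
    terms_grid = _zscore_terms(coords, ref_nodes_arr)

    from .profiles import sample_scalar
    vol_newborn = ScalarVolume(r1_newborn, affine, units="s^-1",
                               valid=brain & ~ventricle)
    node_newborn = {}
    for name, nodes in zip(BUNDLE_NAMES, ref_nodes):
        node_newborn[name] = sample_scalar(vol_newborn, nodes, mode="strict")
    newborn_ref_mean = float(np.concatenate(list(node_newborn.values())).mean())

    sm = config.slope_model
    slope_r1 = _rate_field(terms_grid, r1_newborn, newborn_ref_mean,
                           sm.gamma0, sm.gamma_x, sm.gamma_y, sm.gamma_z,
                           sm.gamma_xy, sm.gamma_xz, sm.gamma_yz,
                           sm.lambda_speedup)
    if config.make_md:
        md_vol_newborn = ScalarVolume(md_newborn, affine, units="mm^2/s",
                                      valid=brain & ~ventricle)
        md_node_newborn = {
            name: sample_scalar(md_vol_newborn, nodes, mode="strict")
            for name, nodes in zip(BUNDLE_NAMES, ref_nodes)}
        md_ref_mean = float(np.concatenate(list(md_node_newborn.values())).mean())
        slope_md = _rate_field(terms_grid, md_newborn, md_ref_mean,
                               md_cfg.gamma0, md_cfg.gamma_x, md_cfg.gamma_y,
                               md_cfg.gamma_z, md_cfg.gamma_xy, md_cfg.gamma_xz,
                               md_cfg.gamma_yz, md_cfg.lambda_speedup)

    slope_vol = ScalarVolume(slope_r1, affine, units="s^-1/day",
                             valid=brain & ~ventricle)
    for name, nodes in zip(BUNDLE_NAMES, ref_nodes):
        node_slope = sample_scalar(slope_vol, nodes, mode="strict")
        for k in range(config.n_nodes):
            rec = {"bundle": name, "node": k + 1,
                   "x_abs": abs(nodes[k, 0]), "y": nodes[k, 1],
                   "z": nodes[k, 2],
                   "newborn_r1": node_newborn[name][k],
                   "slope_r1": node_slope[k]}
            if config.make_md:
                rec["newborn_md"] = md_node_newborn[name][k]
            node_records.append(rec)
    node_truth = pd.DataFrame(node_records)

    # --- longitudinal sessions -------------------------------------------
    sessions_meta = (config.sessions if config.sessions is not None
                     else default_sessions(rng_sessions))
    newborn_ages = [s.age_days for s in sessions_meta if s.timepoint == "0m"]
    if not newborn_ages:
        raise ValueError("phantom cohort needs at least one newborn session")
    ref_age = float(np.mean(newborn_ages))

    subjects = sorted({s.subject_id for s in sessions_meta})
    intercepts = {s: float(rng_subj.normal(0.0, config.subject_intercept_sd))
                  for s in subjects}
    md_intercepts = {s: float(rng_subj.normal(0.0, md_cfg.subject_intercept_sd))
                     for s in subjects} if config.make_md else {}

    valid = brain & ~ventricle
    sessions = []
    for meta in sessions_meta:
        dt = meta.age_days - ref_age
        vals = r1_newborn + slope_r1 * dt + intercepts[meta.subject_id]
        vals = _rician(np.where(brain, vals, 0.0), config.noise_sd, rng_noise)
        r1 = ScalarVolume(vals, affine, units="s^-1", valid=valid.copy())
        md = None
        if config.make_md:
            mvals = md_newborn + slope_md * dt + md_intercepts[meta.subject_id]
            mvals = _rician(np.where(brain, mvals, 0.0), md_cfg.noise_sd,
                            rng_noise)
            md = ScalarVolume(mvals, affine, units="mm^2/s", valid=valid.copy())
        sessions.append(PhantomSession(meta, r1, md))

    truth = PhantomTruth(
        labels=labels, node_truth=node_truth,
        slope_betas={"intercept": sm.gamma0, "zx": sm.gamma_x,
                     "zy": sm.gamma_y, "zz": sm.gamma_z,
                     "zx_zy": sm.gamma_xy, "zx_zz": sm.gamma_xz,
                     "zy_zz": sm.gamma_yz, "newborn": sm.lambda_speedup},
        md_betas=({"intercept": md_cfg.gamma0, "zx": md_cfg.gamma_x,
                   "zy": md_cfg.gamma_y, "zz": md_cfg.gamma_z,
                   "zx_zy": md_cfg.gamma_xy, "zx_zz": md_cfg.gamma_xz,
                   "zy_zz": md_cfg.gamma_yz, "newborn": md_cfg.lambda_speedup}
                  if config.make_md else None),
        newborn_ref_age_days=ref_age,
        subject_intercepts=intercepts,
    )
    return PhantomData(config, sset, atlas, sessions,
                       BinaryMask(ventricle, affine), truth)


# ---------------------------------------------------------------------------
# IR forward simulation

def generate_ir_series(t1_volume: ScalarVolume, schedule: TISchedule,
                       noise_sd: float, seed: int, a: float = 1000.0,
                       b: float = 2.0) -> np.ndarray:
    """Forward-simulate a 4D magnitude IR series from a T1 map (ms).

    Per voxel: |a (1 - b exp(-t/T1))| plus Rician noise of SD ``noise_sd``.
    Invalid voxels produce zero signal.
    """
    rng = np.random.default_rng(seed)
    t = schedule.array
    t1 = np.where(t1_volume.valid, t1_volume.grid, np.inf)
    with np.errstate(over="ignore"):
        sig = np.abs(a * (1.0 - b * np.exp(-t[None, None, None, :]
                                           / t1[..., None])))
    sig = np.where(t1_volume.valid[..., None], sig, 0.0)
    return _rician(sig, noise_sd, rng)


def save_truth_json(truth: PhantomTruth, path: str | Path) -> None:
    d = {
        "labels": truth.labels,
        "slope_betas": truth.slope_betas,
        "md_betas": truth.md_betas,
        "newborn_ref_age_days": truth.newborn_ref_age_days,
        "subject_intercepts": truth.subject_intercepts,
        "origin": list(truth.origin),
        "node_truth": truth.node_truth.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(d))
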