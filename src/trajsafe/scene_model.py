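"""Domain types and file I/O for biopsy-planning scenes and trajectory cohorts.

A *scene* is the full neuroanatomical context of one patient: binary
structure masks (tumour, sulci, eloquent cortex, ventricles), streamline
bundles (corticospinal tract, vessel centerlines), a midsagittal reference
plane derived from the AC/PC landmarks, the biopsy target, and a sampled
cortical surface.  All geometry lives in one world coordinate frame:
RAS axes, millimetres, 0-based voxel indices, a voxel's world position is
its center.

A *cohort table* is one row per planned trajectory (trainee x tumour) with
the behavioural variables recorded during the planning exercise.

Scenes are stored as a directory of standard files (NIfTI masks, TRK
streamlines, a CSV surface point list) tied together by a small JSON
manifest; cohorts are plain CSV.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram
from nibabel.streamlines.trk import TrkFile

__all__ = [
    "Point3",
    "TrajectoryPlan",
    "VolumetricMask",
    "StreamlineBundle",
    "MidlinePlane",
    "AnatomicalScene",
    "SceneError",
    "CohortValidationError",
    "MASK_LABELS",
    "BUNDLE_LABELS",
    "GROUPS",
    "COHORT_COLUMNS",
    "save_scene",
    "load_scene",
    "save_cohort",
    "load_cohort",
    "validate_cohort",
]

MASK_LABELS = ("sulcus", "eloquent_cortex", "ventricle", "tumour", "vessel")
BUNDLE_LABELS = ("CST", "vessel")
#: Study arms: planned with the tractography overlay vs anatomy (MRI) alone.
GROUPS = ("T-nBx", "A-nBx")

COHORT_COLUMNS = (
    "trainee_id",
    "tumour_id",
    "group",
    "entry_x",
    "entry_y",
    "entry_z",
    "target_x",
    "target_y",
    "target_z",
    "planning_time_s",
    "n_trajectory_changes",
    "n_lobe_changes",
    "exercise_order",
    "experience_years",
)


class SceneError(ValueError):
    """A scene file set is missing, inconsistent, or violates an invariant."""


class CohortValidationError(ValueError):
    """One or more cohort rows violate the trajectory-table contract."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid cohort table:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass(frozen=True)
class Point3:
    """A point in world coordinates (RAS, mm)."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        for v in (self.x, self.y, self.z):
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite coordinate in Point3: {self!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Point3":
        a = np.asarray(a, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class TrajectoryPlan:
    """One planned needle path with its behavioural metadata.

    ``entry`` is on the cortical surface, ``target`` inside the tumour.
    ``n_lobe_changes`` counts the subset of trajectory changes where the
    lobe of entry changed, so it can never exceed ``n_trajectory_changes``.
    """

    trainee_id: str
    tumour_id: str
    group: str
    entry: Point3
    target: Point3
    planning_time_s: float
    n_trajectory_changes: int
    n_lobe_changes: int
    exercise_order: int
    experience_years: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.planning_time_s > 0:
            raise ValueError("planning_time_s must be > 0")
        if self.n_trajectory_changes < 0 or self.n_lobe_changes < 0:
            raise ValueError("change counts must be >= 0")
        if self.n_lobe_changes > self.n_trajectory_changes:
            raise ValueError("n_lobe_changes cannot exceed n_trajectory_changes")
        if not 1 <= self.exercise_order <= 10:
            raise ValueError("exercise_order must be in [1, 10]")
        if self.experience_years < 0:
            raise ValueError("experience_years must be >= 0")
        if np.allclose(self.entry.to_array(), self.target.to_array()):
            raise ValueError("entry and target coincide")


@dataclass
class VolumetricMask:
    """A binary structure mask on a regular grid with a voxel->world affine."""

    grid: np.ndarray
    affine: np.ndarray
    label: str

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise SceneError(f"non-invertible affine for mask {self.label!r}")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")
        if np.any(np.linalg.norm(self.affine[:3, :3], axis=0) <= 0):
            raise ValueError("voxel sizes must be > 0")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def nonzero_world(self) -> np.ndarray:
        """World coordinates of the centers of all nonzero voxels, (N, 3)."""
        idx = np.argwhere(self.grid)
        return self.voxel_to_world(idx)

    def contains_point(self, p) -> bool:
        v = np.round(self.world_to_voxel(np.asarray(p, dtype=float))).astype(int)[0]
        if np.any(v < 0) or np.any(v >= np.array(self.grid.shape)):
            return False
        return bool(self.grid[tuple(v)])


@dataclass
class StreamlineBundle:
    """A set of polylines (each an (N, 3) float array in world mm)."""

    streamlines: list
    label: str

    def __post_init__(self):
        if self.label not in BUNDLE_LABELS:
            raise ValueError(f"unknown bundle label {self.label!r}")
        if len(self.streamlines) == 0:
            raise ValueError("bundle must contain at least one streamline")
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            a = np.asarray(sl, dtype=np.float32)
            if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (N>=2, 3) array")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"streamline {i} contains non-finite points")
            cleaned.append(a)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def points(self) -> np.ndarray:
        return np.concatenate(self.streamlines, axis=0)

    def edges(self):
        """All polyline edges concatenated: (P, Q) arrays of shape (M, 3)."""
        P = np.concatenate([sl[:-1] for sl in self.streamlines], axis=0)
        Q = np.concatenate([sl[1:] for sl in self.streamlines], axis=0)
        return P.astype(float), Q.astype(float)


@dataclass(frozen=True)
class MidlinePlane:
    """The midsagittal plane, through the mid-commissural point (MCP).

    The plane contains the AC-PC line; its unit normal is the left-right
    axis, obtained by orthogonalising a lateral hint vector (RAS +x by
    default) against the AC-PC direction.
    """

    ac: Point3
    pc: Point3
    plane_normal: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.plane_normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane_normal must have unit norm")
        object.__setattr__(self, "plane_normal", n)
        if np.allclose(self.ac.to_array(), self.pc.to_array()):
            raise ValueError("AC and PC coincide")

    @classmethod
    def from_landmarks(cls, ac: Point3, pc: Point3, lateral_hint=(1.0, 0.0, 0.0)):
        u = pc.to_array() - ac.to_array()
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise ValueError("AC and PC coincide")
        u = u / nu
        h = np.asarray(lateral_hint, dtype=float)
        n = h - np.dot(h, u) * u
        nn = np.linalg.norm(n)
        if nn < 1e-9:
            raise ValueError("lateral hint is parallel to the AC-PC line")
        return cls(ac=ac, pc=pc, plane_normal=n / nn)

    @property
    def mcp(self) -> np.ndarray:
        """The mid-commissural point, midway between AC and PC."""
        return 0.5 * (self.ac.to_array() + self.pc.to_array())

    def signed_distance(self, p) -> float:
        return float(np.dot(np.asarray(p, dtype=float) - self.mcp, self.plane_normal))


@dataclass
class AnatomicalScene:
    """All structures of one patient in a single world frame.

    ``cst_visible`` models the study presentation: the anatomy-only arm
    plans on the same scene but with the CST overlay withheld from the
    planner.  Safety scoring always uses the full scene.
    """

    tumour_id: str
    tumour_mask: VolumetricMask
    target: Point3
    sulci: VolumetricMask
    eloquent_cortex: VolumetricMask
    ventricles: VolumetricMask
    midline: MidlinePlane
    cortical_surface: np.ndarray
    cst: Optional[StreamlineBundle] = None
    cst_visible: bool = True
    vessels: Optional[StreamlineBundle] = None
    vessel_mask: Optional[VolumetricMask] = None

    def __post_init__(self):
        self.cortical_surface = np.asarray(self.cortical_surface, dtype=np.float32)
        if self.cortical_surface.ndim != 2 or self.cortical_surface.shape[1] != 3:
            raise ValueError("cortical_surface must be an (N, 3) point array")
        if not self.tumour_mask.contains_point(self.target.to_array()):
            raise SceneError(
                f"target {self.target} is not inside the tumour mask of "
                f"scene {self.tumour_id!r}"
            )
        if self.vessels is None and self.vessel_mask is None:
            raise SceneError(f"scene {self.tumour_id!r} has no vessel representation")


# ---------------------------------------------------------------------------
# Scene directory I/O
# ---------------------------------------------------------------------------

_MANIFEST_NAME = "manifest.json"
_SCENE_FORMAT = "trajsafe-scene/1"


def _save_mask(mask: VolumetricMask, path: str) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, path)


def _load_mask(path: str, label: str) -> VolumetricMask:
    img = nib.load(path)
    return VolumetricMask(grid=np.asanyarray(img.dataobj) > 0,
                          affine=np.asarray(img.affine, dtype=float), label=label)


def _save_bundle(bundle: StreamlineBundle, path: str) -> None:
    tg = Tractogram(bundle.streamlines, affine_to_rasmm=np.eye(4))
    TrkFile(tg).save(path)


def _load_bundle(path: str, label: str) -> StreamlineBundle:
    trk = TrkFile.load(path)
    sls = [np.asarray(s, dtype=np.float32) for s in trk.tractogram.streamlines]
    return StreamlineBundle(streamlines=sls, label=label)


def save_scene(scene: AnatomicalScene, path: str) -> None:
    """Write a scene as NIfTI + TRK + CSV files under a JSON manifest."""
    os.makedirs(path, exist_ok=True)
    masks = {
        "tumour": scene.tumour_mask,
        "sulcus": scene.sulci,
        "eloquent_cortex": scene.eloquent_cortex,
        "ventricle": scene.ventricles,
    }
    manifest = {
        "format": _SCENE_FORMAT,
        "tumour_id": scene.tumour_id,
        "target": list(scene.target.to_array()),
        "ac": list(scene.midline.ac.to_array()),
        "pc": list(scene.midline.pc.to_array()),
        "cst_visible": bool(scene.cst_visible),
        "masks": {},
        "bundles": {},
        "surface": "surface.csv",
    }
    for label, mask in masks.items():
        fn = f"{label}.nii"
        _save_mask(mask, os.path.join(path, fn))
        manifest["masks"][label] = fn
    if scene.vessel_mask is not None:
        _save_mask(scene.vessel_mask, os.path.join(path, "vessel.nii"))
        manifest["masks"]["vessel"] = "vessel.nii"
    if scene.cst is not None:
        _save_bundle(scene.cst, os.path.join(path, "cst.trk"))
        manifest["bundles"]["cst"] = "cst.trk"
    if scene.vessels is not None:
        _save_bundle(scene.vessels, os.path.join(path, "vessels.trk"))
        manifest["bundles"]["vessels"] = "vessels.trk"
    # 9 significant digits round-trips float32 exactly
    np.savetxt(
        os.path.join(path, "surface.csv"),
        scene.cortical_surface,
        fmt="%.9g",
        delimiter=",",
        header="x,y,z",
        comments="",
    )
    with open(os.path.join(path, _MANIFEST_NAME), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_scene(path: str) -> AnatomicalScene:
    """Load a scene directory written by :func:`save_scene`."""
    mpath = os.path.join(path, _MANIFEST_NAME)
    if not os.path.exists(mpath):
        raise SceneError(f"no scene manifest at {mpath}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    for label in ("tumour", "sulcus", "eloquent_cortex", "ventricle"):
        if label not in manifest.get("masks", {}):
            raise SceneError(f"scene manifest {mpath} lacks the {label!r} mask")

    def mask_for(label):
        fn = os.path.join(path, manifest["masks"][label])
        if not os.path.exists(fn):
            raise SceneError(f"missing {label!r} mask file: {fn}")
        return _load_mask(fn, label)

    cst = vessels = None
    if manifest["bundles"].get("cst"):
        cst = _load_bundle(os.path.join(path, manifest["bundles"]["cst"]), "CST")
    if manifest["bundles"].get("vessels"):
        vessels = _load_bundle(os.path.join(path, manifest["bundles"]["vessels"]), "vessel")
    vessel_mask = mask_for("vessel") if "vessel" in manifest["masks"] else None
    surface = np.loadtxt(
        os.path.join(path, manifest["surface"]), delimiter=",", skiprows=1
    ).astype(np.float32)
    return AnatomicalScene(
        tumour_id=manifest["tumour_id"],
        tumour_mask=mask_for("tumour"),
        target=Point3.from_array(manifest["target"]),
        sulci=mask_for("sulcus"),
        eloquent_cortex=mask_for("eloquent_cortex"),
        ventricles=mask_for("ventricle"),
        midline=MidlinePlane.from_landmarks(
            Point3.from_array(manifest["ac"]), Point3.from_array(manifest["pc"])
        ),
        cortical_surface=surface,
        cst=cst,
        cst_visible=bool(manifest.get("cst_visible", True)),
        vessels=vessels,
        vessel_mask=vessel_mask,
    )


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the trajectory-table contract row-wise.

    Raises :class:`CohortValidationError` listing every offending row by its
    CSV line number (header = line 1).  Returns the validated frame with
    canonical dtypes.
    """
    problems = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing columns: {', '.join(missing)}"])
    df = df.copy()
    if len(df) == 0:
        return df
    for col in ("n_trajectory_changes", "n_lobe_changes", "exercise_order"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    num_cols = [c for c in COHORT_COLUMNS if c not in ("trainee_id", "tumour_id", "group")]
    for col in num_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    for pos, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict()
        line = f"line {pos}"
        if r["group"] not in GROUPS:
            problems.append(f"{line}: unknown group {r['group']!r}")
        if any(pd.isna(r[c]) for c in num_cols):
            problems.append(f"{line}: non-numeric or missing value")
            continue
        if not r["planning_time_s"] > 0:
            problems.append(f"{line}: planning_time_s must be > 0")
        for c in ("n_trajectory_changes", "n_lobe_changes", "exercise_order"):
            if r[c] != int(r[c]):
                problems.append(f"{line}: {c} must be an integer")
        if r["n_trajectory_changes"] < 0 or r["n_lobe_changes"] < 0:
            problems.append(f"{line}: negative change count")
        elif r["n_lobe_changes"] > r["n_trajectory_changes"]:
            problems.append(f"{line}: n_lobe_changes exceeds n_trajectory_changes")
        if not 1 <= r["exercise_order"] <= 10:
            problems.append(f"{line}: exercise_order outside [1, 10]")
        if r["experience_years"] < 0:
            problems.append(f"{line}: negative experience_years")
        e = np.array([r["entry_x"], r["entry_y"], r["entry_z"]])
        t = np.array([r["target_x"], r["target_y"], r["target_z"]])
        if np.allclose(e, t):
            problems.append(f"{line}: entry and target coincide")

    dup = df.duplicated(subset=["trainee_id", "tumour_id"], keep=False)
    if dup.any():
        for idx in np.flatnonzero(dup.to_numpy()):
            problems.append(
                f"line {idx + 2}: duplicate (trainee_id, tumour_id) pair "
                f"({df.iloc[idx]['trainee_id']}, {df.iloc[idx]['tumour_id']})"
            )
    if problems:
        raise CohortValidationError(problems)
    for col in ("n_trajectory_changes", "n_lobe_changes", "exercise_order"):
        df[col] = df[col].astype(int)
    return df


def load_cohort(path: str) -> pd.DataFrame:
    """Read and validate a cohort CSV (one row per planned trajectory)."""
    df = pd.read_csv(path, dtype={"trainee_id": str, "tumour_id": str, "group": str})
    return validate_cohort(df)


def save_cohort(df: pd.DataFrame, path: str) -> None:
    df = df[list(COHORT_COLUMNS)]
    df.to_csv(path, index=False)
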