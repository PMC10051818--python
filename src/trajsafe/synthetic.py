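"""Seeded generators for synthetic neuroanatomy and planning behaviour.

Patient data from navigation workstations cannot be redistributed, so the
pipeline is exercised on synthetic scenes that reproduce the geometric
situation of the study population: a deep-seated tumour in the central
core with its biopsy target at the centroid, a corticospinal tract (CST)
bundle descending from the precentral (M1) band through the internal
capsule to the brainstem and *deviated laterally* around the tumour,
cortical vessels, sulcal sheets, a ventricle, and the midsagittal plane at
x = 0 (RAS mm; the right hemisphere, x > 0, is modelled).

The behavioural simulator emulates a trainee planning one biopsy on a
navigation workstation: candidate entry points are sampled on the cortical
surface and scored by a penalty built from the structures *visible to the
planner*; the tractography-enhanced arm (T-nBx) sees the true CST while
the anatomy-only arm (A-nBx) works from a noisy anatomical prior (the
undeviated bundle plus a per-trainee offset).  Counts of candidate
rejections and lobe switches, and lognormal planning times, are calibrated
to the group-level means of the study cohort (see
:class:`CohortParams`).  This is an emulation device for exercising the
pipeline, not a model of surgeon cognition.

Everything is deterministic given the seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .geometry import segment_to_edges_distance
from .scene_model import (
    GROUPS,
    AnatomicalScene,
    MidlinePlane,
    Point3,
    StreamlineBundle,
    TrajectoryPlan,
    VolumetricMask,
)

__all__ = [
    "SceneParams",
    "CohortParams",
    "Trainee",
    "LOBE_NAMES",
    "lobe_of",
    "generate_scene",
    "generate_scenes",
    "generate_cst_bundle",
    "generate_trainees",
    "simulate_planning_session",
    "generate_cohort",
]

_T, _A = "T-nBx", "A-nBx"

LOBE_NAMES = ("frontal", "parietal", "temporal", "occipital")


def lobe_of(points: np.ndarray) -> np.ndarray:
    """4-way lobe partition of the hemisphere by fixed landmark planes.

    Frontal anterior of y = 16, occipital posterior of y = -60, temporal
    inferior of z = -6 in between, parietal otherwise.  Returns integer
    codes indexing :data:`LOBE_NAMES`.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    y, z = p[:, 1], p[:, 2]
    codes = np.full(len(p), 1, dtype=int)  # parietal
    codes[z < -6.0] = 2  # temporal
    codes[y < -60.0] = 3  # occipital
    codes[y > 16.0] = 0  # frontal
    return codes


@dataclass
class SceneParams:
    """Geometry of one synthetic patient scene (all lengths in mm).

    The hemisphere is a half-ellipsoid; the central-core box bounds the
    tumour so that every target sits deep among the Rolandic structures,
    with the internal-capsule corridor of the CST running beside it.
    """

    voxel_mm: float = 2.0
    brain_center: tuple = (0.0, -4.0, 4.0)
    semi_axes: tuple = (62.0, 84.0, 66.0)
    core_lo: tuple = (18.0, -26.0, -8.0)
    core_hi: tuple = (40.0, 8.0, 20.0)
    tumour_radius_range: tuple = (8.0, 11.0)
    n_cst_streamlines: int = 25
    cst_spread_mm: float = 3.0
    cst_start_y_range: tuple = (-12.0, 2.0)
    cst_clearance_mm: float = 2.5
    capsule_waypoint: tuple = (24.0, -16.0, 2.0)
    brainstem_lo: tuple = (2.0, -34.0, -64.0)
    brainstem_hi: tuple = (16.0, -12.0, -38.0)
    n_vessels: int = 72
    vessel_step_mm: float = 4.0
    n_sulci: int = 14
    sulcus_halfwidth_mm: float = 2.0
    sulcus_depth_frac: float = 0.72
    m1_y_range: tuple = (-10.0, 26.0)
    m1_z_min: float = 0.0
    m1_shell_frac: float = 0.86
    ventricle_center: tuple = (13.0, -6.0, 4.0)
    ventricle_axes: tuple = (7.0, 26.0, 11.0)
    n_surface_points: int = 6000
    ac: tuple = (0.0, 12.0, 0.0)
    pc: tuple = (0.0, -14.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = np.array(self.core_lo), np.array(self.core_hi)
        rmax = self.tumour_radius_range[1]
        if np.any(hi - lo < 2 * rmax):
            raise ValueError("tumour cannot fit inside the central-core bounds")
        if min(self.semi_axes) <= 0 or self.voxel_mm <= 0:
            raise ValueError("all extents must be positive")
        if self.tumour_radius_range[0] <= 0:
            raise ValueError("tumour radius must be positive")


def _grid_geometry(p: SceneParams):
    bc = np.array(p.brain_center)
    ax = np.array(p.semi_axes)
    lo = np.minimum(bc - 1.06 * ax, -6.0)
    lo[0] = -6.0  # only the x > 0 hemisphere is modelled
    hi = bc + 1.06 * ax
    v = p.voxel_mm
    shape = np.ceil((hi - lo) / v).astype(int)
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = lo + v / 2.0
    return affine, tuple(shape)


def _voxel_center_fields(affine, shape):
    ax = [affine[i, i] * np.arange(shape[i]) + affine[i, 3] for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return X, Y, Z


def _ellipsoid_radius(X, Y, Z, center, axes):
    return np.sqrt(
        ((X - center[0]) / axes[0]) ** 2
        + ((Y - center[1]) / axes[1]) ** 2
        + ((Z - center[2]) / axes[2]) ** 2
    )


def _surface_point(u, p: SceneParams):
    """Map unit-sphere directions to the ellipsoid surface."""
    return np.array(p.brain_center) + np.array(p.semi_axes) * u


def _project_to_surface(pts, p: SceneParams):
    bc = np.array(p.brain_center)
    ax = np.array(p.semi_axes)
    e = (pts - bc) / ax
    e /= np.linalg.norm(e, axis=-1, keepdims=True)
    return bc + ax * e


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _push_lateral(points: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Deviate streamline points laterally (+x) out of a spherical tumour.

    A point inside the clearance sphere is moved along +x onto the sphere
    surface, which strictly increases its x coordinate; the deviated bundle
    therefore sits lateral to where it would run without the tumour.
    """
    out = points.copy()
    d = out - center
    ryz2 = d[:, 1] ** 2 + d[:, 2] ** 2
    r2 = radius**2
    inside = (d**2).sum(axis=1) < r2
    escape = ryz2 < r2
    move = inside & escape
    out[move, 0] = center[0] + np.sqrt(r2 - ryz2[move])
    return out


def generate_cst_bundle(
    p: SceneParams,
    seed: int,
    tumour: Optional[tuple] = None,
) -> StreamlineBundle:
    """Generate the CST as streamlines from the M1 band to the brainstem.

    Every streamline starts on the precentral (M1) band just below the
    cortical surface, descends through the internal-capsule corridor and
    ends inside the brainstem box.  With ``tumour=(center, radius)`` the
    points are deviated laterally around the tumour (never through it);
    with ``tumour=None`` the undeviated anatomical course is produced.
    """
    rng = np.random.default_rng(seed)
    bc = np.array(p.brain_center)
    bs_lo, bs_hi = np.array(p.brainstem_lo), np.array(p.brainstem_hi)
    cap = np.array(p.capsule_waypoint)
    y0, y1 = p.cst_start_y_range
    clearance = None
    if tumour is not None:
        tc, tr = np.asarray(tumour[0], dtype=float), float(tumour[1])
        clearance = tr + p.cst_clearance_mm

    ax_ = np.array(p.semi_axes)
    streamlines = []
    for _ in range(p.n_cst_streamlines):
        # start on the M1 band, slightly inside the cortical shell; the
        # unit-sphere direction is built so the band is hit directly
        uy = (rng.uniform(y0, y1) - bc[1]) / ax_[1] / 0.96
        uz = rng.uniform(0.45, 0.8)
        ux = math.sqrt(max(1e-6, 1.0 - uy**2 - uz**2))
        u = np.array([ux, uy, uz])
        s = bc + ax_ * u * 0.96
        c = cap + rng.normal(scale=p.cst_spread_mm, size=3)
        c_up = c + np.array([0.0, -2.0, 26.0]) + rng.normal(scale=2.0, size=3)
        b = rng.uniform(bs_lo, bs_hi)
        ctrl = np.stack([s, c_up, c, b])
        # chord-length parametrised cubic through the control points
        t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))])
        t /= t[-1]
        spline = CubicSpline(t, ctrl, axis=0)
        pts = spline(np.linspace(0.0, 1.0, 40))
        # resample at ~2 mm so the lateral push cannot leave chord
        # segments cutting back through the clearance sphere
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        n_dense = max(40, int(arc[-1] / 2.0))
        pts = spline(np.interp(np.linspace(0.0, arc[-1], n_dense), arc,
                               np.linspace(0.0, 1.0, 40)))
        if clearance is not None:
            pts = _push_lateral(pts, tc, clearance)
        streamlines.append(pts.astype(np.float32))
    bundle = StreamlineBundle(streamlines=streamlines, label="CST")
    if clearance is not None:
        # deviation model guarantees no point inside the tumour
        dist = np.linalg.norm(bundle.points() - tc, axis=1)
        if np.any(dist < tr):
            raise RuntimeError("tumour geometry blocks all CST paths")
    return bundle


def _generate_vessels(p: SceneParams, rng) -> StreamlineBundle:
    """Smooth random polylines walked over the cortical surface."""
    polylines = []
    for _ in range(p.n_vessels):
        while True:
            u = rng.normal(size=3)
            u[0] = abs(u[0])
            u /= np.linalg.norm(u)
            start = _surface_point(u, p)
            if start[0] > 3.0:
                break
        normal = u
        tang = rng.normal(size=3)
        tang -= np.dot(tang, normal) * normal
        tang /= np.linalg.norm(tang)
        pos = start
        pts = [pos]
        n_steps = int(rng.integers(15, 26))
        for _ in range(n_steps):
            tang = tang + rng.normal(scale=0.35, size=3)
            e = (pos - np.array(p.brain_center)) / np.array(p.semi_axes)
            normal = e / np.linalg.norm(e)
            tang -= np.dot(tang, normal) * normal
            tang /= np.linalg.norm(tang)
            pos = _project_to_surface(pos + p.vessel_step_mm * tang, p)
            if pos[0] < 2.0:
                break
            pts.append(pos)
        if len(pts) >= 2:
            polylines.append(np.asarray(pts, dtype=np.float32))
    return StreamlineBundle(streamlines=polylines, label="vessel")


def generate_scene(p: Optional[SceneParams] = None) -> AnatomicalScene:
    """Build one synthetic patient scene; deterministic given ``p.seed``."""
    p = p or SceneParams()
    p.validate()
    rng = np.random.default_rng(p.seed)
    affine, shape = _grid_geometry(p)
    X, Y, Z = _voxel_center_fields(affine, shape)
    bc, ax = np.array(p.brain_center), np.array(p.semi_axes)
    rr = _ellipsoid_radius(X, Y, Z, bc, ax)

    # tumour: sphere in the central core, target at the centroid
    radius = rng.uniform(*p.tumour_radius_range)
    lo = np.array(p.core_lo) + radius
    hi = np.array(p.core_hi) - radius
    tc = rng.uniform(lo, hi)
    tumour = (X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2 <= radius**2

    # ventricle: paraventricular ellipsoid near the midline
    vc, va = np.array(p.ventricle_center), np.array(p.ventricle_axes)
    ventricle = _ellipsoid_radius(X, Y, Z, vc, va) <= 1.0

    # sulci: thin sheets through the brain center restricted to the
    # outer shell of the hemisphere
    shell = (rr > p.sulcus_depth_frac) & (rr <= 1.0) & (X > 2.0)
    sulci = np.zeros(shape, dtype=bool)
    rel = np.stack([X - bc[0], Y - bc[1], Z - bc[2]], axis=-1)
    for _ in range(p.n_sulci):
        m = rng.normal(size=3)
        m /= np.linalg.norm(m)
        dist = np.abs(rel @ m)
        sulci |= shell & (dist < p.sulcus_halfwidth_mm)

    # eloquent (M1) band: precentral strip of the cortical shell
    y0, y1 = p.m1_y_range
    eloquent = (
        (rr > p.m1_shell_frac)
        & (rr <= 1.0)
        & (Y >= y0)
        & (Y <= y1)
        & (Z >= p.m1_z_min)
        & (X > 2.0)
    )

    cst = generate_cst_bundle(p, seed=int(rng.integers(2**31)), tumour=(tc, radius))
    vessels = _generate_vessels(p, rng)

    surf = _surface_point(_fibonacci_sphere(p.n_surface_points), p)
    surf = surf[surf[:, 0] > 3.0]

    def mask(grid, label):
        return VolumetricMask(grid=grid, affine=affine, label=label)

    return AnatomicalScene(
        tumour_id=f"synthetic-{p.seed}",
        tumour_mask=mask(tumour, "tumour"),
        target=Point3.from_array(tc),
        sulci=mask(sulci, "sulcus"),
        eloquent_cortex=mask(eloquent, "eloquent_cortex"),
        ventricles=mask(ventricle, "ventricle"),
        midline=MidlinePlane.from_landmarks(
            Point3.from_array(p.ac), Point3.from_array(p.pc)
        ),
        cortical_surface=surf.astype(np.float32),
        cst=cst,
        cst_visible=True,
        vessels=vessels,
    )


def generate_scenes(
    seed: int, n: int = 10, base: Optional[SceneParams] = None
) -> list:
    """Generate the study's patient set: ``n`` scenes with derived seeds."""
    base = base or SceneParams()
    scenes = []
    for i in range(n):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        params = SceneParams(**{**base.__dict__, "seed": child})
        scene = generate_scene(params)
        scene.tumour_id = f"P{i + 1:02d}"
        scenes.append(scene)
    return scenes


# ---------------------------------------------------------------------------
# Behavioural cohort simulation
# ---------------------------------------------------------------------------

#: UK specialty-training tiers of the study cohort.
TIER_NAMES = ("ST1-2", "ST3-5", "ST6-8")


@dataclass(frozen=True)
class Trainee:
    trainee_id: str
    tier: str
    experience_years: float


def _dict_tt(t_val, a_val):
    return {_T: t_val, _A: a_val}


@dataclass
class CohortParams:
    """Calibrated behavioural parameters of the simulated study cohort.

    Group-level targets are the published cohort means: absolute planning
    time (s), trajectory-change and lobe-change counts per plan.  Times are
    lognormal with a mean-preserving noise term, scaled up with the number
    of changes and, for the anatomy-only arm, decaying with exercise order
    (the learning curve).  Change counts are Poisson with the group mean;
    lobe switches occur per change with probability (lobe mean)/(change
    mean), so every group mean is matched in expectation.
    """

    n_trainees: int = 19
    n_tumours: int = 10
    tier_sizes: tuple = (5, 7, 7)
    tier_year_ranges: tuple = ((0.5, 2.0), (2.0, 5.0), (5.0, 8.5))
    time_mean_s: dict = field(default_factory=lambda: _dict_tt(197.5, 252.8))
    traj_change_mean: dict = field(default_factory=lambda: _dict_tt(2.89, 3.66))
    lobe_change_mean: dict = field(default_factory=lambda: _dict_tt(0.23, 0.66))
    log_time_sigma: dict = field(default_factory=lambda: _dict_tt(0.55, 0.35))
    learning_rate_a: float = 0.06  # log-time decrement per exercise, A-nBx only
    time_change_coupling: float = 2.0
    cst_prior_jitter_mm: float = 3.0
    judgment_noise: dict = field(default_factory=lambda: _dict_tt(0.4, 0.8))
    length_weight: dict = field(default_factory=lambda: _dict_tt(1.3, 0.8))
    w_sulcus: float = 1.6
    w_eloquent: dict = field(default_factory=lambda: _dict_tt(0.4, 0.15))
    w_vessel: float = 0.6
    w_cst: float = 4.0
    cst_margin_mm: float = 8.0
    sampling_avoidance: dict = field(default_factory=lambda: _dict_tt(3.5, 2.5))
    sampling_margin_mm: float = 4.0
    prior_medial_shift_mm: float = 10.0
    superior_bias_tau: dict = field(default_factory=lambda: _dict_tt(48.0, 22.0))
    lateral_bias_tau: float = 38.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trainees != sum(self.tier_sizes):
            raise ValueError("tier sizes must sum to n_trainees")
        if self.n_tumours % 2 != 0:
            raise ValueError("n_tumours must split evenly between the groups")
        for d in (self.time_mean_s, self.traj_change_mean, self.lobe_change_mean):
            if any(v <= 0 for v in d.values()):
                raise ValueError("behavioural means must be positive")


def generate_trainees(p: CohortParams, rng) -> list:
    trainees = []
    k = 0
    for tier, size, (ylo, yhi) in zip(TIER_NAMES, p.tier_sizes, p.tier_year_ranges):
        for _ in range(size):
            k += 1
            trainees.append(
                Trainee(
                    trainee_id=f"TR{k:02d}",
                    tier=tier,
                    experience_years=float(np.round(rng.uniform(ylo, yhi), 2)),
                )
            )
    return trainees


_PRIOR_SEED = 48611  # canonical "textbook atlas" expectation of the CST course


class _PlannerScene:
    """Precomputed lookups for fast candidate scoring on one scene.

    Candidate entry sampling is *informed*: each arm down-weights surface
    points whose trajectory would approach the CST it can see -- the true
    (laterally deviated) bundle for the tractography arm, a canonical
    medial "textbook" course for the anatomy arm.  The anatomy arm's belief
    is therefore systematically misdirected, which is what produces its
    higher true-CST and eloquent-cortex hit rates.
    """

    def __init__(self, scene: AnatomicalScene, scene_params: SceneParams,
                 cohort_params: CohortParams):
        self.scene = scene
        self.target = scene.target.to_array()
        mask = scene.tumour_mask
        self.inv_affine = np.linalg.inv(mask.affine)
        self.shape = np.array(mask.grid.shape)
        self.sulci = scene.sulci.grid
        self.eloquent = scene.eloquent_cortex.grid
        # vessel distance field (mm), from rasterised centerlines
        vox = mask.voxel_sizes
        vgrid = np.zeros(mask.grid.shape, dtype=bool)
        pts = _densify(scene.vessels.streamlines, step=min(vox) / 2.0)
        idx = self._to_voxels(pts)
        vgrid[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        self.vessel_edt = ndimage.distance_transform_edt(~vgrid, sampling=vox)
        # true CST edges, and the anatomical prior: the canonical
        # (undeviated) course shifted medially -- where the tract "should"
        # run when the tumour's displacement of it cannot be seen
        self.cst_edges = scene.cst.edges() if scene.cst is not None else None
        prior_params = SceneParams(**{**scene_params.__dict__, "seed": _PRIOR_SEED})
        cap = np.array(prior_params.capsule_waypoint, dtype=float)
        cap[0] -= cohort_params.prior_medial_shift_mm
        prior_params.capsule_waypoint = tuple(cap)
        prior = generate_cst_bundle(prior_params, seed=_PRIOR_SEED, tumour=None)
        self.prior_edges = prior.edges()
        # candidate entry points: cortical surface, superior-approach and
        # convexity bias, further shaped by each arm's visible-CST belief
        surf = scene.cortical_surface.astype(float)
        self.surface = surf
        self.lobes = lobe_of(surf)
        lateral = np.exp((surf[:, 0] - surf[:, 0].max()) / cohort_params.lateral_bias_tau)
        d_true = self._surface_cst_distances(self.cst_edges)
        d_prior = self._surface_cst_distances(self.prior_edges)
        margin = cohort_params.sampling_margin_mm
        self.weights = {}
        self.lobe_idx = {}
        for group, d_vis in ((_T, d_true), (_A, d_prior)):
            base = lateral * np.exp(
                (surf[:, 2] - surf[:, 2].max()) / cohort_params.superior_bias_tau[group]
            )
            k = cohort_params.sampling_avoidance[group]
            avoid = np.exp(-k * np.maximum(0.0, margin - d_vis) / margin)
            w = base * avoid
            w = w / w.sum()
            self.weights[group] = w
            pools = {}
            for code in range(4):
                same = np.flatnonzero(self.lobes == code)
                diff = np.flatnonzero(self.lobes != code)
                pools[code] = ((same, _norm(w[same])), (diff, _norm(w[diff])))
            self.lobe_idx[group] = pools

    def _surface_cst_distances(self, edges):
        if edges is None:
            return np.full(len(self.surface), np.inf)
        P, Q = edges
        out = np.empty(len(self.surface))
        for i, pt in enumerate(self.surface):
            out[i] = segment_to_edges_distance(pt, self.target, P, Q).min()
        return out

    def _to_voxels(self, pts):
        v = pts @ self.inv_affine[:3, :3].T + self.inv_affine[:3, 3]
        v = np.round(v).astype(int)
        return np.clip(v, 0, self.shape - 1)

    def penalty(self, entry, group, p: CohortParams, prior_offset):
        d = self.target - entry
        length = float(np.linalg.norm(d))
        n_s = max(3, int(length / 1.5))
        samples = entry + np.linspace(0.0, 1.0, n_s)[:, None] * d
        idx = self._to_voxels(samples)
        ii, jj, kk = idx[:, 0], idx[:, 1], idx[:, 2]
        sulcus_hit = bool(self.sulci[ii, jj, kk].any())
        eloquent_hit = bool(self.eloquent[ii, jj, kk].any())
        d_vessel = float(self.vessel_edt[ii, jj, kk].min())
        if group == _T:
            P, Q = self.cst_edges
            d_cst = float(segment_to_edges_distance(entry, self.target, P, Q).min())
        else:
            P, Q = self.prior_edges
            d_cst = float(
                segment_to_edges_distance(
                    entry, self.target, P + prior_offset, Q + prior_offset
                ).min()
            )
        pen = (
            p.length_weight[group] * length / 60.0
            + p.w_sulcus * sulcus_hit
            + p.w_eloquent[group] * eloquent_hit
            + p.w_vessel * (d_vessel < 3.0)
            + p.w_cst * max(0.0, p.cst_margin_mm - d_cst) / p.cst_margin_mm
        )
        return pen


def _densify(streamlines, step):
    out = []
    for sl in streamlines:
        sl = np.asarray(sl, dtype=float)
        seg = np.diff(sl, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        for a, v, ln in zip(sl[:-1], seg, lens):
            n = max(1, int(np.ceil(ln / step)))
            t = np.arange(n) / n
            out.append(a + t[:, None] * v)
        out.append(sl[-1:])
    return np.concatenate(out, axis=0)


def _norm(w):
    s = w.sum()
    return w / s if s > 0 else w


def simulate_planning_session(
    trainee: Trainee,
    planner_scene: _PlannerScene,
    group: str,
    params: CohortParams,
    seed,
    exercise_order: int = 1,
    prior_offset=None,
) -> TrajectoryPlan:
    """Simulate one trainee planning one biopsy; deterministic given seed.

    The number of rejected candidates is the trajectory-change count; a
    rejected candidate switches the lobe of entry with the calibrated
    per-change probability, and the lobe-change count tallies the actual
    lobe-label switches along the candidate sequence.  The accepted entry
    is the penalty-minimising candidate under the planner-visible anatomy.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if isinstance(planner_scene, AnatomicalScene):
        planner_scene = _PlannerScene(planner_scene, SceneParams(), params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params
    lam = p.traj_change_mean[group]
    p_lobe = min(1.0, p.lobe_change_mean[group] / lam)
    n_changes = int(rng.poisson(lam))
    if prior_offset is None:
        prior_offset = np.zeros(3)

    ps = planner_scene
    first = int(rng.choice(len(ps.surface), p=ps.weights[group]))
    cand_idx = [first]
    lobe = int(ps.lobes[first])
    n_lobe = 0
    for _ in range(n_changes):
        jump = rng.random() < p_lobe
        pool, w = ps.lobe_idx[group][lobe][1 if jump else 0]
        if jump and len(pool) == 0:
            jump = False
            pool, w = ps.lobe_idx[group][lobe][0]
        nxt = int(rng.choice(pool, p=w))
        new_lobe = int(ps.lobes[nxt])
        if new_lobe != lobe:
            n_lobe += 1
        lobe = new_lobe
        cand_idx.append(nxt)

    noise = rng.normal(0.0, p.judgment_noise[group], size=len(cand_idx))
    pens = [
        ps.penalty(ps.surface[i], group, p, prior_offset) + e
        for i, e in zip(cand_idx, noise)
    ]
    entry = ps.surface[cand_idx[int(np.argmin(pens))]]

    # mean-preserving planning time: group mean x change coupling x
    # learning factor x lognormal noise, each factor with expectation 1
    c = p.time_change_coupling
    f_changes = (c + n_changes) / (c + lam)
    if group == _A:
        a_positions = np.arange(2, 11, 2, dtype=float)
        norm = np.mean(np.exp(-p.learning_rate_a * a_positions))
        g_order = math.exp(-p.learning_rate_a * exercise_order) / norm
    else:
        g_order = 1.0
    sigma = p.log_time_sigma[group]
    noise_t = math.exp(rng.normal(-0.5 * sigma**2, sigma))
    time_s = p.time_mean_s[group] * f_changes * g_order * noise_t

    return TrajectoryPlan(
        trainee_id=trainee.trainee_id,
        tumour_id=ps.scene.tumour_id,
        group=group,
        entry=Point3.from_array(entry),
        target=ps.scene.target,
        planning_time_s=float(time_s),
        n_trajectory_changes=n_changes,
        n_lobe_changes=n_lobe,
        exercise_order=int(exercise_order),
        experience_years=trainee.experience_years,
    )


def build_planner_scenes(scenes, cohort_params: Optional[CohortParams] = None,
                         scene_params: Optional[SceneParams] = None):
    """Precompute planner lookups for each scene (shared across trainees).

    The lookups depend only on the scenes and the behavioural constants,
    not on the cohort seed, so they can be reused across replicate cohorts.
    """
    scene_params = scene_params or SceneParams()
    cohort_params = cohort_params or CohortParams()
    return [_PlannerScene(s, scene_params, cohort_params) for s in scenes]


def generate_cohort(
    scenes: Sequence[AnatomicalScene],
    p: Optional[CohortParams] = None,
    planner_scenes=None,
) -> "pd.DataFrame":
    """Simulate the full planning exercise: every trainee plans every tumour.

    The first half of ``scenes`` forms the tractography-enhanced arm, the
    second half the anatomy-only arm; patients are presented in alternating
    group order, identical for every trainee.  Returns a validated cohort
    table (one row per trajectory).
    """
    import pandas as pd

    from .scene_model import COHORT_COLUMNS, validate_cohort

    p = p or CohortParams()
    p.validate()
    if len(scenes) != p.n_tumours:
        raise ValueError(f"expected {p.n_tumours} scenes, got {len(scenes)}")
    half = p.n_tumours // 2
    presentation = []
    for i in range(half):
        presentation.append((scenes[i], _T, i))
        presentation.append((scenes[half + i], _A, half + i))

    rng = np.random.default_rng(np.random.SeedSequence([p.seed % 2**31, 1]))
    trainees = generate_trainees(p, rng)
    prior_offsets = {
        t.trainee_id: rng.normal(0.0, p.cst_prior_jitter_mm, size=3) for t in trainees
    }
    if planner_scenes is None:
        planner_scenes = build_planner_scenes(scenes, p)
    by_id = {s.tumour_id: ps for s, ps in zip(scenes, planner_scenes)}

    rows = []
    for ti, trainee in enumerate(trainees):
        for order, (scene, group, _si) in enumerate(presentation, start=1):
            child = np.random.SeedSequence([p.seed % 2**31, 2, ti, order])
            plan = simulate_planning_session(
                trainee,
                by_id[scene.tumour_id],
                group,
                p,
                np.random.default_rng(child),
                exercise_order=order,
                prior_offset=prior_offsets[trainee.trainee_id],
            )
            rows.append(
                {
                    "trainee_id": plan.trainee_id,
                    "tumour_id": plan.tumour_id,
                    "group": plan.group,
                    "entry_x": plan.entry.x,
                    "entry_y": plan.entry.y,
                    "entry_z": plan.entry.z,
                    "target_x": plan.target.x,
                    "target_y": plan.target.y,
                    "target_z": plan.target.z,
                    "planning_time_s": plan.planning_time_s,
                    "n_trajectory_changes": plan.n_trajectory_changes,
                    "n_lobe_changes": plan.n_lobe_changes,
                    "exercise_order": plan.exercise_order,
                    "experience_years": plan.experience_years,
                }
            )
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return validate_cohort(df)
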