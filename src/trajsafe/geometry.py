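"""Exact geometric measurements of a needle trajectory against anatomy.

A planned trajectory is a straight segment from the cortical entry point to
the biopsy target.  Every safety quantity reduces to one of four primitives:

* Euclidean length of the segment;
* minimum distance from the segment to a streamline bundle (each polyline
  edge treated as a straight segment);
* minimum distance from the segment to the nonzero-voxel centers of a
  binary mask (0 if the segment passes through a nonzero voxel);
* minimum unsigned distance from the segment to the midsagittal plane.

Mask transgression is decided by exact segment / axis-aligned-voxel-box
intersection using a 3-D DDA (Amanatides-Woo) traversal in voxel space, so
there are no step-size artefacts.  Voxel boxes are centered on the voxel's
world position (the voxel-center convention of :mod:`trajsafe.scene_model`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scene_model import MidlinePlane, Point3, StreamlineBundle, VolumetricMask

__all__ = [
    "Segment",
    "segment_length",
    "point_to_segment_distance",
    "segment_to_edges_distance",
    "min_distance_to_streamlines",
    "min_distance_to_mask",
    "transgresses_mask",
    "distance_to_midline",
    "EmptyBundleError",
    "EmptyMaskError",
]


class EmptyBundleError(ValueError):
    """Raised for an empty streamline bundle (distinct from distance=inf)."""


class EmptyMaskError(ValueError):
    """Raised when a mask has no nonzero voxel."""


def _vec(p) -> np.ndarray:
    if isinstance(p, Point3):
        return p.to_array()
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


@dataclass(frozen=True)
class Segment:
    """A straight trajectory segment from entry ``a`` to target ``b`` (mm)."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = _vec(self.a)
        b = _vec(self.b)
        if np.allclose(a, b):
            raise ValueError("degenerate segment: endpoints coincide")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))

    def reversed(self) -> "Segment":
        return Segment(self.b, self.a)


def segment_length(seg: Segment) -> float:
    """Length of the trajectory: entry point to target, in mm."""
    return seg.length


def point_to_segment_distance(points, a, b) -> np.ndarray:
    """Distance from each of ``points`` (N, 3) to the segment a-b."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    a = _vec(a)
    d = _vec(b) - a
    denom = float(d @ d)
    t = np.clip((P - a) @ d / denom, 0.0, 1.0)
    closest = a + t[:, None] * d
    return np.linalg.norm(P - closest, axis=1)


def segment_to_edges_distance(a, b, P, Q) -> np.ndarray:
    """Distance from segment a-b to each edge P[i]-Q[i]; vectorised.

    Robust clamped closest-point computation between segment pairs
    (Ericson, *Real-Time Collision Detection*, 5.1.9), with zero-length
    edges handled as points.
    """
    a = _vec(a)
    b = _vec(b)
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    d1 = b - a
    d2 = Q - P
    r = a - P
    A = float(d1 @ d1)
    E = np.einsum("ij,ij->i", d2, d2)
    F = np.einsum("ij,ij->i", d2, r)
    C = r @ d1
    B = d2 @ d1
    denom = A * E - B * B

    eps = 1e-12 * max(A, 1.0)
    s = np.where(denom > eps, (B * F - C * E) / np.where(denom > eps, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    degenerate = E <= 1e-12
    t = np.where(degenerate, 0.0, (B * s + F) / np.where(degenerate, 1.0, E))
    t_cl = np.clip(t, 0.0, 1.0)
    # where t left [0,1], recompute s for the clamped t
    reclamp = (t < 0.0) | (t > 1.0)
    s = np.where(reclamp, np.clip((B * t_cl - C) / A, 0.0, 1.0), s)
    # degenerate edges: closest point on the segment to the point P
    s = np.where(degenerate, np.clip(-C / A, 0.0, 1.0), s)
    p1 = a + s[:, None] * d1
    p2 = P + t_cl[:, None] * d2
    return np.linalg.norm(p1 - p2, axis=1)


def min_distance_to_streamlines(seg: Segment, bundle: StreamlineBundle) -> float:
    """Minimum distance (mm) from the trajectory to any streamline.

    Polyline edges are straight (TRK semantics); 0 if trajectory and
    bundle intersect.
    """
    if bundle is None or len(bundle) == 0:
        raise EmptyBundleError("cannot measure distance to an empty bundle")
    P, Q = bundle.edges()
    return float(segment_to_edges_distance(seg.a, seg.b, P, Q).min())


def transgresses_mask(seg: Segment, mask: VolumetricMask) -> bool:
    """True iff the segment intersects at least one nonzero voxel box.

    The segment is mapped into voxel coordinates (voxel i occupying the box
    [i-0.5, i+0.5]) and traversed with a 3-D DDA.
    """
    inv = np.linalg.inv(mask.affine)
    p0 = inv[:3, :3] @ seg.a + inv[:3, 3]
    p1 = inv[:3, :3] @ seg.b + inv[:3, 3]
    d = p1 - p0
    shape = mask.grid.shape
    lo = -0.5
    t0, t1 = 0.0, 1.0
    for i in range(3):
        hi = shape[i] - 0.5
        if abs(d[i]) < 1e-12:
            if p0[i] < lo or p0[i] > hi:
                return False
        else:
            ta = (lo - p0[i]) / d[i]
            tb = (hi - p0[i]) / d[i]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
            if t0 > t1:
                return False
    pos = p0 + t0 * d
    v = np.floor(pos + 0.5).astype(int)
    np.clip(v, 0, np.asarray(shape) - 1, out=v)
    step = np.sign(d).astype(int)
    tmax = np.full(3, np.inf)
    tdelta = np.full(3, np.inf)
    for i in range(3):
        if step[i] != 0:
            boundary = v[i] + 0.5 * step[i]
            tmax[i] = (boundary - p0[i]) / d[i]
            tdelta[i] = abs(1.0 / d[i])
    grid = mask.grid
    while True:
        if grid[v[0], v[1], v[2]]:
            return True
        axis = int(np.argmin(tmax))
        if tmax[axis] > t1 + 1e-12:
            return False
        v[axis] += step[axis]
        if v[axis] < 0 or v[axis] >= shape[axis]:
            return False
        tmax[axis] += tdelta[axis]


def min_distance_to_mask(seg: Segment, mask: VolumetricMask) -> float:
    """Minimum distance (mm) from the segment to any nonzero-voxel center.

    Returns 0 if the segment passes through a nonzero voxel (box test),
    otherwise the exact minimum over voxel centers.
    """
    if not mask.grid.any():
        raise EmptyMaskError(f"mask {mask.label!r} has no nonzero voxel")
    if transgresses_mask(seg, mask):
        return 0.0
    centers = mask.nonzero_world()
    return float(point_to_segment_distance(centers, seg.a, seg.b).min())


def distance_to_midline(seg: Segment, plane: MidlinePlane) -> float:
    """Minimum unsigned distance (mm) from the trajectory to the midline.

    For a straight segment against a plane this is 0 if the endpoints lie
    on opposite sides, else the smaller endpoint distance.
    """
    sa = plane.signed_distance(seg.a)
    sb = plane.signed_distance(seg.b)
    if sa * sb <= 0.0:
        return 0.0
    return float(min(abs(sa), abs(sb)))
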