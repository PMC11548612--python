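"""Geometric canopy-occlusion and survey-flight simulator.

A plantation is modelled as a square lattice of identical trees built
from closed primitives: a vertical stem cylinder (30 m tall, 0.30 m
diameter), four branch cylinders (1 m long, 0.15 m diameter, 45 deg
elevation, laid out as a cross at the stem top) and a foliage sphere
centred at the stem top (1 m diameter for light canopy, 2 m for heavy).
The animal is a 0.25 m-radius sphere tangent to the central stem at a
configurable altitude and compass side.

Occlusion is binary: any ray from the camera centre to a sample point on
the animal sphere that intersects (including grazes) a stem, branch or
foliage primitive fully blocks that line of sight — no partial intensity
attenuation. Visibility is the unblocked fraction of a deterministic
Fibonacci-lattice sample of the camera-facing hemisphere; the animal's
on-image size follows the slant-range/pin-hole relations

    dca = (fh - ka) / cos(90 - da + theta)
    size_px = image_dim * koala_size_m / (2 * dca * tan(fov/2))

and the animal counts as detected when its estimated visible pixel area
reaches one pixel (a binary-occlusion render thresholded at any visible
pixel). Surveys follow a serpentine (lawn-mower) pattern with 2 m
transect spacing and a 2 m along-track step; detection probability per
configuration is the detected fraction of images with the animal inside
the field of view, pooled over eight compass orientations.

A Beer-Lambert surrogate for foliage attenuation is available as the
integrated path length of the camera-animal segment through foliage
spheres, reported as a percentage of the foliage radius.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRUCTURE_LEVELS",
    "TreeScene",
    "KoalaModel",
    "CameraPose",
    "FlightPlan",
    "GeometryQuery",
    "VisibilityResult",
    "build_scene",
    "camera_poses",
    "koala_visibility",
    "detection_probability",
    "slant_range",
    "koala_pixel_size",
    "foliage_path_length",
    "attenuation_profile",
    "segment_blocked",
]

STRUCTURE_LEVELS = ("stems", "stems_branches", "light_foliage", "heavy_foliage")

STEM_HEIGHT_M = 30.0
STEM_RADIUS_M = 0.15
BRANCH_LENGTH_M = 1.0
BRANCH_RADIUS_M = 0.075
BRANCH_ELEVATION_DEG = 45.0
KOALA_RADIUS_M = 0.25
_GRAZE_EPS = 1e-6


class GeometryRangeError(ValueError):
    """Raised when the slant-range cosine is non-positive."""


@dataclasses.dataclass(frozen=True)
class TreeScene:
    """Lattice of tree primitives, stored as flat arrays for ray tests."""

    spacing: float
    structure_level: str
    grid: int
    cyl_base: np.ndarray   # (M, 3)
    cyl_axis: np.ndarray   # (M, 3) unit
    cyl_len: np.ndarray    # (M,)
    cyl_rad: np.ndarray    # (M,)
    sph_centre: np.ndarray  # (K, 3)
    sph_rad: np.ndarray     # (K,)

    @property
    def n_trees(self) -> int:
        return self.grid * self.grid


@dataclasses.dataclass(frozen=True)
class KoalaModel:
    """Animal sphere tangent to the central stem on a compass side."""

    altitude: float
    orientation_deg: float = 0.0  # 0 = north of the stem, clockwise
    radius: float = KOALA_RADIUS_M

    @property
    def centre(self) -> np.ndarray:
        offset = STEM_RADIUS_M + self.radius
        az = math.radians(self.orientation_deg)
        return np.array([offset * math.sin(az), offset * math.cos(az), self.altitude])


@dataclasses.dataclass(frozen=True)
class CameraPose:
    """Camera centre plus viewing direction (heading from +y/north,
    depression angle below horizontal; 90 deg = nadir)."""

    position: np.ndarray
    depression_deg: float
    heading_deg: float = 0.0
    fov_deg: float = 50.0
    image_dim: int = 640

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Right, up, forward unit vectors of the camera frame."""
        h = math.radians(self.heading_deg)
        da = math.radians(self.depression_deg)
        forward = np.array([math.sin(h) * math.cos(da),
                            math.cos(h) * math.cos(da),
                            -math.sin(da)])
        right = np.array([math.cos(h), -math.sin(h), 0.0])
        up = np.cross(right, forward)
        return right, up, forward

    def in_fov(self, point: np.ndarray) -> bool:
        r, u, f = self.basis()
        v = np.asarray(point, dtype=float) - np.asarray(self.position, dtype=float)
        z = float(v @ f)
        if z <= 0:
            return False
        half = math.radians(self.fov_deg) / 2.0
        return (abs(math.atan2(float(v @ r), z)) <= half
                and abs(math.atan2(float(v @ u), z)) <= half)


@dataclasses.dataclass(frozen=True)
class FlightPlan:
    """Serpentine survey: transects at ``transect_spacing``, images every
    ``step`` metres along track, all at altitude ``altitude``."""

    altitude: float
    bounds: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    transect_spacing: float = 2.0
    step: float = 2.0


@dataclasses.dataclass(frozen=True)
class GeometryQuery:
    """Symbols of the slant-range and pixel-size relations."""

    fh: float                 # flight height above ground, m
    ka: float                 # animal altitude, m
    da: float                 # depression angle, deg (90 = nadir)
    theta: float = 0.0        # in-FOV incident angle, deg
    fov: float = 50.0         # full field of view, deg
    image_dimension: int = 640
    koala_size_m: float = 0.5


@dataclasses.dataclass(frozen=True)
class VisibilityResult:
    visible_fraction: float
    visible_pixels: float
    detected: bool
    in_fov: bool


# ---------------------------------------------------------------------------
# scene construction


def build_scene(spacing: float, structure_level: str, grid: int = 9) -> TreeScene:
    """Build the tree lattice at one of the four nested structure levels."""
    if structure_level not in STRUCTURE_LEVELS:
        raise ValueError(f"unknown structure level {structure_level!r}; "
                         f"expected one of {STRUCTURE_LEVELS}")
    if spacing <= 2 * STEM_RADIUS_M:
        raise ValueError("tree spacing must exceed the stem diameter")
    # grid=0 gives an empty (no-tree control) scene
    half = (grid - 1) // 2 if grid > 0 else 0
    xy = [(i * spacing, j * spacing)
          for i in range(-half, grid - half) for j in range(-half, grid - half)]

    bases, axes, lens, rads = [], [], [], []
    for x, y in xy:
        bases.append([x, y, 0.0])
        axes.append([0.0, 0.0, 1.0])
        lens.append(STEM_HEIGHT_M)
        rads.append(STEM_RADIUS_M)
    if structure_level != "stems":
        el = math.radians(BRANCH_ELEVATION_DEG)
        for x, y in xy:
            for az_deg in (0.0, 90.0, 180.0, 270.0):
                az = math.radians(az_deg)
                bases.append([x, y, STEM_HEIGHT_M])
                axes.append([math.sin(az) * math.cos(el),
                             math.cos(az) * math.cos(el),
                             math.sin(el)])
                lens.append(BRANCH_LENGTH_M)
                rads.append(BRANCH_RADIUS_M)

    centres, srads = [], []
    if structure_level in ("light_foliage", "heavy_foliage"):
        r = 0.5 if structure_level == "light_foliage" else 1.0
        for x, y in xy:
            centres.append([x, y, STEM_HEIGHT_M])
            srads.append(r)

    return TreeScene(
        spacing=spacing,
        structure_level=structure_level,
        grid=grid,
        cyl_base=np.array(bases, dtype=float).reshape(-1, 3),
        cyl_axis=np.array(axes, dtype=float).reshape(-1, 3),
        cyl_len=np.array(lens, dtype=float),
        cyl_rad=np.array(rads, dtype=float),
        sph_centre=np.array(centres, dtype=float).reshape(-1, 3),
        sph_rad=np.array(srads, dtype=float),
    )


# ---------------------------------------------------------------------------
# ray intersection (vectorised over rays x primitives)


def _segment_sphere_hit(o: np.ndarray, d: np.ndarray,
                        centre: np.ndarray, radius: np.ndarray) -> np.ndarray:
    """(N rays, K spheres) boolean: segment o + t*d, t in (eps, 1-eps),
    intersects or is inside the closed sphere."""
    if radius.size == 0:
        return np.zeros((o.shape[0], 0), dtype=bool)
    oc = o[:, None, :] - centre[None, :, :]          # (N, K, 3)
    a = np.einsum("ij,ij->i", d, d)[:, None]          # (N, 1)
    b = 2.0 * np.einsum("ij,ikj->ik", d, oc)          # (N, K)
    c = np.einsum("ikj,ikj->ik", oc, oc) - radius[None, :] ** 2
    disc = b * b - 4 * a * c
    hit = np.zeros_like(c, dtype=bool)
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = (-b - sq) / (2 * a)
    t2 = (-b + sq) / (2 * a)
    lo, hi = _GRAZE_EPS, 1.0 - _GRAZE_EPS
    in_range = ((t1 >= lo) & (t1 <= hi)) | ((t2 >= lo) & (t2 <= hi))
    spans = (t1 < lo) & (t2 > hi)  # segment fully inside
    hit[ok] = (in_range | spans)[ok]
    return hit


def _segment_cylinder_hit(o: np.ndarray, d: np.ndarray, base: np.ndarray,
                          axis: np.ndarray, length: np.ndarray,
                          radius: np.ndarray) -> np.ndarray:
    """(N rays, M cylinders) boolean: segment intersects a closed, capped
    finite cylinder (side surface or either cap disc)."""
    if radius.size == 0:
        return np.zeros((o.shape[0], 0), dtype=bool)
    ob = o[:, None, :] - base[None, :, :]             # (N, M, 3)
    d_par = d @ axis.T                                # (N, M)
    o_par = np.einsum("nmj,mj->nm", ob, axis)
    d_perp = d[:, None, :] - d_par[..., None] * axis[None, :, :]
    o_perp = ob - o_par[..., None] * axis[None, :, :]
    a = np.einsum("nmj,nmj->nm", d_perp, d_perp)
    b = 2.0 * np.einsum("nmj,nmj->nm", o_perp, d_perp)
    c = np.einsum("nmj,nmj->nm", o_perp, o_perp) - radius[None, :] ** 2
    lo, hi = _GRAZE_EPS, 1.0 - _GRAZE_EPS

    hit = np.zeros_like(a, dtype=bool)
    # side surface
    disc = b * b - 4 * a * c
    ok = (disc >= 0) & (a > 1e-30)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-b - sq) / (2 * a)
        t2 = (-b + sq) / (2 * a)
    for t in (t1, t2):
        m = o_par + t * d_par
        hit |= ok & (t >= lo) & (t <= hi) & (m >= 0) & (m <= length[None, :])
    # cap discs at m = 0 and m = length
    with np.errstate(divide="ignore", invalid="ignore"):
        for m_plane in (np.zeros_like(length), length):
            t = (m_plane[None, :] - o_par) / d_par
            p_perp = o_perp + t[..., None] * d_perp
            r2 = np.einsum("nmj,nmj->nm", p_perp, p_perp)
            hit |= (np.abs(d_par) > 1e-30) & (t >= lo) & (t <= hi) \
                & (r2 <= radius[None, :] ** 2)
    # segment parallel to axis and inside radius, spanning a cap, is caught
    # by the cap tests; side-parallel grazing inside is caught when c <= 0
    inside_side = (a <= 1e-30) & (c <= 0)
    mids = o_par + 0.5 * d_par
    hit |= inside_side & (mids >= 0) & (mids <= length[None, :])
    return hit


def segment_blocked(origins: np.ndarray, targets: np.ndarray,
                    scene: TreeScene) -> np.ndarray:
    """Boolean per ray: the open segment origin->target intersects any
    scene primitive (grazing counts as blocked)."""
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    tg = np.atleast_2d(np.asarray(targets, dtype=float))
    if o.shape[0] == 1 and tg.shape[0] > 1:
        o = np.broadcast_to(o, tg.shape).copy()
    d = tg - o
    blocked = _segment_sphere_hit(o, d, scene.sph_centre, scene.sph_rad).any(axis=1)
    blocked |= _segment_cylinder_hit(o, d, scene.cyl_base, scene.cyl_axis,
                                     scene.cyl_len, scene.cyl_rad).any(axis=1)
    return blocked


# ---------------------------------------------------------------------------
# visibility and detection probability


def _hemisphere_points(centre: np.ndarray, radius: float, towards: np.ndarray,
                       n: int = 64) -> np.ndarray:
    """Deterministic Fibonacci lattice on the hemisphere facing ``towards``."""
    to_cam = np.asarray(towards, dtype=float) - centre
    w = to_cam / np.linalg.norm(to_cam)
    # orthonormal basis around w
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    i = np.arange(n)
    z = (i + 0.5) / n                      # in (0, 1]: camera-facing half
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    dirs = (np.outer(rho * np.cos(phi), u)
            + np.outer(rho * np.sin(phi), v)
            + np.outer(z, w))
    return centre + radius * dirs


def koala_visibility(scene: TreeScene, koala: KoalaModel, pose: CameraPose,
                     n_rays: int = 64) -> VisibilityResult:
    """Cast rays from the camera to the animal's camera-facing hemisphere.

    ``visible_fraction`` is the unblocked ray fraction; ``visible_pixels``
    the pin-hole pixel area scaled by that fraction; ``detected`` requires
    at least one visible pixel. Out-of-FOV poses are flagged undetected.
    """
    if not pose.in_fov(koala.centre):
        return VisibilityResult(0.0, 0.0, False, in_fov=False)
    return koala_visibility_batch(scene, koala, [pose], n_rays=n_rays)[0]


def _cull_slack(scene: TreeScene, koala_radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal reach of each primitive plus the ray-bundle fattening.

    All rays of one pose lie inside the camera->centre segment fattened by
    the animal radius, so a primitive whose horizontal footprint stays
    further than this slack from the segment's ground track cannot block
    any ray of that pose.
    """
    # branches lean outward by up to length*cos(elevation) from their base
    lean = np.where(scene.cyl_axis[:, 2] < 1.0 - 1e-12,
                    scene.cyl_len * np.sqrt(1.0 - scene.cyl_axis[:, 2] ** 2), 0.0)
    cyl_slack = scene.cyl_rad + lean + koala_radius + 0.05
    sph_slack = scene.sph_rad + koala_radius + 0.05
    return cyl_slack, sph_slack


def _near_segment_2d(points_xy: np.ndarray, a_xy: np.ndarray, b_xy: np.ndarray,
                     slack: np.ndarray) -> np.ndarray:
    """Boolean: horizontal distance from each point to segment a->b <= slack."""
    if points_xy.size == 0:
        return np.zeros(0, dtype=bool)
    ab = b_xy - a_xy
    denom = float(ab @ ab)
    ap = points_xy - a_xy
    t = np.clip(ap @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(ap))
    closest = a_xy + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", points_xy - closest, points_xy - closest)
    return d2 <= slack * slack


def koala_visibility_batch(scene: TreeScene, koala: KoalaModel,
                           poses: Sequence[CameraPose],
                           n_rays: int = 64) -> list[VisibilityResult]:
    """:func:`koala_visibility` for many poses already inside the FOV.

    Primitives far from each pose's line of sight are culled with a cheap
    2-D ground-track test before the exact ray intersections, which keeps
    full-lattice sweeps tractable.
    """
    centre = koala.centre
    cyl_slack, sph_slack = _cull_slack(scene, koala.radius)
    cyl_xy = scene.cyl_base[:, :2]
    sph_xy = scene.sph_centre[:, :2]
    results: list[VisibilityResult] = []
    for pose in poses:
        cam = np.asarray(pose.position, dtype=float)
        ci = np.flatnonzero(_near_segment_2d(cyl_xy, cam[:2], centre[:2], cyl_slack))
        si = np.flatnonzero(_near_segment_2d(sph_xy, cam[:2], centre[:2], sph_slack))
        pts = _hemisphere_points(centre, koala.radius, cam, n_rays)
        o = np.broadcast_to(cam, pts.shape)
        d = pts - o
        blocked = np.zeros(n_rays, dtype=bool)
        if si.size:
            blocked |= _segment_sphere_hit(
                o, d, scene.sph_centre[si], scene.sph_rad[si]).any(axis=1)
        if ci.size:
            blocked |= _segment_cylinder_hit(
                o, d, scene.cyl_base[ci], scene.cyl_axis[ci],
                scene.cyl_len[ci], scene.cyl_rad[ci]).any(axis=1)
        frac = 1.0 - blocked.mean()
        dca = float(np.linalg.norm(cam - centre))
        side_px = pose.image_dim * (2 * koala.radius) / (
            2.0 * dca * math.tan(math.radians(pose.fov_deg) / 2.0))
        visible_px = side_px * side_px * frac
        results.append(VisibilityResult(float(frac), float(visible_px),
                                        detected=bool(visible_px >= 1.0),
                                        in_fov=True))
    return results


def camera_poses(plan: FlightPlan, depression_deg: float) -> list[CameraPose]:
    """Serpentine pose sequence: adjacent transects run in opposite
    directions, headings along the direction of travel."""
    xmin, xmax, ymin, ymax = plan.bounds
    xs = np.arange(xmin, xmax + 1e-9, plan.transect_spacing)
    ys = np.arange(ymin, ymax + 1e-9, plan.step)
    poses = []
    for k, x in enumerate(xs):
        track = ys if k % 2 == 0 else ys[::-1]
        heading = 0.0 if k % 2 == 0 else 180.0
        for y in track:
            poses.append(CameraPose(position=np.array([x, y, plan.altitude]),
                                    depression_deg=depression_deg,
                                    heading_deg=heading))
    return poses


def detection_probability(
    spacings: Sequence[float] = (1.0, 3.0, 5.0),
    structure_levels: Sequence[str] = STRUCTURE_LEVELS,
    koala_altitudes: Sequence[float] = (25.0, 15.0, 0.0),
    depression_angles: Sequence[float] = tuple(range(0, 91, 10)),
    flight_heights: Sequence[float] = (40.0,),
    n_orientations: int = 8,
    n_rays: int = 64,
    grid: int = 9,
    transect_spacing: float = 2.0,
    step: float = 2.0,
    margin: float | None = None,
) -> pd.DataFrame:
    """Probability-of-detection sweep over the full configuration grid.

    For each (spacing, structure level, animal altitude, depression angle,
    flight height), the camera flies a serpentine pattern over the lattice
    and Pd is the detected fraction of animal-in-FOV images, pooled over
    ``n_orientations`` compass placements of the animal. Returned as a
    tidy table with columns spacing, structure_level, ka, da, fh, pd,
    n_images, n_detected (cells with zero in-FOV images carry pd = NaN).
    """
    rows = []
    orientations = [i * 360.0 / n_orientations for i in range(n_orientations)]
    for spacing in spacings:
        scenes = {lvl: build_scene(spacing, lvl, grid=grid) for lvl in structure_levels}
        half_extent = (grid - 1) / 2 * spacing
        for fh in flight_heights:
            m = fh if margin is None else margin
            bound = half_extent + m
            for da in depression_angles:
                plan = FlightPlan(altitude=fh, bounds=(-bound, bound, -bound, bound),
                                  transect_spacing=transect_spacing, step=step)
                poses = camera_poses(plan, da)
                for ka in koala_altitudes:
                    koalas = [KoalaModel(altitude=ka, orientation_deg=o)
                              for o in orientations]
                    in_fov_poses = {
                        o: [p for p in poses if p.in_fov(k.centre)]
                        for o, k in zip(orientations, koalas)
                    }
                    for lvl in structure_levels:
                        scene = scenes[lvl]
                        n_images = 0
                        n_detected = 0
                        for o, k in zip(orientations, koalas):
                            results = koala_visibility_batch(
                                scene, k, in_fov_poses[o], n_rays=n_rays)
                            n_images += len(results)
                            n_detected += sum(r.detected for r in results)
                        rows.append({
                            "spacing": spacing, "structure_level": lvl,
                            "ka": ka, "da": da, "fh": fh,
                            "pd": n_detected / n_images if n_images else float("nan"),
                            "n_images": n_images, "n_detected": n_detected,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analytic geometry (slant range, pixel size, foliage path length)


def slant_range(q: GeometryQuery) -> float:
    """Camera-animal distance (m): ``(fh - ka) / cos(90 - da + theta)``."""
    c = math.cos(math.radians(90.0 - q.da + q.theta))
    if c <= 1e-12:  # includes the horizontal-view limit (cos 90 in floats)
        raise GeometryRangeError(
            f"cos(90 - da + theta) = {c:.4f} <= 0: range undefined")
    return (q.fh - q.ka) / c


def koala_pixel_size(q: GeometryQuery) -> float:
    """Per-side animal image size in pixels from the pin-hole relation."""
    dca = slant_range(q)
    return q.image_dimension * q.koala_size_m / (
        2.0 * dca * math.tan(math.radians(q.fov / 2.0)))


def foliage_path_length(scene: TreeScene, camera: np.ndarray,
                        koala_pos: np.ndarray) -> float:
    """Total length (m) of the camera->animal segment inside foliage
    spheres (the Beer-Lambert surrogate; zero for a clear line of sight)."""
    o = np.asarray(camera, dtype=float)
    d = np.asarray(koala_pos, dtype=float) - o
    total = 0.0
    seg_len = float(np.linalg.norm(d))
    for centre, r in zip(scene.sph_centre, scene.sph_rad):
        oc = o - centre
        a = float(d @ d)
        b = 2.0 * float(oc @ d)
        c = float(oc @ oc) - r * r
        disc = b * b - 4 * a * c
        if disc <= 0:
            continue
        sq = math.sqrt(disc)
        t1 = max((-b - sq) / (2 * a), 0.0)
        t2 = min((-b + sq) / (2 * a), 1.0)
        if t2 > t1:
            total += (t2 - t1) * seg_len
    return total


def attenuation_profile(
    scene: TreeScene,
    camera_height: float = 40.0,
    koala_altitude: float = 25.0,
    max_offset_pct: float = 1000.0,
    n_samples: int = 201,
) -> pd.DataFrame:
    """Integrated foliage path length versus horizontal camera offset.

    The camera moves horizontally away from directly above the animal;
    both offset and path length are reported as percentages of the
    foliage radius R. Multiplying the path column by an attenuation
    coefficient alpha yields the surrogate attenuation.
    """
    if scene.sph_rad.size == 0:
        raise ValueError("scene has no foliage spheres")
    r = float(scene.sph_rad[0])
    koala = KoalaModel(altitude=koala_altitude).centre
    offsets = np.linspace(0.0, max_offset_pct, n_samples)
    rows = []
    for pct in offsets:
        cam = np.array([koala[0] + pct / 100.0 * r, koala[1], camera_height])
        path = foliage_path_length(scene, cam, koala)
        rows.append({"offset_pct_R": pct, "path_pct_R": 100.0 * path / r})
    return pd.DataFrame(rows)
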