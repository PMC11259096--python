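"""Synthetic phantoms with exact ground truth for every pipeline stage.

Every generator is a pure function of its spec (seed included): the same
spec yields byte-identical output. The vessel phantoms emulate confocal
z-stacks of tubular branching networks grown in a soft hydrogel — thin
(~100 µm) volumes, possibly anisotropic voxels (e.g. 5 µm z-step over
1 µm x/y) — so that skeleton metrics can be validated against a known
centerline topology. Other phantoms cover partially overlapping channel
masks, radially growing spheroids, and dot-blot array membranes with
reference spots, plus the seeding-ratio arithmetic of the co-culture
experiment design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stacks import ImageStack

__all__ = [
    "VesselPhantomSpec",
    "PhantomGroundTruth",
    "ColocPhantomSpec",
    "SpheroidPhantomSpec",
    "ArrayPhantomSpec",
    "SeedingConfig",
    "generate_vessel_phantom",
    "generate_coloc_phantom",
    "generate_spheroid_series",
    "generate_array_membrane",
    "stromal_density",
]


class GeometryError(ValueError):
    """Requested phantom geometry does not fit the grid."""


# --------------------------------------------------------------------------
# vessel phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselPhantomSpec:
    """Recipe for a tubular-network phantom.

    ``topology`` is one of ``straight_tube``, ``y_junction`` or
    ``random_tree``. All geometry is specified in physical µm; voxels may
    be anisotropic (``voxel_size`` is µm per (z, y, x) axis). The intensity
    model is foreground/background means, an isotropic-in-physical-units
    Gaussian PSF applied before additive Gaussian noise, mimicking
    acquisition order.
    """

    grid_shape: tuple[int, int, int] = (25, 220, 220)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    topology: str = "straight_tube"
    tube_radius_um: float = 3.0
    length_um: float = 200.0              # straight_tube stem length
    n_segments: int = 12                  # random_tree target
    branch_prob: float = 0.85             # random_tree bifurcation probability
    segment_length_um: float = 35.0       # random_tree mean segment length
    foreground: float = 200.0
    background: float = 20.0
    noise_sd: float = 10.0
    psf_sigma_um: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("straight_tube", "y_junction", "random_tree"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.tube_radius_um < max(self.voxel_size):
            raise GeometryError(
                "tube radius must span at least one voxel along every axis "
                f"(radius {self.tube_radius_um} µm vs voxel {self.voxel_size})"
            )


@dataclass
class PhantomGroundTruth:
    """Known centerline geometry of a vessel phantom.

    ``polylines`` are per-segment (k, 3) physical coordinates (z, y, x in
    µm). ``clean_mask`` is the noise-free rasterized tube mask, kept for
    validating the preprocessing stage.
    """

    polylines: list[np.ndarray]
    total_length_um: float
    n_segments: int
    n_junctions: int
    n_endpoints: int
    segment_lengths_um: list[float]
    clean_mask: np.ndarray | None = None

    def check_invariants(self) -> None:
        assert math.isclose(
            self.total_length_um, sum(self.segment_lengths_um), rel_tol=1e-9
        )
        # tree identity for acyclic topologies
        assert self.n_endpoints + self.n_junctions == self.n_segments + 1


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _build_centerlines(spec: VesselPhantomSpec, rng: np.random.Generator):
    """Return (polylines, junction points, endpoint points) in physical µm."""
    extent = np.array(spec.grid_shape, float) * np.array(spec.voxel_size, float)
    margin = spec.tube_radius_um + 3.0 * spec.psf_sigma_um + 2.0 * max(spec.voxel_size)
    lo, hi = np.full(3, margin), extent - margin
    if np.any(hi <= lo):
        raise GeometryError("grid too small for the requested radius/PSF")

    def centred(axis: int) -> float:
        # snap to a voxel centre: exact half-grid placement is a degenerate
        # symmetry no real acquisition produces
        return (spec.grid_shape[axis] // 2 + 0.5) * spec.voxel_size[axis]

    zc = centred(0)

    if spec.topology == "straight_tube":
        if spec.length_um > hi[2] - lo[2]:
            raise GeometryError("straight tube longer than the grid allows")
        y = centred(1)
        x0 = (extent[2] - spec.length_um) / 2.0
        seg = np.array([[zc, y, x0], [zc, y, x0 + spec.length_um]])
        return [seg], [], [seg[0], seg[1]]

    if spec.topology == "y_junction":
        stem = 0.45 * spec.length_um
        arm = 0.55 * spec.length_um
        ang = math.radians(35.0)
        y = centred(1)
        x0 = lo[2]
        j = np.array([zc, y, x0 + stem])
        a = j + arm * np.array([0.0, math.sin(ang), math.cos(ang)])
        b = j + arm * np.array([0.0, -math.sin(ang), math.cos(ang)])
        for tip in (a, b):
            if np.any(tip < lo) or np.any(tip > hi):
                raise GeometryError("y-junction arms leave the grid")
        root = np.array([zc, y, x0])
        segs = [np.array([root, j]), np.array([j, a]), np.array([j, b])]
        return segs, [j], [root, a, b]

    return _grow_random_tree(spec, rng, lo, hi, extent)


def _grow_random_tree(spec, rng, lo, hi, extent):
    """Recursive bifurcation with angle jitter and inter-segment clearance.

    A minimum clearance of 2x the tube radius between non-adjacent segments
    is enforced by rejection so the ground-truth topology survives
    rasterization and thinning. A growth that terminates short of the
    target segment count (early tip death, crowding) is redrawn from the
    same stream, keeping the result a deterministic function of the seed.
    """
    best = None
    for _ in range(25):
        try:
            out = _grow_random_tree_once(spec, rng, lo, hi, extent)
        except GeometryError:
            continue
        n = len(out[0])
        if best is None or n > len(best[0]):
            best = out
        if n >= spec.n_segments:
            return out
    return best


def _grow_random_tree_once(spec, rng, lo, hi, extent):
    # clearance keeps non-adjacent tube surfaces from fusing after PSF blur:
    # 2x radius separates the surfaces, 3x the PSF sigma keeps the blurred
    # halos from bridging, one voxel absorbs rasterization rounding
    clearance = (
        2.0 * spec.tube_radius_um
        + 3.0 * spec.psf_sigma_um
        + max(spec.voxel_size)
    )
    sample_step = max(1.0, min(spec.voxel_size))

    segments: list[np.ndarray] = []
    seg_samples: list[np.ndarray] = []
    junctions: list[np.ndarray] = []
    endpoints: list[np.ndarray] = []

    def sample(p0, p1):
        n = max(2, int(np.linalg.norm(p1 - p0) / sample_step) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        return p0[None, :] * (1 - t) + p1[None, :] * t

    def clear_of_others(pts, attach: np.ndarray | None):
        """Candidate points must clear every existing segment; only segments
        sharing the attachment point (parent, sibling) are exempt, and only
        within 2x clearance of the junction where tubes genuinely meet."""
        d_attach = (
            None
            if attach is None
            else np.linalg.norm(pts - attach[None, :], axis=1)
        )
        for s, seg in zip(seg_samples, segments):
            adjacent = attach is not None and (
                np.linalg.norm(seg[0] - attach) < 1e-9
                or np.linalg.norm(seg[-1] - attach) < 1e-9
            )
            keep = pts
            if adjacent:
                keep = pts[d_attach > 2.0 * clearance]
                if keep.size == 0:
                    continue
            d = np.linalg.norm(keep[:, None, :] - s[None, :, :], axis=2)
            if d.min() < clearance:
                return False
        return True

    root = np.array([extent[0] / 2.0, extent[1] / 2.0, lo[2]])
    direction = np.array([0.0, 0.0, 1.0])
    # queue of (start point, unit direction, attached-at junction or None)
    queue: list[tuple[np.ndarray, np.ndarray, np.ndarray | None]] = [
        (root, direction, None)
    ]
    endpoints.append(root)

    while queue and len(segments) < spec.n_segments:
        start, direc, attach = queue.pop(0)
        placed = False
        for _ in range(30):
            length = spec.segment_length_um * rng.uniform(0.7, 1.3)
            tilt = rng.normal(0.0, math.radians(8.0))
            swing = rng.normal(0.0, math.radians(10.0))
            d = _rotate_zyx(direc, swing, tilt)
            end = start + length * d
            if np.any(end < lo) or np.any(end > hi):
                continue
            pts = sample(start, end)
            if not clear_of_others(pts, attach):
                continue
            segments.append(np.array([start, end]))
            seg_samples.append(pts)
            placed = True
            break
        if not placed:
            endpoints.append(start)
            if attach is None and len(segments) == 0:
                raise GeometryError("could not place the root segment")
            continue
        end = segments[-1][1]
        if len(segments) + 2 <= spec.n_segments and rng.random() < spec.branch_prob:
            junctions.append(end)
            base = math.radians(32.0)
            for sign in (1.0, -1.0):
                jit = rng.normal(0.0, math.radians(6.0))
                child = _rotate_zyx(_seg_dir(segments[-1]), sign * base + jit,
                                    rng.normal(0.0, math.radians(6.0)))
                queue.append((end, child, end))
        else:
            endpoints.append(end)
    # anything left queued never grew: its start is already a tip of the
    # parent bifurcation, so the parent junction must be demoted if only
    # one child was placed. Count incident segments per junction to fix up.
    junctions, endpoints, segments = _canonical_tree(segments)
    if len(segments) < 1:
        raise GeometryError("random tree generation produced no segments")
    return segments, junctions, endpoints


def _seg_dir(seg: np.ndarray) -> np.ndarray:
    d = seg[1] - seg[0]
    return d / np.linalg.norm(d)


def _rotate_zyx(d: np.ndarray, swing: float, tilt: float) -> np.ndarray:
    """Rotate a unit vector by ``swing`` in the y-x plane and ``tilt`` toward z."""
    z, y, x = d
    cs, ss = math.cos(swing), math.sin(swing)
    y2 = y * cs + x * ss
    x2 = -y * ss + x * cs
    ct, st = math.cos(tilt), math.sin(tilt)
    r = math.hypot(y2, x2)
    z2 = z * ct + r * st
    scale = math.sqrt(max(1e-12, 1.0 - z2 * z2)) / max(r, 1e-12)
    out = np.array([z2, y2 * scale, x2 * scale])
    return out / np.linalg.norm(out)


def _canonical_tree(segments: list[np.ndarray]):
    """Merge chains and classify nodes so the tree identity holds exactly.

    Nodes are segment ends; degree-2 nodes (a bifurcation where only one
    child could be placed) are dissolved by merging the two incident
    segments into one polyline.
    """
    def key(p):
        return tuple(np.round(p, 6))

    incident: dict[tuple, list[int]] = {}
    for i, s in enumerate(segments):
        for p in (s[0], s[-1]):
            incident.setdefault(key(p), []).append(i)

    # dissolve degree-2 nodes by merging
    merged = [np.asarray(s, float) for s in segments]
    changed = True
    while changed:
        changed = False
        incident = {}
        for i, s in enumerate(merged):
            if s is None:
                continue
            for p in (s[0], s[-1]):
                incident.setdefault(key(p), []).append(i)
        for node, segs in incident.items():
            if len(segs) == 2 and segs[0] != segs[1]:
                i, j = segs
                a, b = merged[i], merged[j]
                if key(a[-1]) != node:
                    a = a[::-1]
                if key(b[0]) != node:
                    b = b[::-1]
                merged[i] = np.vstack([a, b[1:]])
                merged[j] = None
                changed = True
                break
    merged = [s for s in merged if s is not None]

    incident = {}
    for i, s in enumerate(merged):
        for p in (s[0], s[-1]):
            incident.setdefault(key(p), []).append(i)
    junctions = [np.array(n) for n, segs in incident.items() if len(segs) >= 3]
    endpoints = [np.array(n) for n, segs in incident.items() if len(segs) == 1]
    return junctions, endpoints, merged


def _rasterize_tubes(
    polylines: Sequence[np.ndarray],
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    radius_um: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centre lies within ``radius_um`` of any
    centerline, measured in physical units (correct under anisotropy)."""
    vs = np.array(voxel_size, float)
    mask = np.zeros(grid_shape, dtype=bool)
    for poly in polylines:
        for p0, p1 in zip(poly[:-1], poly[1:]):
            lo_um = np.minimum(p0, p1) - radius_um
            hi_um = np.maximum(p0, p1) + radius_um
            lo_ix = np.maximum(0, np.floor(lo_um / vs - 0.5).astype(int))
            hi_ix = np.minimum(
                np.array(grid_shape), np.ceil(hi_um / vs + 0.5).astype(int) + 1
            )
            if np.any(hi_ix <= lo_ix):
                continue
            axes = [
                (np.arange(lo_ix[a], hi_ix[a]) + 0.5) * vs[a] for a in range(3)
            ]
            zz, yy, xx = np.meshgrid(*axes, indexing="ij")
            pts = np.stack([zz, yy, xx], axis=-1)
            d = _dist_point_segment(pts, p0, p1)
            sub = d <= radius_um
            mask[
                lo_ix[0]:hi_ix[0], lo_ix[1]:hi_ix[1], lo_ix[2]:hi_ix[2]
            ] |= sub
    return mask


def _dist_point_segment(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray):
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0.0:
        return np.linalg.norm(pts - p0, axis=-1)
    t = np.clip(((pts - p0) @ v) / vv, 0.0, 1.0)
    proj = p0 + t[..., None] * v
    return np.linalg.norm(pts - proj, axis=-1)


def generate_vessel_phantom(
    spec: VesselPhantomSpec,
) -> tuple[ImageStack, PhantomGroundTruth]:
    """Rasterize a tube network around known centerlines, blur, and noise it.

    Returns the intensity stack and the ground truth (centerlines, counts,
    lengths, and the noise-free tube mask).
    """
    rng = np.random.default_rng(spec.rng_seed)
    polylines, junctions, endpoints = _build_centerlines(spec, rng)
    mask = _rasterize_tubes(
        polylines, spec.grid_shape, spec.voxel_size, spec.tube_radius_um
    )
    img = np.where(mask, spec.foreground, spec.background).astype(np.float64)
    if spec.psf_sigma_um > 0:
        sigma_vox = [spec.psf_sigma_um / v for v in spec.voxel_size]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    lengths = [_polyline_length(p) for p in polylines]
    gt = PhantomGroundTruth(
        polylines=list(polylines),
        total_length_um=float(sum(lengths)),
        n_segments=len(polylines),
        n_junctions=len(junctions),
        n_endpoints=len(endpoints),
        segment_lengths_um=lengths,
        clean_mask=mask,
    )
    gt.check_invariants()
    stack = ImageStack(img, spec.voxel_size, channel="phantom")
    return stack, gt


# --------------------------------------------------------------------------
# colocalization phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocPhantomSpec:
    """Two random voxel masks with an exactly controlled overlap fraction."""

    grid_shape: tuple[int, ...] = (20, 100, 100)
    size_a: int = 10_000
    overlap_fraction: float = 0.3
    size_b: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap fraction must lie in [0, 1]")
        if self.size_a <= 0:
            raise ValueError("mask A must contain at least one voxel")


def generate_coloc_phantom(
    spec: ColocPhantomSpec,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Construct masks A, B with |A∩B|/|A| equal to the target up to integer
    rounding of voxel counts; the realized exact fraction is returned."""
    n_total = int(np.prod(spec.grid_shape))
    size_b = spec.size_b if spec.size_b is not None else spec.size_a
    n_shared = int(round(spec.overlap_fraction * spec.size_a))
    n_shared = min(n_shared, size_b)
    if spec.size_a + (size_b - n_shared) > n_total:
        raise GeometryError("grid too small for the requested mask sizes")
    rng = np.random.default_rng(spec.rng_seed)
    perm = rng.permutation(n_total)
    idx_a = perm[: spec.size_a]
    shared = rng.choice(idx_a, size=n_shared, replace=False)
    extra_b = perm[spec.size_a : spec.size_a + (size_b - n_shared)]
    mask_a = np.zeros(n_total, dtype=bool)
    mask_a[idx_a] = True
    mask_b = np.zeros(n_total, dtype=bool)
    mask_b[shared] = True
    mask_b[extra_b] = True
    realized = n_shared / spec.size_a
    return (
        mask_a.reshape(spec.grid_shape),
        mask_b.reshape(spec.grid_shape),
        float(realized),
    )


# --------------------------------------------------------------------------
# spheroid outgrowth phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpheroidPhantomSpec:
    """Radially growing spheroid: a disk core plus rectangular protrusions.

    The true area per day is closed-form: pi r_d^2 + n_protrusions x width x
    protrusion_length_d (protrusions start at the circle edge, so the union
    is exact up to a sub-pixel sliver at the attachment).
    """

    pixel_size_um: float = 2.0
    image_shape: tuple[int, int] = (512, 512)
    days: tuple[int, ...] = (0, 1, 2, 3)
    core_radius_um: tuple[float, ...] = (150.0, 170.0, 195.0, 225.0)
    n_protrusions: int = 8
    protrusion_width_um: float = 14.0
    protrusion_length_per_day_um: float = 40.0
    foreground: float = 40.0
    background: float = 200.0          # brightfield: spheroid darker than bg
    noise_sd: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if list(self.days) != sorted(self.days) or self.days[0] != 0:
            raise ValueError("days must be ascending and start at 0")
        if len(self.core_radius_um) != len(self.days):
            raise ValueError("need one core radius per day")
        if any(r <= 0 for r in self.core_radius_um):
            raise GeometryError("core radii must be positive")


def spheroid_true_area_mm2(spec: SpheroidPhantomSpec, day_index: int) -> float:
    """Closed-form union area (mm²) of core disk plus protrusions."""
    r = spec.core_radius_um[day_index]
    day = spec.days[day_index]
    length = spec.protrusion_length_per_day_um * day
    area_um2 = math.pi * r * r
    if length > 0:
        area_um2 += spec.n_protrusions * spec.protrusion_width_um * length
    return area_um2 / 1e6


def generate_spheroid_series(
    spec: SpheroidPhantomSpec,
) -> tuple[list[ImageStack], list[float]]:
    """Render one image per day; return images and true areas (mm²)."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_shape
    cy, cx = (h / 2.0) * spec.pixel_size_um, (w / 2.0) * spec.pixel_size_um
    ys = (np.arange(h) + 0.5) * spec.pixel_size_um - cy
    xs = (np.arange(w) + 0.5) * spec.pixel_size_um - cx
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    rho = np.hypot(yy, xx)
    if spec.n_protrusions > 0:
        angles = np.linspace(0.0, 2.0 * math.pi, spec.n_protrusions, endpoint=False)
        angles = angles + rng.uniform(0.0, 2.0 * math.pi / spec.n_protrusions)
    else:
        angles = np.empty(0)

    images: list[ImageStack] = []
    truths: list[float] = []
    for di, day in enumerate(spec.days):
        r = spec.core_radius_um[di]
        length = spec.protrusion_length_per_day_um * day
        if r + length > min(cy, cx) - 4 * spec.pixel_size_um:
            raise GeometryError("spheroid outgrows the image")
        inside = rho <= r
        if length > 0:
            for th in angles:
                u = math.cos(th) * xx + math.sin(th) * yy
                v = -math.sin(th) * xx + math.cos(th) * yy
                inside |= (
                    (u >= r)
                    & (u <= r + length)
                    & (np.abs(v) <= spec.protrusion_width_um / 2.0)
                )
        img = np.where(inside, spec.foreground, spec.background).astype(float)
        img = ndimage.gaussian_filter(img, 1.0)
        img += rng.normal(0.0, spec.noise_sd, img.shape)
        images.append(
            ImageStack(
                img,
                (spec.pixel_size_um, spec.pixel_size_um),
                channel=f"day{day}",
            )
        )
        truths.append(spheroid_true_area_mm2(spec, di))
    return images, truths


# --------------------------------------------------------------------------
# dot-blot array membrane phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrayPhantomSpec:
    """Duplicate-spot dot-blot membrane with reference spots.

    ``true_levels`` maps target name -> level on the normalized scale where
    the negative-control spots sit at 0 and the positive-control spots at 1.
    ``gain``/``offset`` model a global affine detector response applied
    after blur and noise, so normalized quantities are exactly invariant
    to them for a fixed seed.
    """

    true_levels: dict[str, float] = field(
        default_factory=lambda: {f"T{i:02d}": lv for i, lv in enumerate(
            [0.0, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 1.0, 0.45, 0.25, 0.7]
        )}
    )
    spot_radius_px: int = 6
    pitch_px: int = 22
    blur_sigma_px: float = 1.0
    noise_sd: float = 2.0
    gain: float = 1.0
    offset: float = 0.0
    neg_base: float = 30.0
    pos_base: float = 210.0
    membrane_background: float = 15.0
    rng_seed: int = 0


def generate_array_membrane(spec: ArrayPhantomSpec):
    """Render a membrane image plus its layout and truth table.

    Targets are laid out in duplicate (two adjacent spots per target, as on
    commercial profiler membranes); one duplicate pair of positive-reference
    spots and one of negative-reference spots are placed on the first row.

    Returns ``(ImageStack, ArrayLayout, truth)`` where ``truth`` maps target
    name to its true level on the normalized scale.
    """
    from .secretome import ArrayLayout, Spot

    targets = list(spec.true_levels)
    n_pairs = len(targets) + 2  # + positive and negative reference pairs
    cols = 8  # spots per row
    pairs_per_row = cols // 2
    rows = int(math.ceil(n_pairs / pairs_per_row))
    h = (rows + 1) * spec.pitch_px
    w = (cols + 1) * spec.pitch_px

    spots: list[Spot] = []
    levels: list[float] = []
    names = ["POS", "NEG"] + targets
    for k, name in enumerate(names):
        r, c = divmod(k, pairs_per_row)
        for dup in (0, 1):
            cyx = (
                (r + 1) * spec.pitch_px,
                (2 * c + dup + 1) * spec.pitch_px,
            )
            spots.append(Spot(target=name, center=cyx))
            if name == "POS":
                levels.append(1.0)
            elif name == "NEG":
                levels.append(0.0)
            else:
                levels.append(float(spec.true_levels[name]))

    rng = np.random.default_rng(spec.rng_seed)
    img = np.full((h, w), spec.membrane_background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for spot, level in zip(spots, levels):
        cy, cx = spot.center
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.spot_radius_px**2
        img[disk] = spec.neg_base + level * (spec.pos_base - spec.neg_base)
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = spec.gain * img + spec.offset

    layout = ArrayLayout(
        spots=spots,
        positive_controls=("POS",),
        negative_controls=("NEG",),
        measure_radius_px=max(1, spec.spot_radius_px - 2),
    )
    stack = ImageStack(img, (1.0, 1.0), channel="membrane")
    return stack, layout, dict(spec.true_levels)


# --------------------------------------------------------------------------
# experiment-configuration arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedingConfig:
    """Co-culture seeding: fixed endothelial density and an endo:stroma ratio."""

    endothelial_density: float = 500_000.0  # cells/mL
    ratio_endo: int = 2
    ratio_stroma: int = 1

    def __post_init__(self) -> None:
        if self.endothelial_density <= 0:
            raise ValueError("endothelial density must be positive")
        if self.ratio_endo <= 0 or self.ratio_stroma <= 0:
            raise ValueError("ratio components must be positive integers")


def stromal_density(config: SeedingConfig) -> float:
    """Stromal cells/mL implied by holding endothelial density fixed.

    A ratio endo:stroma of a:b at endothelial density D gives stromal
    density D * b / a — e.g. 2:1 at 500,000/mL seeds 250,000 stromal
    cells/mL, 1:2 seeds 1,000,000/mL.
    """
    return config.endothelial_density * config.ratio_stroma / config.ratio_endo
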