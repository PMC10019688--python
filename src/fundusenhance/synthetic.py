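"""Procedural generation of fundus-like phantom images.

Real fundus photograph pairs used to train enhancement networks are
clinical data and cannot ship with a package. This module generates
aligned high-quality phantoms that carry the geometric features the
rest of the pipeline depends on: a circular field of view, an
orange-red background, a bright optic disc, a darker macula, and a
dark branching vessel tree with *known* crossing coordinates (the
patch sampler draws training patches around vessel crossings and the
macula). Two independently grown vessel trees are overlaid so that
transversal crossings exist by construction and their coordinates can
be recorded as ground truth.

Everything is deterministic given the seed; no global random state is
touched.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.ndimage
from skimage.draw import line as _draw_line

from .degrade import DegradationSpec, SpecSampler, apply_degradation, default_spec_sampler
from .image import FundusImage, ImagePair

__all__ = [
    "VesselMap",
    "Landmarks",
    "generate_fundus",
    "generate_pair",
    "generate_dataset",
]

_VESSEL_COLOR = np.array([0.45, 0.10, 0.08])


@dataclasses.dataclass
class VesselMap:
    """Ground-truth vessel geometry of a generated phantom.

    ``skeleton`` holds the 1-pixel rasterized centerlines, ``mask`` the
    dilated (width-bearing) vessels, ``crossings`` the recorded
    transversal intersections of the two overlaid trees and
    ``width_profile`` the width (pixels) of every grown branch.
    """

    mask: np.ndarray
    skeleton: np.ndarray
    crossings: list[tuple[int, int]]
    width_profile: list[float]

    def __post_init__(self) -> None:
        if np.any(self.skeleton & ~self.mask):
            raise ValueError("skeleton must be a subset of the vessel mask")


@dataclasses.dataclass
class Landmarks:
    macula_center: tuple[int, int]
    disc_center: tuple[int, int]
    fov_center: tuple[int, int]
    fov_radius: float


def _grow_tree(
    rng: np.random.Generator,
    start: tuple[float, float],
    initial_angles: Sequence[float],
    fov_center: tuple[float, float],
    fov_radius: float,
    size: int,
    width0: float,
    max_depth: int = 4,
) -> list[tuple[list[tuple[float, float]], float]]:
    """Recursive binary branching with random-walk jitter.

    Returns a list of branches, each a polyline with a width. Branches
    stop near the fov rim; children inherit the endpoint with a reduced
    width and an opening angle, so widths decrease toward the periphery.
    """
    branches: list[tuple[list[tuple[float, float]], float]] = []
    stack = [((float(start[0]), float(start[1])), float(a), width0, 0) for a in initial_angles]
    step = size / 55.0
    while stack:
        pos, ang, width, depth = stack.pop()
        curve = rng.uniform(-0.10, 0.10)  # per-branch curvature bias
        pts = [pos]
        for _ in range(int(rng.integers(8, 16))):
            ang += curve + rng.normal(0.0, 0.16)
            pos = (pos[0] + step * np.sin(ang), pos[1] + step * np.cos(ang))
            if np.hypot(pos[0] - fov_center[0], pos[1] - fov_center[1]) > 0.93 * fov_radius:
                break
            pts.append(pos)
        if len(pts) >= 2:
            branches.append((pts, width))
        if width > 1.1 and depth < max_depth and len(pts) >= 3:
            half = rng.uniform(0.25, 0.55)
            for s in (1.0, -1.0):
                stack.append((pts[-1], ang + s * half, width * rng.uniform(0.62, 0.85), depth + 1))
    return branches


def _rasterize(branches, shape) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    H, W = shape
    for pts, _w in branches:
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = _draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            grid[rr[keep], cc[keep]] = True
    return grid


def _dilate_by_width(branches, shape) -> np.ndarray:
    """Vessel mask: each branch centerline dilated to its width."""
    mask = np.zeros(shape, dtype=bool)
    by_radius: dict[int, list] = {}
    for pts, w in branches:
        by_radius.setdefault(max(0, int(round(w / 2.0))), []).append((pts, w))
    for radius, group in by_radius.items():
        grid = _rasterize(group, shape)
        if radius > 0:
            yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
            selem = (yy**2 + xx**2) <= radius**2
            grid = scipy.ndimage.binary_dilation(grid, structure=selem)
        mask |= grid
    return mask


def _neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    return scipy.ndimage.convolve(skeleton.astype(np.int32), kernel.astype(np.int32),
                                  mode="constant", cval=0)


def _extract_crossings(grid_a, grid_b, skeleton, exclude, min_sep: int = 5):
    """Transversal intersections of the two trees, snapped to skeleton pixels
    with >= 3 skeleton neighbors (true junctions), deduplicated."""
    overlap = grid_a & grid_b & ~exclude
    nbr = _neighbor_counts(skeleton)
    labels, n = scipy.ndimage.label(overlap, structure=np.ones((3, 3), dtype=int))
    points: list[tuple[int, int]] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        counts = nbr[rows, cols]
        best = int(np.argmax(counts))
        if counts[best] >= 3:
            points.append((int(rows[best]), int(cols[best])))
    points.sort()
    kept: list[tuple[int, int]] = []
    for p in points:
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2 for q in kept):
            kept.append(p)
    return kept


def generate_fundus(seed: int, size: int = 640) -> tuple[FundusImage, VesselMap, Landmarks]:
    """Generate one high-quality fundus phantom.

    Parameters
    ----------
    seed
        Controls all randomness; identical seeds give bit-identical output.
    size
        Side length in pixels, at least 256. The default 640 keeps the
        phantom desk-scale while preserving the landmark geometry of a
        full-resolution acquisition.

    Returns
    -------
    (image, vessels, landmarks)
        The rendered HQ image (black outside the circular fov), the
        ground-truth vessel map with recorded crossings, and the
        macula/disc/fov landmarks.
    """
    if size < 256:
        raise ValueError(f"size must be >= 256 pixels, got {size}")
    rng = np.random.default_rng(seed)
    H = W = int(size)
    center = (H / 2.0, W / 2.0)
    fov_radius = 0.48 * size

    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    rho = np.hypot(rr - center[0], cc - center[1])
    fov_mask = rho <= fov_radius

    side = rng.choice([-1.0, 1.0])  # which eye: disc left or right of center
    disc = (center[0] + rng.normal(0, 0.03) * fov_radius,
            center[1] + side * (0.55 + rng.normal(0, 0.03)) * fov_radius)
    macula = (center[0] + rng.normal(0, 0.04) * fov_radius,
              center[1] - side * (0.10 + abs(rng.normal(0, 0.03))) * fov_radius)

    # --- background: orange-red gradient with vignetting and low-freq texture
    base = np.array([0.72, 0.34, 0.12])
    vignette = 1.0 - 0.35 * (rho / fov_radius) ** 2
    pix = base[None, None, :] * vignette[:, :, None]
    for _ in range(3):  # smooth illumination variation
        fr, fc = rng.uniform(0.5, 1.8, size=2)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        wave = 0.03 * np.cos(2 * np.pi * fr * rr / H + ph[0]) * np.cos(2 * np.pi * fc * cc / W + ph[1])
        pix += wave[:, :, None] * np.array([1.0, 0.6, 0.3])[None, None, :]

    # --- optic disc (bright) and macula (dark)
    d2 = (rr - disc[0]) ** 2 + (cc - disc[1]) ** 2
    disc_blob = np.exp(-d2 / (2 * (0.055 * size) ** 2))
    pix += disc_blob[:, :, None] * np.array([0.25, 0.40, 0.25])[None, None, :]
    m2 = (rr - macula[0]) ** 2 + (cc - macula[1]) ** 2
    mac_blob = np.exp(-m2 / (2 * (0.07 * size) ** 2))
    pix -= mac_blob[:, :, None] * np.array([0.12, 0.14, 0.06])[None, None, :]

    # --- two overlaid vessel trees rooted at the disc
    toward = np.arctan2(center[0] - disc[0], center[1] - disc[1])
    fan = np.array([-1.15, -0.45, 0.45, 1.15])
    width0 = max(2.5, size / 170.0)
    tree_a = _grow_tree(rng, disc, toward + fan, center, fov_radius, size, width0)
    tree_b = _grow_tree(rng, disc, toward + fan + rng.uniform(-0.35, 0.35, size=4),
                        center, fov_radius, size, width0 * 0.85)

    exclude = (d2 <= (0.12 * size) ** 2) | ~fov_mask
    grid_a = _rasterize(tree_a, (H, W))
    grid_b = _rasterize(tree_b, (H, W))
    skeleton = (grid_a | grid_b) & fov_mask
    crossings = _extract_crossings(grid_a, grid_b, skeleton, exclude)

    # grow extra curved branches until enough transversal crossings exist
    attempts = 0
    while len(crossings) < 10 and attempts < 12:
        attempts += 1
        extra = _grow_tree(rng, disc, toward + rng.uniform(-1.3, 1.3, size=2),
                           center, fov_radius, size, width0 * 0.8)
        tree_b.extend(extra)
        grid_b |= _rasterize(extra, (H, W))
        skeleton = (grid_a | grid_b) & fov_mask
        crossings = _extract_crossings(grid_a, grid_b, skeleton, exclude)

    vessel_mask = _dilate_by_width(tree_a + tree_b, (H, W)) & fov_mask
    vessel_mask |= skeleton
    alpha = scipy.ndimage.gaussian_filter(vessel_mask.astype(np.float64), 0.7)
    alpha = np.clip(alpha, 0.0, 1.0) * 0.85
    pix = pix * (1.0 - alpha[:, :, None]) + _VESSEL_COLOR[None, None, :] * alpha[:, :, None]

    # --- mild sensor noise, smoothed so it reads as texture not salt
    noise = rng.normal(0.0, 0.02, size=(H, W))
    pix += scipy.ndimage.gaussian_filter(noise, 1.2)[:, :, None]

    pix = np.clip(pix, 0.0, 1.0) * fov_mask[:, :, None]

    image = FundusImage(pix, fov_mask, meta={"seed": int(seed), "size": int(size),
                                             "kind": "synthetic_hq"})
    vessels = VesselMap(mask=vessel_mask, skeleton=skeleton, crossings=crossings,
                        width_profile=[w for _, w in tree_a + tree_b])
    landmarks = Landmarks(
        macula_center=(int(round(macula[0])), int(round(macula[1]))),
        disc_center=(int(round(disc[0])), int(round(disc[1]))),
        fov_center=(int(round(center[0])), int(round(center[1]))),
        fov_radius=float(fov_radius),
    )
    return image, vessels, landmarks


def generate_pair(
    seed: int,
    spec: DegradationSpec | Sequence[DegradationSpec],
    size: int = 640,
) -> tuple[ImagePair, VesselMap, Landmarks]:
    """Generate an aligned (LQ, HQ) phantom pair.

    ``spec`` may be a single degradation or a sequence applied in order
    (e.g. gamma darkening followed by blur). The LQ image is re-masked
    to the fov afterwards, since the camera aperture bounds any real
    acquisition. Pairs are pixel-aligned by construction.
    """
    hq, vessels, landmarks = generate_fundus(seed, size)
    specs = [spec] if isinstance(spec, DegradationSpec) else list(spec)
    lq = hq
    for s in specs:
        if s.kind == "identity":
            continue
        lq = apply_degradation(lq, s)
    pix = lq.pixels * hq.fov_mask[:, :, None]
    lq = FundusImage(pix, hq.fov_mask.copy(),
                     meta={**lq.meta, "specs": [s.to_record() for s in specs],
                           "seed": int(seed), "kind": "synthetic_lq"})
    return ImagePair(lq=lq, hq=hq), vessels, landmarks


def generate_dataset(
    n: int,
    seed: int,
    spec_sampler: SpecSampler = default_spec_sampler,
    size: int = 640,
) -> list[tuple[ImagePair, VesselMap, Landmarks]]:
    """Generate ``n`` independent phantom pairs, reproducible from ``seed``.

    The degradation of each pair is drawn from ``spec_sampler``; the
    drawn parameters are logged in each LQ image's metadata.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pair_seed = int(master.integers(0, 2**31 - 1))
        specs = spec_sampler(master)
        out.append(generate_pair(pair_seed, specs, size=size))
    return out
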