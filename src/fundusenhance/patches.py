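"""Patch sampling for training and non-overlapping tiling for inference.

Training patches are drawn around the macula (where detailed vision is
graded), around vessel crossings (high-frequency structure the network
must preserve), and uniformly over the field of view. Whole-image
inference covers the image with a non-overlapping grid of tiles,
reflection-padding up to the next multiple of the tile size, and the
layout record makes the tiling exactly invertible.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .image import FundusImage, ImagePair
from .synthetic import Landmarks, VesselMap

__all__ = [
    "PatchSpec",
    "PatchPair",
    "Tile",
    "TileLayout",
    "sample_training_patches",
    "detect_crossings",
    "tile",
    "untile",
]


@dataclasses.dataclass(frozen=True)
class PatchSpec:
    """How many patches of each kind to draw, and at what size.

    Defaults follow the training protocol: 320x320 patches, 5 around
    the macula, 10 around vessel crossings, 5 at random. The jitter
    radius operationalizes "around the macula" as a uniform center
    offset (default one tenth of the patch side).
    """

    patch_size: int = 320
    n_macula: int = 5
    n_crossing: int = 10
    n_random: int = 5
    jitter_radius: int | None = None

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")
        if min(self.n_macula, self.n_crossing, self.n_random) < 0:
            raise ValueError("patch counts must be >= 0")

    @property
    def jitter(self) -> int:
        return self.patch_size // 10 if self.jitter_radius is None else self.jitter_radius


@dataclasses.dataclass
class PatchPair:
    """An aligned LQ/HQ patch cut from identical coordinates."""

    lq_patch: np.ndarray
    hq_patch: np.ndarray
    origin: tuple[int, int]
    source_kind: str


@dataclasses.dataclass
class Tile:
    """One tile of a non-overlapping cover, tagged with its grid origin
    (top-left corner in the padded image) so reassembly can be checked."""

    pixels: np.ndarray
    origin: tuple[int, int]

    def with_pixels(self, pixels: np.ndarray) -> "Tile":
        return Tile(pixels, self.origin)


@dataclasses.dataclass(frozen=True)
class TileLayout:
    original_shape: tuple[int, int]
    padded_shape: tuple[int, int]
    patch_size: int
    grid: tuple[int, int]


def _clip_origin(center: tuple[float, float], patch: int, H: int, W: int) -> tuple[int, int]:
    r = int(round(center[0])) - patch // 2
    c = int(round(center[1])) - patch // 2
    return min(max(r, 0), H - patch), min(max(c, 0), W - patch)


def sample_training_patches(
    pair: ImagePair,
    landmarks: Landmarks,
    crossings: list[tuple[int, int]],
    spec: PatchSpec = PatchSpec(),
    seed: int = 0,
) -> list[PatchPair]:
    """Draw macula / crossing / random patch pairs from an aligned pair.

    Crossings are sampled without replacement while enough remain, then
    with replacement; if none are available the crossing quota falls
    back to random centers (with a warning). Patch origins are clipped
    so every patch lies fully inside the image. Deterministic per seed.
    """
    H, W, _ = pair.hq.pixels.shape
    p = spec.patch_size
    if p > H or p > W:
        raise ValueError(f"patch_size {p} exceeds image size {(H, W)}")
    rng = np.random.default_rng(seed)
    fov = pair.hq.fov_mask
    out: list[PatchPair] = []

    def cut(center, kind):
        r, c = _clip_origin(center, p, H, W)
        out.append(PatchPair(
            lq_patch=pair.lq.pixels[r:r + p, c:c + p].copy(),
            hq_patch=pair.hq.pixels[r:r + p, c:c + p].copy(),
            origin=(r, c), source_kind=kind))

    for _ in range(spec.n_macula):
        jr, jc = rng.uniform(-spec.jitter, spec.jitter, size=2)
        cut((landmarks.macula_center[0] + jr, landmarks.macula_center[1] + jc), "macula")

    n_cross = spec.n_crossing
    if n_cross > 0 and not crossings:
        warnings.warn("no vessel crossings available; falling back to random centers")
        n_random_extra = n_cross
        n_cross = 0
    else:
        n_random_extra = 0
    if n_cross > 0:
        idx = np.arange(len(crossings))
        if len(crossings) >= n_cross:
            chosen = rng.choice(idx, size=n_cross, replace=False)
        else:
            chosen = rng.choice(idx, size=n_cross, replace=True)
        for i in chosen:
            cut(crossings[int(i)], "crossing")

    if fov is not None:
        rows, cols = np.nonzero(fov)
    for _ in range(spec.n_random + n_random_extra):
        if fov is not None and len(rows):
            j = int(rng.integers(0, len(rows)))
            center = (float(rows[j]), float(cols[j]))
        else:
            center = (float(rng.uniform(0, H)), float(rng.uniform(0, W)))
        cut(center, "random")
    return out


def detect_crossings(vessels: VesselMap, min_sep: int = 3) -> list[tuple[int, int]]:
    """Junction pixels of a vessel skeleton.

    A skeleton pixel whose 8-neighborhood contains at least 3 skeleton
    pixels is a branch/crossing candidate; candidates are deduplicated
    within ``min_sep`` pixels. Returns an empty list for an empty
    skeleton. Intended for real images lacking generator ground truth.
    """
    skel = vessels.skeleton
    if not skel.any():
        return []
    padded = np.pad(skel, 1)
    counts = np.zeros(skel.shape, dtype=int)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            counts += padded[1 + dr:1 + dr + skel.shape[0], 1 + dc:1 + dc + skel.shape[1]]
    rows, cols = np.nonzero(skel & (counts >= 3))
    order = np.argsort(-counts[rows, cols], kind="stable")  # strongest junctions first
    kept: list[tuple[int, int]] = []
    for i in order:
        p = (int(rows[i]), int(cols[i]))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2 for q in kept):
            kept.append(p)
    return kept


def tile(image: FundusImage | np.ndarray, patch_size: int) -> tuple[list[Tile], TileLayout]:
    """Cover an image with a non-overlapping grid of ``patch_size`` tiles.

    Images whose sides are not multiples of the tile size are
    reflection-padded up to the next multiple; the layout records the
    original size so :func:`untile` can crop back exactly.
    """
    pix = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    H, W = pix.shape[:2]
    gh = -(-H // patch_size)
    gw = -(-W // patch_size)
    ph, pw = gh * patch_size, gw * patch_size
    if (ph, pw) != (H, W):
        pad = [(0, ph - H), (0, pw - W)] + [(0, 0)] * (pix.ndim - 2)
        pix = np.pad(pix, pad, mode="reflect")
    layout = TileLayout((H, W), (ph, pw), patch_size, (gh, gw))
    tiles = [
        Tile(pix[r * patch_size:(r + 1) * patch_size,
                 c * patch_size:(c + 1) * patch_size].copy(),
             (r * patch_size, c * patch_size))
        for r in range(gh) for c in range(gw)
    ]
    return tiles, layout


def untile(tiles: list[Tile], layout: TileLayout) -> np.ndarray:
    """Exact inverse of :func:`tile` (reassemble, then crop the padding).

    Refuses tile lists that do not match the layout: wrong count, wrong
    tile shape, or tiles out of grid order (e.g. a shuffled list).
    """
    gh, gw = layout.grid
    if len(tiles) != gh * gw:
        raise ValueError(f"expected {gh * gw} tiles, got {len(tiles)}")
    p = layout.patch_size
    out = np.zeros(layout.padded_shape + np.asarray(tiles[0].pixels).shape[2:],
                   dtype=np.asarray(tiles[0].pixels).dtype)
    for k, t in enumerate(tiles):
        r, c = divmod(k, gw)
        if t.origin != (r * p, c * p):
            raise ValueError(
                f"tile {k} has origin {t.origin}, expected {(r * p, c * p)}: "
                "tile list does not match layout")
        pix = np.asarray(t.pixels)
        if pix.shape[:2] != (p, p):
            raise ValueError(f"tile {k} has shape {pix.shape[:2]}, expected {(p, p)}")
        out[r * p:(r + 1) * p, c * p:(c + 1) * p] = pix
    H, W = layout.original_shape
    return out[:H, :W]
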