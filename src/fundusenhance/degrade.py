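"""Parametric degradation models for fundus photographs.

Low-quality fundus images arise from motion blur, media opacity
("haze"), and insufficient illumination. Each of these is simulated
here as a closed-form forward model applied to a high-quality image:

* linear interpolation between an LQ/HQ pair,
  ``L = (H - L0) * lam + L0``, producing intermediate-quality images;
* Gaussian blur, a 2-D convolution with a normalized k x k kernel;
* haze via the atmospheric scattering model
  ``L(x) = H(x) * t(x) + (1 - t(x)) * A`` with transmission
  ``t(x) = exp(-beta * d(x))``, extinction coefficient ``beta``,
  crafted depth map ``d`` and airlight ``A``;
* low illumination via gamma darkening ``L = H ** (1/gamma)`` with
  ``0 < gamma <= 1``;
* exact right-angle rotation (90/180/270 degrees) for augmentation.

All operators map [0, 1] images to [0, 1] images and clip their output.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Callable, Iterable, Sequence

import numpy as np
import scipy.ndimage

from .image import FundusImage, ImagePair

__all__ = [
    "DegradationSpec",
    "DepthMap",
    "AugmentConfig",
    "interpolate",
    "gaussian_blur",
    "gaussian_kernel",
    "transmission",
    "synthesize_haze",
    "gamma_darken",
    "rotate",
    "craft_depth_map",
    "apply_degradation",
    "augment",
    "default_spec_sampler",
    "gamma_blur_sampler",
]

_KINDS = {"identity", "interp", "blur", "haze", "gamma", "rotate"}

# which parameter fields belong to each degradation kind
_KIND_FIELDS = {
    "identity": set(),
    "interp": {"lam"},
    "blur": {"kernel_size", "sigma"},
    "haze": {"beta", "airlight", "depth_family", "depth_params"},
    "gamma": {"gamma"},
    "rotate": {"angle"},
}


@dataclasses.dataclass(frozen=True)
class DegradationSpec:
    """Tagged parameter record for one degradation model.

    Exactly the parameters of the named ``kind`` may be set; the seed
    feeds any internal randomness (e.g. the orientation of an axial
    depth ramp).
    """

    kind: str
    lam: float | None = None
    kernel_size: int | None = None
    sigma: float | None = None
    beta: float | None = None
    airlight: tuple[float, float, float] | None = None
    depth_family: str | None = None
    depth_params: tuple[tuple[str, float], ...] | None = None
    gamma: float | None = None
    angle: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        allowed = _KIND_FIELDS[self.kind]
        for f in ("lam", "kernel_size", "sigma", "beta", "airlight",
                  "depth_family", "depth_params", "gamma", "angle"):
            if getattr(self, f) is not None and f not in allowed:
                raise ValueError(f"field {f!r} is not valid for kind {self.kind!r}")
        if self.kind == "interp" and not (0.0 <= float(self.lam) <= 1.0):
            raise ValueError("lam must lie in [0, 1]")
        if self.kind == "gamma" and not (0.0 < float(self.gamma) <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.kind == "haze" and float(self.beta) < 0:
            raise ValueError("beta must be >= 0")
        if self.kind == "rotate" and int(self.angle) not in (90, 180, 270):
            raise ValueError("angle must be one of 90, 180, 270")

    def to_record(self) -> dict[str, Any]:
        rec: dict[str, Any] = {"kind": self.kind, "seed": self.seed}
        for f in _KIND_FIELDS[self.kind]:
            rec[f] = getattr(self, f)
        return rec


@dataclasses.dataclass
class DepthMap:
    """Nonnegative scene depth in arbitrary units, one value per pixel."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("depth values must be finite and >= 0")


def _as_pixels(img: FundusImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, FundusImage) else np.asarray(img, dtype=np.float64)


def _wrap(template: FundusImage | np.ndarray, pixels: np.ndarray, **meta: Any):
    pixels = np.clip(pixels, 0.0, 1.0)
    if isinstance(template, FundusImage):
        return template.with_pixels(pixels, **meta)
    return pixels


def interpolate(lq, hq, lam: float):
    """Blend an LQ/HQ pair: ``(hq - lq) * lam + lq`` pixel-wise.

    ``lam=0`` returns the LQ image, ``lam=1`` the HQ image; intermediate
    values synthesize intermediate-quality training targets.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    a, b = _as_pixels(lq), _as_pixels(hq)
    if a.shape != b.shape:
        raise ValueError("lq and hq must have the same shape")
    return _wrap(lq, (b - a) * lam + a, degradation="interp", lam=lam)


def gaussian_kernel(kernel_size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel (entries sum to 1)."""
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel_size must be odd and positive")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = kernel_size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def gaussian_blur(img, kernel_size: int = 5, sigma: float = 1.0):
    """Per-channel 2-D convolution with a normalized Gaussian kernel.

    Boundaries are handled by reflection so the fov rim is not darkened.
    """
    k = gaussian_kernel(kernel_size, sigma)
    pix = _as_pixels(img)
    out = np.empty_like(pix)
    for c in range(pix.shape[2]):
        # "mirror" = reflection about the edge pixel (no edge repeat)
        out[:, :, c] = scipy.ndimage.convolve(pix[:, :, c], k, mode="mirror")
    return _wrap(img, out, degradation="blur", kernel_size=kernel_size, sigma=sigma)


def transmission(depth: DepthMap | np.ndarray, beta: float) -> np.ndarray:
    """Transmission map ``t(x) = exp(-beta * d(x))`` in (0, 1]."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    d = depth.values if isinstance(depth, DepthMap) else np.asarray(depth, dtype=np.float64)
    return np.exp(-beta * d)


def synthesize_haze(img, depth: DepthMap | np.ndarray, beta: float,
                    airlight: Sequence[float] = (1.0, 1.0, 1.0)):
    """Atmospheric-scattering haze: ``H*t + (1 - t)*A`` per channel."""
    A = np.asarray(airlight, dtype=np.float64)
    if A.shape != (3,) or A.min() < 0 or A.max() > 1:
        raise ValueError("airlight must be an RGB triple in [0, 1]")
    pix = _as_pixels(img)
    d = depth.values if isinstance(depth, DepthMap) else np.asarray(depth, dtype=np.float64)
    if d.shape != pix.shape[:2]:
        raise ValueError("depth map shape must match image")
    t = transmission(d, beta)[:, :, None]
    out = pix * t + (1.0 - t) * A[None, None, :]
    return _wrap(img, out, degradation="haze", beta=beta, airlight=tuple(A))


def gamma_darken(img, gamma: float):
    """Low-illumination model ``H ** (1/gamma)``; darkens for gamma < 1."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    pix = _as_pixels(img)
    return _wrap(img, np.power(pix, 1.0 / gamma), degradation="gamma", gamma=gamma)


def rotate(img, angle: int):
    """Exact lossless rotation by 90, 180 or 270 degrees (counterclockwise)."""
    if angle not in (90, 180, 270):
        raise ValueError("angle must be one of 90, 180, 270")
    k = angle // 90
    pix = np.rot90(_as_pixels(img), k=k, axes=(0, 1)).copy()
    if isinstance(img, FundusImage):
        mask = None if img.fov_mask is None else np.rot90(img.fov_mask, k=k).copy()
        meta = dict(img.meta)
        meta["rotated"] = angle
        return FundusImage(pix, mask, meta)
    return pix


def craft_depth_map(shape: tuple[int, int], family: str = "radial",
                    params: dict[str, Any] | None = None, seed: int = 0) -> DepthMap:
    """Manually crafted depth maps for haze synthesis.

    families
    --------
    ``constant``
        homogeneous depth ``value`` (default 1.0) -> homogeneous t.
    ``axial_ramp``
        depth rising linearly from 0 at one edge to ``peak`` along a
        random orientation (seeded), imitating one-sided haze.
    ``radial``
        depth ``peak * (rho / radius) ** 2`` rising from the center
        outward, imitating haze concentrated at the image corners.
    """
    params = dict(params or {})
    H, W = shape
    if family == "constant":
        value = float(params.get("value", 1.0))
        if value < 0:
            raise ValueError("constant depth must be >= 0")
        return DepthMap(np.full(shape, value))
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    if family == "axial_ramp":
        peak = float(params.get("peak", 1.0))
        rng = np.random.default_rng(seed)
        theta = float(params.get("theta", rng.uniform(0.0, 2.0 * np.pi)))
        proj = np.cos(theta) * cc + np.sin(theta) * rr
        proj -= proj.min()
        span = proj.max()
        if span > 0:
            proj /= span
        return DepthMap(peak * proj)
    if family == "radial":
        peak = float(params.get("peak", 1.0))
        center = params.get("center", ((H - 1) / 2.0, (W - 1) / 2.0))
        radius = float(params.get("radius", min(H, W) / 2.0))
        rho = np.hypot(rr - center[0], cc - center[1])
        return DepthMap(peak * (rho / radius) ** 2)
    raise ValueError(f"unknown depth family {family!r}")


def apply_degradation(hq: FundusImage, spec: DegradationSpec) -> FundusImage:
    """Apply one degradation spec to an HQ image, producing the LQ image.

    ``interp`` requires a pair and is rejected here; ``rotate`` would
    break LQ/HQ alignment and is likewise rejected (use :func:`augment`).
    """
    if spec.kind == "identity":
        return hq.with_pixels(hq.pixels.copy(), degradation="identity")
    if spec.kind == "blur":
        return gaussian_blur(hq, spec.kernel_size or 5, spec.sigma or 1.0)
    if spec.kind == "gamma":
        return gamma_darken(hq, spec.gamma)
    if spec.kind == "haze":
        depth = craft_depth_map(
            hq.pixels.shape[:2],
            spec.depth_family or "radial",
            dict(spec.depth_params or ()),
            seed=spec.seed,
        )
        return synthesize_haze(hq, depth, spec.beta, spec.airlight or (1.0, 1.0, 1.0))
    raise ValueError(f"degradation kind {spec.kind!r} cannot be applied to a single image")


@dataclasses.dataclass
class AugmentConfig:
    """Which augmentation factors :func:`augment` expands with."""

    rotations: bool = True
    interp_lams: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    blur: bool = True
    haze: bool = True
    gamma: bool = True
    blur_sigma_range: tuple[float, float] = (0.8, 2.0)
    beta_range: tuple[float, float] = (0.5, 2.0)
    airlight_range: tuple[float, float] = (0.7, 1.0)
    gamma_range: tuple[float, float] = (0.4, 0.9)

    @classmethod
    def none(cls) -> "AugmentConfig":
        return cls(rotations=False, interp_lams=(), blur=False, haze=False, gamma=False)


def augment(pairs: Iterable[ImagePair], config: AugmentConfig | None = None,
            seed: int = 0) -> list[ImagePair]:
    """Expand a dataset of aligned pairs with the five augmentation factors.

    For every input pair the output contains the pair itself, its three
    right-angle rotations, interpolated LQs at the configured lambda
    values, and one blur-, haze- and gamma-degraded copy built from the
    HQ image. Every synthetic LQ stays paired with its source HQ and
    carries the generating parameters in its metadata.
    """
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    out: list[ImagePair] = []
    for pair in pairs:
        out.append(pair)
        if config.rotations:
            for angle in (90, 180, 270):
                out.append(ImagePair(rotate(pair.lq, angle), rotate(pair.hq, angle)))
        for lam in config.interp_lams:
            out.append(ImagePair(interpolate(pair.lq, pair.hq, lam), pair.hq))
        if config.blur:
            sigma = float(rng.uniform(*config.blur_sigma_range))
            spec = DegradationSpec(kind="blur", kernel_size=5, sigma=sigma)
            out.append(ImagePair(apply_degradation(pair.hq, spec), pair.hq))
        if config.haze:
            spec = _sample_haze(rng, config)
            out.append(ImagePair(apply_degradation(pair.hq, spec), pair.hq))
        if config.gamma:
            g = float(rng.uniform(*config.gamma_range))
            spec = DegradationSpec(kind="gamma", gamma=g)
            out.append(ImagePair(apply_degradation(pair.hq, spec), pair.hq))
    return out


def _sample_haze(rng: np.random.Generator, config: AugmentConfig) -> DegradationSpec:
    family = rng.choice(["constant", "axial_ramp", "radial"])
    return DegradationSpec(
        kind="haze",
        beta=float(rng.uniform(*config.beta_range)),
        airlight=tuple(rng.uniform(*config.airlight_range, size=3)),
        depth_family=str(family),
        depth_params=(("peak", 1.0),) if family != "constant" else (("value", 1.0),),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def default_spec_sampler(rng: np.random.Generator) -> list[DegradationSpec]:
    """Sample one degradation uniformly over {blur, haze, gamma}.

    Parameter ranges: blur 5x5 kernel with sigma in [0.8, 2.0]; haze
    beta in [0.5, 2.0] with per-channel airlight in [0.7, 1.0] and a
    uniformly chosen depth family; gamma in [0.4, 0.9].
    """
    cfg = AugmentConfig()
    kind = rng.choice(["blur", "haze", "gamma"])
    if kind == "blur":
        return [DegradationSpec(kind="blur", kernel_size=5,
                                sigma=float(rng.uniform(*cfg.blur_sigma_range)))]
    if kind == "haze":
        return [_sample_haze(rng, cfg)]
    return [DegradationSpec(kind="gamma", gamma=float(rng.uniform(*cfg.gamma_range)))]


def gamma_blur_sampler(rng: np.random.Generator) -> list[DegradationSpec]:
    """Gamma darkening (gamma in [0.4, 0.9]) followed by a 5x5 blur."""
    g = float(rng.uniform(0.4, 0.9))
    return [
        DegradationSpec(kind="gamma", gamma=g),
        DegradationSpec(kind="blur", kernel_size=5, sigma=1.0),
    ]


SpecSampler = Callable[[np.random.Generator], list[DegradationSpec]]
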