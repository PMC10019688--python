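"""Core image containers and file I/O.

All processing in this package operates on :class:`FundusImage`: an RGB
float array with intensities in the closed interval [0, 1], an optional
boolean field-of-view (fov) mask marking the circular illuminated region
of the photograph, and a free-form metadata record used for provenance.

Interchange on disk is 8-bit PNG (default) or 16-bit TIFF, always
accompanied by a plain-text key/value sidecar recording provenance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FundusImage",
    "ImagePair",
    "read_image",
    "write_image",
    "read_sidecar",
    "write_sidecar",
]


@dataclasses.dataclass
class FundusImage:
    """An RGB fundus photograph in float [0, 1] with optional fov mask.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` float array, every value in ``[0, 1]``.
    fov_mask
        ``(H, W)`` boolean array, ``True`` inside the circular field of
        view. ``None`` means "whole frame is valid".
    meta
        Free-form provenance record (seed, degradation spec, ...).
    """

    pixels: np.ndarray
    fov_mask: np.ndarray | None = None
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("image sides must be >= 64 pixels")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != self.pixels.shape[:2]:
                raise ValueError("fov_mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self) -> "FundusImage":
        return FundusImage(
            self.pixels.copy(),
            None if self.fov_mask is None else self.fov_mask.copy(),
            dict(self.meta),
        )

    def with_pixels(self, pixels: np.ndarray, **meta: Any) -> "FundusImage":
        """New image with the same mask and merged metadata."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return FundusImage(
            pixels,
            None if self.fov_mask is None else self.fov_mask.copy(),
            new_meta,
        )


@dataclasses.dataclass
class ImagePair:
    """A spatially aligned (low-quality, high-quality) pair.

    The HQ image is the supervision target; the LQ image is its degraded
    counterpart. For synthetic data the pair is pixel-aligned by
    construction.
    """

    lq: FundusImage
    hq: FundusImage

    def __post_init__(self) -> None:
        if self.lq.pixels.shape != self.hq.pixels.shape:
            raise ValueError(
                f"pair shapes differ: {self.lq.pixels.shape} vs {self.hq.pixels.shape}"
            )


def read_image(path: str | Path) -> FundusImage:
    """Read a PNG/TIFF/JPEG file into a float [0, 1] :class:`FundusImage`."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    if raw.dtype == np.uint8:
        pixels = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        pixels = raw.astype(np.float64) / 65535.0
    else:
        pixels = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return FundusImage(pixels, meta={"source": str(path)})


def write_image(img: FundusImage, path: str | Path, bitdepth: int = 8) -> None:
    """Write as 8-bit PNG/JPEG or 16-bit TIFF depending on ``bitdepth``."""
    path = Path(path)
    if bitdepth == 8:
        data = np.round(np.clip(img.pixels, 0, 1) * 255.0).astype(np.uint8)
    elif bitdepth == 16:
        data = np.round(np.clip(img.pixels, 0, 1) * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    iio.imwrite(path, data)


def write_sidecar(path: str | Path, record: Mapping[str, Any]) -> None:
    """Write a flat ``key = value`` provenance sidecar."""
    lines = [f"{k} = {v}" for k, v in record.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
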