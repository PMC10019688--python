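"""Image quality metrics: PSNR, SSIM, and the linear index of fuzziness.

PSNR and SSIM are full-reference metrics computed against an aligned
ground-truth image. The linear index of fuzziness ``r`` is
no-reference: intensities are read as fuzzy memberships and

    r = 2 / (M * N) * sum_ij min(mu_ij, 1 - mu_ij)

measures how far the image sits from a crisp black/white picture; a
lower value indicates a crisper, less noisy image. ``r`` is computed
on the grayscale (luma) image, optionally restricted to the circular
field of view.
"""

from __future__ import annotations

import dataclasses
import io

import numpy as np
import skimage.metrics

from .image import FundusImage

__all__ = ["MetricsReport", "psnr", "ssim", "fuzziness_index", "report"]

PSNR_CAP_DB = 100.0
_LUMA = np.array([0.299, 0.587, 0.114])


def _pix(x) -> np.ndarray:
    return x.pixels if isinstance(x, FundusImage) else np.asarray(x, dtype=np.float64)


def psnr(a, b, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10 * log10(range^2 / MSE)`` in dB.

    Identical images (zero MSE) return the cap value 100 dB; values are
    capped there in general so the metric stays finite.
    """
    pa, pb = _pix(a), _pix(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((pa - pb) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    value = skimage.metrics.peak_signal_noise_ratio(pa, pb, data_range=data_range)
    return min(float(value), PSNR_CAP_DB)


def ssim(a, b, data_range: float = 1.0) -> float:
    """Structural similarity index, the canonical formulation.

    11x11 Gaussian window with sigma 1.5, stability constants
    K1=0.01 and K2=0.03; computed per channel and averaged.
    """
    pa, pb = _pix(a), _pix(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    if min(pa.shape[0], pa.shape[1]) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    channel_axis = 2 if pa.ndim == 3 else None
    return float(skimage.metrics.structural_similarity(
        pa, pb, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, channel_axis=channel_axis))


def fuzziness_index(img, mask: np.ndarray | None = None) -> float:
    """Linear index of fuzziness ``r`` of a [0, 1] image; lower is crisper."""
    pix = _pix(img)  # fov-masked evaluation is opt-in via the mask argument
    mu = pix @ _LUMA if pix.ndim == 3 else pix
    if mask is not None:
        mu = mu[np.asarray(mask, dtype=bool)]
        if mu.size == 0:
            raise ValueError("empty evaluation mask")
    if mu.size == 0:
        raise ValueError("empty image")
    return float(2.0 * np.mean(np.minimum(mu, 1.0 - mu)))


@dataclasses.dataclass
class MetricsReport:
    """Per-image metric values with mean +/- sample standard deviation."""

    per_image: list[tuple[str, float | None, float | None, float]]
    aggregate: dict[str, tuple[float, float]]
    n: int

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("id\tpsnr_db\tssim\tr\n")
        for ident, p, s, r in self.per_image:
            pt = "" if p is None else f"{p:.4f}"
            st = "" if s is None else f"{s:.4f}"
            buf.write(f"{ident}\t{pt}\t{st}\t{r:.4f}\n")
        buf.write("\n")
        for name, (mean, std) in self.aggregate.items():
            buf.write(f"{name}: {mean:.4f} ± {std:.4f} (n={self.n})\n")
        return buf.getvalue()


def _mean_std(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=np.float64)
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), std


def report(items, reference_available: bool = True,
           fov_masked: bool = False) -> MetricsReport:
    """Aggregate metrics over images or (image, reference) pairs.

    ``items`` is a list of ``(id, image)`` when no references exist
    (only ``r`` is computed) or ``(id, image, reference)`` otherwise.
    Aggregates are mean and sample standard deviation.
    """
    items = list(items)
    if not items:
        raise ValueError("need at least one image")
    rows: list[tuple[str, float | None, float | None, float]] = []
    for item in items:
        if reference_available:
            ident, img, ref = item
            p = psnr(img, ref)
            s = ssim(img, ref)
        else:
            ident, img = item[0], item[1]
            p = s = None
        mask = img.fov_mask if (fov_masked and isinstance(img, FundusImage)) else None
        rows.append((str(ident), p, s, fuzziness_index(img, mask)))
    aggregate: dict[str, tuple[float, float]] = {}
    if reference_available:
        aggregate["psnr_db"] = _mean_std([row[1] for row in rows])
        aggregate["ssim"] = _mean_std([row[2] for row in rows])
    aggregate["r"] = _mean_std([row[3] for row in rows])
    return MetricsReport(per_image=rows, aggregate=aggregate, n=len(rows))
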