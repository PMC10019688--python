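"""Retinal fundus image enhancement with an attention-over-operations
encoder-decoder, parametric degradation simulation, and quality metrics."""

from .image import FundusImage, ImagePair, read_image, write_image
from .degrade import (
    AugmentConfig,
    DegradationSpec,
    DepthMap,
    augment,
    craft_depth_map,
    gamma_darken,
    gaussian_blur,
    interpolate,
    rotate,
    synthesize_haze,
    transmission,
)
from .synthetic import Landmarks, VesselMap, generate_dataset, generate_fundus, generate_pair
from .patches import PatchPair, PatchSpec, Tile, detect_crossings, sample_training_patches, tile, untile
from .metrics import MetricsReport, fuzziness_index, psnr, report, ssim

__version__ = "0.1.0"

__all__ = [
    "FundusImage", "ImagePair", "read_image", "write_image",
    "DegradationSpec", "DepthMap", "AugmentConfig",
    "interpolate", "gaussian_blur", "transmission", "synthesize_haze",
    "gamma_darken", "rotate", "craft_depth_map", "augment",
    "generate_fundus", "generate_pair", "generate_dataset", "VesselMap", "Landmarks",
    "PatchSpec", "PatchPair", "Tile", "sample_training_patches", "detect_crossings",
    "tile", "untile",
    "psnr", "ssim", "fuzziness_index", "report", "MetricsReport",
    "FundusEnhancer",
]


def __getattr__(name):  # lazy: the estimator pulls in the nn stack
    if name == "FundusEnhancer":
        from .enhancer import FundusEnhancer
        return FundusEnhancer
    raise AttributeError(name)
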