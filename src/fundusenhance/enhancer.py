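"""Whole-image enhancement and the scikit-learn-style estimator.

:func:`enhance` applies a trained model to an image of arbitrary size
by covering it with non-overlapping tiles of the model's patch size,
running each tile through the network, and reassembling exactly.

:class:`FundusEnhancer` packages the full training pipeline — patch
sampling around landmarks and vessel crossings, minibatch SGD on the
L1 + weight-decay objective — behind a ``fit``/``transform`` estimator
that composes with sklearn tooling.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .image import FundusImage, ImagePair
from .nn import ModelConfig, build_model, no_grad
from .nn.model import AttentionOperationUNet
from .patches import PatchPair, PatchSpec, sample_training_patches, tile, untile
from .synthetic import Landmarks, VesselMap
from .train import LossConfig, TrainConfig, TrainHistory, train

__all__ = ["enhance", "FundusEnhancer"]


def enhance(model: AttentionOperationUNet, image: FundusImage,
            tile_batch: int = 8) -> FundusImage:
    """Enhance a whole image via non-overlapping tiled inference.

    Output has the image's dimensions, intensities clipped to [0, 1];
    deterministic (inference builds no autodiff graph). When the input
    carries a fov mask the exterior is reset to black afterwards — the
    aperture region of a fundus photograph is black by construction and
    carries no signal for the network to restore.
    """
    p = model.config.patch_size
    tiles, layout = tile(image, p)
    dt = model.config.np_dtype
    batch = tile_batch if p <= 128 else 1  # full-scale tiles go one at a time
    outs = []
    with no_grad():
        for i in range(0, len(tiles), batch):
            x = np.stack([t.pixels.transpose(2, 0, 1) for t in tiles[i:i + batch]]).astype(dt)
            y, _ = model.forward(x)
            outs.append(y.data)
    out = np.concatenate(outs).transpose(0, 2, 3, 1).astype(np.float64)
    result = untile([t.with_pixels(out[k]) for k, t in enumerate(tiles)], layout)
    result = np.clip(result, 0.0, 1.0)
    if image.fov_mask is not None:
        result *= image.fov_mask[:, :, None]
    return image.with_pixels(result, enhanced=True)


class FundusEnhancer(BaseEstimator, TransformerMixin):
    """Learnable fundus image enhancer (fit on pairs, transform images).

    Parameters mirror the architecture/training configuration; ``None``
    means "take the preset's value". The default desk_small preset
    (64x64 patches, base width 8, batch 8, 200 iterations) trains in
    minutes on one CPU; the paper_full preset is the full-scale
    architecture (320x320 patches, base width 64).

    Attributes (after fit)
    ----------------------
    model_ : the trained network
    history_ : per-epoch loss history
    n_patches_ : number of training patches sampled
    """

    def __init__(self, preset: str = "desk_small", patch_size: int | None = None,
                 base_channels: int | None = None, n_levels: int = 4,
                 attention_layers: int = 3, batch_size: int | None = None,
                 epochs: int | None = None, iters_per_epoch: int | None = None,
                 learning_rate: float | None = None, lr_decay: float = 0.9,
                 decay_period: int = 100, momentum: float = 0.9,
                 weight_decay: float | None = None, pixel_mean: bool | None = None,
                 n_macula: int = 5, n_crossing: int = 10, n_random: int = 5,
                 seed: int = 0):
        self.preset = preset
        self.patch_size = patch_size
        self.base_channels = base_channels
        self.n_levels = n_levels
        self.attention_layers = attention_layers
        self.batch_size = batch_size
        self.epochs = epochs
        self.iters_per_epoch = iters_per_epoch
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.decay_period = decay_period
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.pixel_mean = pixel_mean
        self.n_macula = n_macula
        self.n_crossing = n_crossing
        self.n_random = n_random
        self.seed = seed

    # -- config resolution ---------------------------------------------
    def _configs(self) -> tuple[ModelConfig, TrainConfig, LossConfig]:
        if self.preset == "desk_small":
            mc, tc, lc = ModelConfig.desk_small(), TrainConfig.desk_small(self.seed), \
                LossConfig.desk_small()
        elif self.preset == "paper_full":
            mc, tc, lc = ModelConfig.paper_full(), TrainConfig(seed=self.seed), LossConfig()
        else:
            raise ValueError(f"unknown preset {self.preset!r}")
        mc = ModelConfig(
            n_levels=self.n_levels,
            base_channels=self.base_channels or mc.base_channels,
            patch_size=self.patch_size or mc.patch_size,
            attention_layers=self.attention_layers,
            dtype=mc.dtype,
        )
        tc = TrainConfig(
            batch_size=self.batch_size or tc.batch_size,
            initial_lr=self.learning_rate if self.learning_rate is not None else tc.initial_lr,
            decay_rate=self.lr_decay, epochs=self.epochs or tc.epochs,
            iters_per_epoch=self.iters_per_epoch or tc.iters_per_epoch,
            decay_period=self.decay_period, momentum=self.momentum,
            clip_grad_norm=tc.clip_grad_norm, seed=self.seed)
        lc = LossConfig(
            weight_decay_lambda=self.weight_decay if self.weight_decay is not None
            else lc.weight_decay_lambda,
            pixel_mean=lc.pixel_mean if self.pixel_mean is None else self.pixel_mean)
        return mc, tc, lc

    # -- estimator API --------------------------------------------------
    def fit(self, X: Sequence, y=None) -> "FundusEnhancer":
        """Fit on aligned pairs.

        ``X`` is a list of ``ImagePair``, of ``(ImagePair, VesselMap,
        Landmarks)`` tuples (as produced by the synthetic generator; the
        landmark-aware patch sampler is then used), or of
        ``PatchPair`` (pre-sampled patches used as-is).
        """
        mc, tc, lc = self._configs()
        patch_pairs: list[PatchPair] = []
        spec = PatchSpec(patch_size=mc.patch_size, n_macula=self.n_macula,
                         n_crossing=self.n_crossing, n_random=self.n_random)
        rng = np.random.default_rng(self.seed)
        for item in X:
            if isinstance(item, PatchPair):
                patch_pairs.append(item)
            elif isinstance(item, ImagePair):
                blank = Landmarks((0, 0), (1, 1), (0, 0), 0.0)
                flat = PatchSpec(patch_size=mc.patch_size, n_macula=0, n_crossing=0,
                                 n_random=self.n_macula + self.n_crossing + self.n_random)
                patch_pairs.extend(sample_training_patches(
                    item, blank, [], flat, seed=int(rng.integers(2**31 - 1))))
            else:
                pair, vessels, landmarks = item
                patch_pairs.extend(sample_training_patches(
                    pair, landmarks, vessels.crossings, spec,
                    seed=int(rng.integers(2**31 - 1))))
        model = build_model(mc, seed=self.seed)
        self.model_, self.history_ = train(patch_pairs, model, tc, lc)
        self.n_patches_ = len(patch_pairs)
        return self

    def transform(self, X: Sequence[FundusImage]) -> list[FundusImage]:
        """Enhance a list of images with the fitted model."""
        if not hasattr(self, "model_"):
            raise RuntimeError("FundusEnhancer is not fitted; call fit first")
        return [enhance(self.model_, img) for img in X]
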