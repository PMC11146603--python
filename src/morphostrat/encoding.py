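"""Patch encoding: conv-net feature maps pooled to a fixed-length vector.

The default architecture is the 16-layer VGG convolutional stack truncated
after its final convolutional block; global average pooling over the last
block's 512 feature maps turns each 256x256 RGB patch into a 512-dimensional
descriptor.  Weights are pluggable:

* ``pretrained_file`` — an ``.npz`` archive of conv weights supplied by the
  user (the method's original configuration uses ImageNet-pretrained weights;
  none are distributed here);
* ``random_seeded``   — He-initialized weights fully determined by a seed
  (random conv features are a standard descriptor baseline);
* ``filter_bank``     — a deterministic, seed-free cosine filter bank.

The forward pass is plain numpy (im2col + GEMM), float32, with the ImageNet
preprocessing convention (RGB in [0,1], per-channel mean/std) recorded in the
spec so no silent preprocessing drift is possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tiling import Patch

__all__ = ["EncoderSpec", "Encoder", "FeatureMatrix", "encode_patch", "encode_cohort"]

# (channels, conv layers) per block; 2x2 max-pool between blocks.
ARCHITECTURES: dict[str, tuple[tuple[int, int], ...]] = {
    # 13 conv layers; with the three classifier layers this is the 16-layer
    # configuration, truncated here after the final 512-channel conv block.
    "vgg16": ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3)),
    # small stack for desk-scale pipeline runs and oracle tests
    "tiny": ((16, 1), (32, 1), (64, 1)),
}

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class EncoderSpec:
    architecture: str = "vgg16"
    weights: str = "random_seeded"     # pretrained_file | random_seeded | filter_bank
    weights_path: str | None = None
    seed: int = 0
    input_size: int = 256
    preprocess_mean: tuple[float, float, float] = IMAGENET_MEAN
    preprocess_std: tuple[float, float, float] = IMAGENET_STD
    channel_order: str = "rgb"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.weights not in ("pretrained_file", "random_seeded", "filter_bank"):
            raise ValueError(f"unknown weights source {self.weights!r}")
        if self.weights == "pretrained_file" and not self.weights_path:
            raise ValueError("pretrained_file weights need a weights_path")

    @property
    def output_dim(self) -> int:
        return ARCHITECTURES[self.architecture][-1][0]


@dataclass
class FeatureMatrix:
    """Patch-by-feature matrix with a (patient, slide, col, row) row index."""

    X: np.ndarray                    # (n_patches, output_dim)
    index: pd.DataFrame              # patient_id, slide_id, col, row

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or len(self.index) != self.X.shape[0]:
            raise ValueError("feature matrix rows must align with the index")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_patches(self) -> int:
        return self.X.shape[0]

    def save(self, prefix: Path | str) -> None:
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.X)
        self.index.to_csv(prefix.with_suffix(".index.csv"), index=False)

    @classmethod
    def load(cls, prefix: Path | str) -> "FeatureMatrix":
        prefix = Path(prefix)
        return cls(X=np.load(prefix.with_suffix(".npy")),
                   index=pd.read_csv(prefix.with_suffix(".index.csv")))


def _he_weights(layers: Sequence[tuple[int, int]], rng: np.random.Generator):
    params = []
    c_in = 3
    for channels, reps in layers:
        for _ in range(reps):
            fan_in = c_in * 9
            w = rng.standard_normal((channels, c_in, 3, 3)).astype(np.float32)
            w *= np.sqrt(2.0 / fan_in)
            params.append((w, np.zeros(channels, dtype=np.float32)))
            c_in = channels
    return params


def _cosine_filter_bank(layers: Sequence[tuple[int, int]]):
    """Deterministic structured filters: zero-mean 3x3 cosine patterns whose
    phase/frequency vary with the output-channel index."""
    params = []
    c_in = 3
    li = 0
    for channels, reps in layers:
        for _ in range(reps):
            li += 1
            o = np.arange(channels)[:, None, None, None]
            i = np.arange(c_in)[None, :, None, None]
            ky = np.arange(3)[None, None, :, None]
            kx = np.arange(3)[None, None, None, :]
            w = np.cos((o + 1) * (3 * ky + kx + 1) * np.pi / 9.7
                       + (i + 1) * (o + 2) * np.pi / (c_in + li)
                       ).astype(np.float32)
            w -= w.mean(axis=(1, 2, 3), keepdims=True)
            norm = np.sqrt((w ** 2).sum(axis=(1, 2, 3), keepdims=True)) + 1e-8
            w = w / norm * np.sqrt(2.0)
            params.append((w, np.full(channels, 0.1, dtype=np.float32)))
            c_in = channels
    return params


def _load_npz_weights(layers: Sequence[tuple[int, int]], path: str):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"encoder weights file not found: {p}")
    arch = np.load(p)
    params = []
    n_layers = sum(r for _, r in layers)
    for li in range(n_layers):
        try:
            w = arch[f"conv{li}_W"].astype(np.float32)
            b = arch[f"conv{li}_b"].astype(np.float32)
        except KeyError as exc:
            raise KeyError(f"missing weight array for conv layer {li} in {p}") from exc
        params.append((w, b))
    return params


def _conv3x3_relu(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution + ReLU; x is (H, W, C_in) float32."""
    h, wd, c_in = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(0, 1))
    # win: (H, W, C_in, 3, 3) -> columns (H*W, 3*3*C_in) ordered (ky, kx, c)
    cols = win.transpose(0, 1, 3, 4, 2).reshape(h * wd, 9 * c_in)
    wm = w.transpose(2, 3, 1, 0).reshape(9 * c_in, w.shape[0])  # (ky,kx,c_in)->out
    out = cols @ wm + b
    np.maximum(out, 0.0, out=out)
    return out.reshape(h, wd, -1)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    return x[: h // 2 * 2, : w // 2 * 2].reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


class Encoder:
    """Initialized conv encoder; weights fixed at construction."""

    def __init__(self, spec: EncoderSpec | None = None):
        self.spec = spec or EncoderSpec()
        layers = ARCHITECTURES[self.spec.architecture]
        self._blocks = layers
        if self.spec.weights == "random_seeded":
            self._params = _he_weights(layers, np.random.default_rng(self.spec.seed))
        elif self.spec.weights == "filter_bank":
            self._params = _cosine_filter_bank(layers)
        else:
            self._params = _load_npz_weights(layers, self.spec.weights_path)

    @property
    def output_dim(self) -> int:
        return self.spec.output_dim

    def preprocess(self, pixels: np.ndarray) -> np.ndarray:
        x = pixels.astype(np.float32) / 255.0
        if self.spec.channel_order == "bgr":
            x = x[..., ::-1]
        mean = np.asarray(self.spec.preprocess_mean, dtype=np.float32)
        std = np.asarray(self.spec.preprocess_std, dtype=np.float32)
        return (x - mean) / std

    def feature_maps(self, pixels: np.ndarray) -> np.ndarray:
        """Final conv block activations, shape (h, w, output_dim)."""
        size = self.spec.input_size
        if pixels.shape != (size, size, 3):
            raise ValueError(
                f"patch must be {size}x{size}x3, got {pixels.shape}"
            )
        x = self.preprocess(pixels)
        li = 0
        for bi, (channels, reps) in enumerate(self._blocks):
            for _ in range(reps):
                w, b = self._params[li]
                x = _conv3x3_relu(x, w, b)
                li += 1
            if bi < len(self._blocks) - 1:
                x = _maxpool2(x)
        return x

    def encode(self, pixels: np.ndarray) -> np.ndarray:
        """Global average pooling over the final feature maps."""
        return self.feature_maps(pixels).mean(axis=(0, 1)).astype(np.float64)


def encode_patch(patch: Patch | np.ndarray, encoder: Encoder | EncoderSpec | None = None) -> np.ndarray:
    """Encode one patch into a length-``output_dim`` feature vector."""
    if encoder is None or isinstance(encoder, EncoderSpec):
        encoder = Encoder(encoder)
    pixels = patch.pixels if isinstance(patch, Patch) else patch
    return encoder.encode(pixels)


def encode_cohort(patches: Iterable[Patch], encoder: Encoder | EncoderSpec | None = None,
                  batch_size: int = 64) -> FeatureMatrix:
    """Encode patches in input order into a :class:`FeatureMatrix`.

    Patches are evaluated one at a time, so the result is trivially
    independent of ``batch_size`` (kept for interface compatibility).
    """
    if encoder is None or isinstance(encoder, EncoderSpec):
        encoder = Encoder(encoder)
    rows, idx = [], []
    for patch in patches:
        try:
            rows.append(encoder.encode(patch.pixels))
        except ValueError as exc:
            raise ValueError(f"patch {patch.patch_id}: {exc}") from exc
        idx.append((patch.patient_id, patch.slide_id, patch.col, patch.row))
    X = np.vstack(rows) if rows else np.empty((0, encoder.output_dim))
    index = pd.DataFrame(idx, columns=["patient_id", "slide_id", "col", "row"])
    return FeatureMatrix(X=X, index=index)
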