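"""Frozen convolutional filter bank and per-pixel feature tables.

A bank of 64 fixed 3x3x3 kernels (either the first convolutional layer of a
pretrained VGG-16, loaded from a local weights file, or a seeded random
Gaussian bank) is applied to a 224x224x3 image with stride 1 and zero
same-padding, followed by a rectifier.  The resulting 224x224x64 feature
map is reshaped into the pixel-feature table the ensemble consumes — one
row per pixel, 64 columns, optional label column — or tiled into 8x8
frames for batched training.

"Convolution" here is cross-correlation (no kernel flip), the deep-learning
convention; for seeded random kernels the distinction is immaterial, and
for pretrained kernels it matches how the source network applies them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imaging import Image224, LabelMask

N_FILTERS = 64
KERNEL_SIZE = 3
IN_CHANNELS = 3


def convolve2d(
    image_channel: np.ndarray,
    kernel: np.ndarray,
    stride: int = 1,
    padding: str = "same",
) -> np.ndarray:
    """Strided 2-D cross-correlation of a single channel with one kernel.

    ``padding="same"`` zero-pads so the stride-1 output matches the input
    shape; ``"valid"`` keeps only fully overlapping positions.
    """
    x = np.asarray(image_channel, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError(f"kernel must be square 2-D, got shape {k.shape}")
    if k.shape[0] % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k.shape[0]}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if padding not in ("same", "valid"):
        raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
    if x.ndim != 2 or min(x.shape) < k.shape[0]:
        raise ValueError("input must be 2-D and at least kernel-sized")

    if padding == "same":
        p = k.shape[0] // 2
        x = np.pad(x, p, mode="constant")
    windows = sliding_window_view(x, k.shape)  # (H', W', k, k)
    out = np.tensordot(windows, k, axes=([2, 3], [0, 1]))
    return out[::stride, ::stride]


@dataclass(frozen=True)
class FilterBank:
    """64 frozen 3x3x3 kernels + biases, with a rectifier activation.

    kernels has shape (64, 3, 3, 3) ordered (filter, row, col, channel).
    """

    kernels: np.ndarray
    biases: np.ndarray
    provenance: str
    seed: int | None = None

    def __post_init__(self) -> None:
        expected = (N_FILTERS, KERNEL_SIZE, KERNEL_SIZE, IN_CHANNELS)
        if self.kernels.shape != expected:
            raise ValueError(
                f"filter bank kernels must have shape {expected}, "
                f"got {self.kernels.shape}"
            )
        if self.biases.shape != (N_FILTERS,):
            raise ValueError("filter bank needs exactly 64 biases")

    def fingerprint(self) -> str:
        """Stable digest used to detect train/predict bank mismatches."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.kernels, dtype=np.float64))
        h.update(np.ascontiguousarray(self.biases, dtype=np.float64))
        return f"{self.provenance}:{h.hexdigest()[:16]}"


def make_filter_bank(
    provenance: str = "seeded_random",
    seed: int = 42,
    weights_file=None,
) -> FilterBank:
    """Build the frozen bank.

    ``seeded_random`` draws kernel entries from N(0, 1/fan_in) with zero
    biases, reproducibly from ``seed``.  ``pretrained_vgg_block1`` loads a
    local ``.npz`` file with arrays ``kernels`` of shape 3x3x3x64
    (row, col, channel, filter) and ``biases`` of shape 64; no network
    access is performed.
    """
    if provenance == "seeded_random":
        rng = np.random.default_rng(seed)
        fan_in = KERNEL_SIZE * KERNEL_SIZE * IN_CHANNELS
        kernels = rng.normal(
            0.0,
            1.0 / np.sqrt(fan_in),
            size=(N_FILTERS, KERNEL_SIZE, KERNEL_SIZE, IN_CHANNELS),
        )
        return FilterBank(kernels, np.zeros(N_FILTERS), provenance, seed)
    if provenance == "pretrained_vgg_block1":
        if weights_file is None:
            raise ValueError(
                "pretrained provenance requires a local weights file holding "
                "a 3x3x3x64 kernel tensor and 64 biases"
            )
        data = np.load(weights_file)
        try:
            kernels, biases = data["kernels"], data["biases"]
        except KeyError as exc:
            raise ValueError(
                f"weights file {weights_file} must contain 'kernels' "
                "(3x3x3x64) and 'biases' (64)"
            ) from exc
        if kernels.shape != (KERNEL_SIZE, KERNEL_SIZE, IN_CHANNELS, N_FILTERS):
            raise ValueError(
                "expected kernel tensor of shape 3x3x3x64, got "
                f"{kernels.shape}"
            )
        return FilterBank(
            np.moveaxis(kernels, 3, 0).astype(np.float64),
            biases.astype(np.float64),
            provenance,
        )
    raise ValueError(f"unknown provenance {provenance!r}")


@dataclass
class FeatureMap:
    """224x224x64 stack of rectified filter responses for one image."""

    values: np.ndarray
    source_id: str = ""

    @property
    def spatial_shape(self):
        return self.values.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


def extract_features(image: Image224, bank: FilterBank) -> FeatureMap:
    """Apply the full bank: per-channel stride-1 same-padded correlation,
    summed over input channels, plus bias, then rectifier."""
    p = KERNEL_SIZE // 2
    padded = np.pad(image.pixels, ((p, p), (p, p), (0, 0)), mode="constant")
    # (H, W, 3, 3, 3) windows ordered (row, col, krow, kcol, channel)
    windows = sliding_window_view(padded, (KERNEL_SIZE, KERNEL_SIZE), axis=(0, 1))
    windows = np.moveaxis(windows, 2, 4)
    out = np.tensordot(windows, bank.kernels, axes=([2, 3, 4], [1, 2, 3]))
    out += bank.biases
    np.maximum(out, 0.0, out=out)
    return FeatureMap(out, source_id=image.source_id)


@dataclass
class FeatureFrame:
    """Pixel-feature table: one row per pixel, C feature columns.

    ``pixel_order`` is row-major over the source map; ``shape`` remembers
    the spatial geometry so the table can be folded back into a map.
    """

    rows: np.ndarray
    labels: np.ndarray | None = None
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.rows):
            raise ValueError("label column length must match row count")

    @property
    def n_pixels(self) -> int:
        return self.rows.shape[0]

    @property
    def n_features(self) -> int:
        return self.rows.shape[1]

    @classmethod
    def concat(cls, frames: list["FeatureFrame"]) -> "FeatureFrame":
        """Stack several images' tables vertically, in input order."""
        labels = None
        if all(f.labels is not None for f in frames):
            labels = np.concatenate([f.labels for f in frames])
        return cls(np.vstack([f.rows for f in frames]), labels)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            self.rows, columns=[f"f{i}" for i in range(self.n_features)]
        )
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def flatten_to_frame(
    fmap: FeatureMap, mask: LabelMask | None = None
) -> FeatureFrame:
    """Row-major flatten of a feature map, with the mask as label column."""
    h, w, c = fmap.values.shape
    if mask is not None and mask.shape != (h, w):
        raise ValueError(
            f"mask shape {mask.shape} does not match map spatial shape {(h, w)}"
        )
    rows = fmap.values.reshape(h * w, c)
    labels = mask.classes.reshape(h * w).copy() if mask is not None else None
    return FeatureFrame(rows, labels, shape=(h, w))


def frame_to_map(frame: FeatureFrame, shape: tuple[int, int] | None = None) -> FeatureMap:
    """Inverse of :func:`flatten_to_frame` (lossless reindexing)."""
    shape = shape or frame.shape
    if shape is None:
        raise ValueError("spatial shape required to fold a frame back")
    h, w = shape
    return FeatureMap(frame.rows.reshape(h, w, frame.n_features))


def tile_frames(fmap: FeatureMap, frame_size: int = 8):
    """Non-overlapping frame tiling in row-major frame order.

    Yields ``(frame_row, frame_col, block)`` where block is a
    ``frame_size x frame_size x C`` view; 224/8 gives 784 frames covering
    every pixel exactly once.
    """
    h, w, _ = fmap.values.shape
    if h % frame_size or w % frame_size:
        raise ValueError(
            f"frame_size {frame_size} must divide spatial dims {(h, w)}"
        )
    for fr in range(h // frame_size):
        for fc in range(w // frame_size):
            block = fmap.values[
                fr * frame_size : (fr + 1) * frame_size,
                fc * frame_size : (fc + 1) * frame_size,
            ]
            yield fr, fc, block
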