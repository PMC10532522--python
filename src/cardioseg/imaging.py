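"""Image and label-mask I/O for the segmentation pipeline.

Everything downstream works on a fixed canonical geometry: RGB images of
shape 224x224x3 with intensities in [0, 1], and integer label masks of the
same spatial shape.  Three-class masks use the fixed semantics
0 = background (black), 1 = heart tissue (grey), 2 = enlarged region
(white); two-class masks are {0 = not enlarged, 1 = enlarged}.

Masks travel as grayscale PNGs in the dialect {0, 128, 255} (three-class)
or {0, 255} (two-class), decoded with a +/-32 tolerance band around each
canonical value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize

SIDE = 224

# canonical gray codes per class, three-class dialect
_GRAY3 = np.array([0, 128, 255])
_GRAY2 = np.array([0, 255])
_TOL = 32


class MaskDecodeError(ValueError):
    """A gray value fell outside every class tolerance band."""


class ImageFormatError(ValueError):
    """A file could not be read in the named format."""


@dataclass
class Image224:
    """Canonical pipeline input: 224x224 RGB, intensities in [0, 1]."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (SIDE, SIDE, 3):
            raise ValueError(
                f"Image224 requires shape {(SIDE, SIDE, 3)}, got {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("Image224 intensities must lie in [0, 1]")


@dataclass
class LabelMask:
    """Integer class mask; n_classes is 2 or 3."""

    classes: np.ndarray
    n_classes: int = 3

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise ValueError("LabelMask classes must be integers")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.classes.size and (
            self.classes.min() < 0 or self.classes.max() >= self.n_classes
        ):
            raise ValueError(
                f"mask values must lie in [0, {self.n_classes - 1}]"
            )

    @property
    def shape(self):
        return self.classes.shape


def _infer_modality(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return "dicom"
    if suffix == ".png":
        return "png"
    if suffix in (".jpg", ".jpeg"):
        return "jpeg"
    raise ImageFormatError(f"cannot infer modality from {path}")


def _read_dicom_frame(path: Path) -> np.ndarray:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover - message path
        raise ImageFormatError(f"unreadable DICOM file {path}: {exc}") from exc
    if int(getattr(ds, "NumberOfFrames", 1)) > 1 or arr.ndim > 2:
        raise ImageFormatError(
            f"{path} is a multi-frame DICOM; select a single frame before reading"
        )
    arr = arr.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr


def _read_pil(path: Path, fmt: str) -> np.ndarray:
    try:
        with PILImage.open(path) as im:
            if im.format is not None and im.format.lower() != fmt:
                raise ImageFormatError(
                    f"{path}: expected {fmt}, file is {im.format.lower()}"
                )
            if im.mode in ("RGBA", "P", "LA"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    except ImageFormatError:
        raise
    except Exception as exc:
        raise ImageFormatError(f"unreadable {fmt} file {path}: {exc}") from exc
    arr = arr.astype(np.float64)
    if arr.ndim == 2:
        # scale by the dtype range: 8-bit 255, 16-bit 65535
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    else:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def read_image(
    path, modality: str | None = None, interpolation: str = "bilinear"
) -> Image224:
    """Read a DICOM/PNG/JPEG file into the canonical 224x224x3 form.

    DICOM intensities are mapped through RescaleSlope/Intercept when present
    and then min-max scaled to [0, 1]; PNG/JPEG are scaled by their dtype
    range.  Images are resized with bilinear interpolation by default;
    ``interpolation="nearest"`` preserves exact gray levels.  Grayscale
    sources are replicated across the three channels.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    modality = modality or _infer_modality(path)
    if modality == "dicom":
        arr = _read_dicom_frame(path)
    elif modality in ("png", "jpeg"):
        arr = _read_pil(path, modality)
    else:
        raise ImageFormatError(f"unknown modality {modality!r}")

    order = {"bilinear": 1, "nearest": 0}[interpolation]
    if arr.ndim == 2:
        if arr.shape != (SIDE, SIDE):
            arr = resize(arr, (SIDE, SIDE), order=order, anti_aliasing=False,
                         preserve_range=True)
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    else:
        if arr.shape[:2] != (SIDE, SIDE):
            arr = resize(arr, (SIDE, SIDE, 3), order=order,
                         anti_aliasing=False, preserve_range=True)
    return Image224(np.clip(arr, 0.0, 1.0), source_id=path.stem)


def decode_mask(gray_image: np.ndarray, n_classes: int = 3) -> LabelMask:
    """Decode a grayscale mask image to integer classes.

    Gray values must fall within +/-32 of a canonical code: {0, 128, 255}
    for three classes or {0, 255} for two.
    """
    gray = np.asarray(gray_image)
    if gray.ndim != 2:
        raise ValueError(f"mask image must be 2-D, got shape {gray.shape}")
    codes = _GRAY3 if n_classes == 3 else _GRAY2
    dist = np.abs(gray.astype(np.int64)[:, :, None] - codes[None, None, :])
    nearest = dist.argmin(axis=2)
    bad = dist.min(axis=2) > _TOL
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise MaskDecodeError(
            f"gray value {int(gray[r, c])} at (row={r}, col={c}) is outside "
            f"every +/-{_TOL} band around {codes.tolist()}"
        )
    return LabelMask(nearest.astype(np.int64), n_classes=n_classes)


def encode_mask(mask: LabelMask) -> np.ndarray:
    """Inverse of :func:`decode_mask` on the canonical gray codes."""
    codes = _GRAY3 if mask.n_classes == 3 else _GRAY2
    return codes[mask.classes].astype(np.uint8)


def write_overlay(image: Image224, binary_mask: LabelMask) -> Image224:
    """Paint the enlarged region opaque red on a copy of the image."""
    if binary_mask.n_classes != 2:
        raise ValueError("overlay requires a two-class mask")
    if binary_mask.shape != image.pixels.shape[:2]:
        raise ValueError(
            f"mask shape {binary_mask.shape} does not match image "
            f"{image.pixels.shape[:2]}"
        )
    out = image.pixels.copy()
    hot = binary_mask.classes == 1
    out[hot] = (1.0, 0.0, 0.0)
    return Image224(out, source_id=image.source_id)


def load_mask(path, n_classes: int = 3) -> LabelMask:
    """Read a grayscale mask PNG and decode it."""
    with PILImage.open(path) as im:
        gray = np.asarray(im.convert("L"))
    return decode_mask(gray, n_classes=n_classes)


def save_mask(path, mask: LabelMask) -> None:
    PILImage.fromarray(encode_mask(mask), mode="L").save(path)


def save_image(path, image: Image224) -> None:
    arr = np.round(image.pixels * 255.0).astype(np.uint8)
    PILImage.fromarray(arr, mode="RGB").save(path)
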