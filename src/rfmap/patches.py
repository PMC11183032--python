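"""ROI patch extraction and network-ready channel assembly.

An ROI mask drawn along a lesion contour is turned into (a) the minimum
bounding-box patch and (b) an expanded patch grown by a pixel margin
(default 10) to include peri-lesional tissue, then resized to 224 x 224 and
stacked into three channels: either the grayscale patch broadcast, or
grayscale plus two selected radiomic feature maps.

Coordinates are 0-based, half-open ``[start, end)`` throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .rfm_engine import resize_map

__all__ = [
    "ImagePatch", "RoiMask", "CompositeInput",
    "min_bounding_patch", "expand_patch", "to_three_channel",
    "largest_foreground_slice", "load_image", "read_manifest",
]


@dataclass
class ImagePatch:
    """A cropped 2D intensity grid with provenance back to its parent image."""

    pixels: np.ndarray
    modality: str = "synthetic"
    subject_id: str = ""
    slice_id: int | None = None
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # (r0, c0, r1, c1), half-open
    clipped: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.size == 0:
            raise ValueError("empty patch")
        if not np.isfinite(self.pixels).all():
            raise ValueError("patch contains non-finite values")


@dataclass
class RoiMask:
    """Binary foreground mask congruent with its parent image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mask.any():
            raise ValueError("ROI mask has no foreground pixels")
        _, n = ndimage.label(self.mask)
        if n > 1:
            warnings.warn(f"ROI mask has {n} connected components; expected 1",
                          stacklevel=2)

    def bbox(self) -> tuple[int, int, int, int]:
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


@dataclass
class CompositeInput:
    """3 x H x W network input: (gray, map A, map B) or broadcast gray."""

    channels: np.ndarray
    channel_names: tuple[str, str, str]

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("channels must be 3 x H x W")


def min_bounding_patch(image: np.ndarray, roi: RoiMask, modality: str = "synthetic",
                       subject_id: str = "") -> ImagePatch:
    """Crop the tightest axis-aligned rectangle containing the ROI."""
    image = np.asarray(image, dtype=float)
    if image.shape != roi.mask.shape:
        raise ValueError("image and mask shapes differ")
    r0, c0, r1, c1 = roi.bbox()
    return ImagePatch(image[r0:r1, c0:c1], modality, subject_id,
                      bbox=(r0, c0, r1, c1))


def expand_patch(image: np.ndarray, roi: RoiMask, margin_px: int = 10,
                 modality: str = "synthetic", subject_id: str = "") -> ImagePatch:
    """Grow the ROI bounding box by ``margin_px`` per side, clipped to the image."""
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    image = np.asarray(image, dtype=float)
    if image.shape != roi.mask.shape:
        raise ValueError("image and mask shapes differ")
    r0, c0, r1, c1 = roi.bbox()
    er0, ec0 = r0 - margin_px, c0 - margin_px
    er1, ec1 = r1 + margin_px, c1 + margin_px
    cr0, cc0 = max(er0, 0), max(ec0, 0)
    cr1, cc1 = min(er1, image.shape[0]), min(ec1, image.shape[1])
    clipped = (cr0, cc0, cr1, cc1) != (er0, ec0, er1, ec1)
    return ImagePatch(image[cr0:cr1, cc0:cc1], modality, subject_id,
                      bbox=(cr0, cc0, cr1, cc1), clipped=clipped)


def _normalize(channel: np.ndarray, policy: str) -> np.ndarray:
    if policy == "minmax":
        lo, hi = channel.min(), channel.max()
        if hi <= lo:
            return np.zeros_like(channel)  # constant channel convention
        return (channel - lo) / (hi - lo)
    if policy == "zscore":
        sd = channel.std()
        if sd == 0:
            return np.zeros_like(channel)
        return (channel - channel.mean()) / sd
    raise ValueError(f"unknown normalization {policy!r}")


def to_three_channel(
    gray: np.ndarray,
    extra: tuple[np.ndarray, np.ndarray] | None = None,
    target: tuple[int, int] = (224, 224),
    normalization: str = "minmax",
) -> CompositeInput:
    """Assemble the 3-channel network input.

    Without ``extra`` the grayscale patch is broadcast to three identical
    channels; with ``extra = (map_a, map_b)`` the channels are
    (gray, map_a, map_b).  Each channel is resized to ``target`` and
    normalized per channel (min-max to [0, 1] by default).
    """
    gray = np.asarray(gray, dtype=float)
    if extra is not None:
        a, b = (np.asarray(m, dtype=float) for m in extra)
        if a.shape != gray.shape or b.shape != gray.shape:
            raise ValueError("extra maps must be congruent with gray")
        planes = [gray, a, b]
        names = ("gray", "rfm_a", "rfm_b")
    else:
        planes = [gray, gray, gray]
        names = ("gray", "gray", "gray")
    chans = np.stack([
        _normalize(resize_map(p, target), normalization) for p in planes
    ])
    return CompositeInput(chans, names)


def largest_foreground_slice(mask_volume: np.ndarray) -> int:
    """Index of the axial slice with maximal foreground area (tie: lowest)."""
    areas = np.asarray(mask_volume).astype(bool).sum(axis=(1, 2))
    return int(np.argmax(areas))


def load_image(path: str | Path) -> np.ndarray:
    """Read a 2D image from NIfTI, PNG (8/16-bit) or a numpy archive."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        return np.squeeze(data).astype(float)
    if name.endswith(".png"):
        import imageio.v3 as iio

        return np.asarray(iio.imread(path)).astype(float)
    if name.endswith(".npy"):
        return np.load(path).astype(float)
    if name.endswith(".npz"):
        with np.load(path) as z:
            return z[list(z.files)[0]].astype(float)
    raise ValueError(f"unsupported image format: {path}")


MANIFEST_COLUMNS = ("subject_id", "image_path", "mask_path", "modality", "label")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["label"].unique()) - {"PM", "NM"}
    if bad:
        raise ValueError(f"labels must be PM or NM, got {sorted(bad)}")
    return df
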