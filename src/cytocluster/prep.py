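"""Image preprocessing: 8-bit conversion, thresholding, and cluster labeling.

Field images of liquid-based cytology slides arrive as RGB or grayscale
arrays of arbitrary bit depth.  The morphometry stage operates on binary
masks, so this module mirrors the standard particle-analysis workflow:
convert to 8-bit grayscale, threshold to binary, and label connected
cell clusters.

The thresholding method is configurable because published workflows
rarely state it; the default is the iterative intermeans ("isodata")
algorithm, the default of the common interactive analysis tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label

__all__ = [
    "FieldImage",
    "BinarizeResult",
    "to_gray8",
    "isodata_threshold",
    "binarize",
    "label_clusters",
]

# Rec. 601 luma weights for RGB -> grayscale conversion.
_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class FieldImage:
    """One microscope field: 8-bit pixels plus an optional binary mask.

    Attributes
    ----------
    pixels : uint8 array, shape (H, W)
    field_index : int
        Position index 1..5 (top, bottom, left, right, center).
    specimen_id : str
    mask : bool array or None
        Foreground (cluster) mask, same shape as ``pixels``.
    """

    pixels: np.ndarray
    field_index: int
    specimen_id: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("FieldImage.pixels must be uint8")
        if not 1 <= self.field_index <= 5:
            raise ValueError("field_index must be in 1..5")
        if self.mask is not None and self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must match pixels")


def to_gray8(image: np.ndarray) -> np.ndarray:
    """Convert an image to 8-bit grayscale.

    RGB(A) input is reduced with Rec. 601 luminance weights; integer
    inputs of higher bit depth are rescaled linearly to [0, 255]; float
    input is assumed to lie in [0, 1].  Rounding is half away from zero.
    Already-8-bit grayscale input is returned unchanged.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        if image.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count {image.shape[2]}")
        rgb = image[..., :3].astype(np.float64)
        if np.issubdtype(image.dtype, np.integer) and image.dtype != np.uint8:
            rgb = rgb * (255.0 / np.iinfo(image.dtype).max)
        elif np.issubdtype(image.dtype, np.floating):
            rgb = rgb * 255.0
        gray = rgb @ _REC601
        return _round_u8(gray)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale or 3-D RGB image")
    if image.dtype == np.uint8:
        return image
    if np.issubdtype(image.dtype, np.integer):
        scaled = image.astype(np.float64) * (255.0 / np.iinfo(image.dtype).max)
        return _round_u8(scaled)
    if np.issubdtype(image.dtype, np.floating):
        return _round_u8(np.clip(image, 0.0, 1.0) * 255.0)
    raise ValueError(f"unsupported dtype {image.dtype}")


def _round_u8(x: np.ndarray) -> np.ndarray:
    # round half away from zero, matching common imaging conventions
    return np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8)


def isodata_threshold(gray: np.ndarray) -> int:
    """Iterative intermeans (isodata) threshold of an 8-bit image.

    Starting from the mid-point of the occupied intensity range, iterate
    t <- round((mean below or at t + mean above t) / 2) until it is a
    fixed point.  Pixels <= t form one side, > t the other.
    """
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    lo, hi = np.flatnonzero(hist)[[0, -1]]
    if lo == hi:
        raise ValueError("constant image has no isodata threshold")
    t = int((lo + hi) // 2)
    for _ in range(256):
        w_low = hist[: t + 1].sum()
        w_high = hist[t + 1 :].sum()
        if w_low == 0 or w_high == 0:
            t += 1 if w_low == 0 else -1
            continue
        m_low = (hist[: t + 1] * levels[: t + 1]).sum() / w_low
        m_high = (hist[t + 1 :] * levels[t + 1 :]).sum() / w_high
        t_new = int(np.floor((m_low + m_high) / 2.0 + 0.5))
        if t_new == t:
            return t
        t = t_new
    return t


@dataclass
class BinarizeResult:
    """Binary mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    method: str
    polarity: str
    degenerate: bool = False


def binarize(
    gray: np.ndarray,
    method: str = "isodata",
    polarity: Literal["dark_foreground", "light_foreground"] = "dark_foreground",
    min_contrast: float = 30.0,
) -> BinarizeResult:
    """Threshold an 8-bit grayscale image to a binary cluster mask.

    Parameters
    ----------
    gray : uint8 array
    method : "isodata", "otsu", or "fixed:<t>" for an explicit threshold.
    polarity : which side of the threshold is foreground.  Papanicolaou-
        stained clusters imaged in brightfield are dark on a light
        background, hence the default.
    min_contrast : minimum separation (gray levels) between the mean
        intensities on the two sides of a data-driven threshold.  A
        field containing no objects is just sensor noise around the
        background level; splitting it would turn half the pixels into
        spurious foreground, so such images are flagged degenerate and
        returned all-background.  Set to 0 to disable.

    A constant image likewise has no data-driven threshold and yields an
    all-background mask with ``degenerate=True``.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    if gray.dtype != np.uint8:
        raise ValueError("binarize expects uint8 input; use to_gray8 first")
    if polarity not in ("dark_foreground", "light_foreground"):
        raise ValueError(f"unknown polarity {polarity!r}")

    degenerate = False
    if method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
    elif gray.min() == gray.max():
        if method not in ("isodata", "otsu"):
            raise ValueError(f"unknown method {method!r}")
        return BinarizeResult(
            mask=np.zeros(gray.shape, bool),
            threshold=float("nan"),
            method=method,
            polarity=polarity,
            degenerate=True,
        )
    elif method == "isodata":
        t = float(isodata_threshold(gray))
    elif method == "otsu":
        t = float(threshold_otsu(gray))
    else:
        raise ValueError(f"unknown method {method!r}")

    if not method.startswith("fixed:") and min_contrast > 0:
        lo = gray[gray <= t]
        hi = gray[gray > t]
        if lo.size == 0 or hi.size == 0 or \
                hi.mean() - lo.mean() < min_contrast:
            return BinarizeResult(
                mask=np.zeros(gray.shape, bool), threshold=t,
                method=method, polarity=polarity, degenerate=True)

    if polarity == "dark_foreground":
        mask = gray <= t
    else:
        mask = gray > t
    return BinarizeResult(mask=mask, threshold=t, method=method,
                          polarity=polarity, degenerate=degenerate)


def label_clusters(
    mask: np.ndarray,
    connectivity: int = 8,
    min_area: int = 64,
    exclude_border: bool = False,
) -> np.ndarray:
    """Label connected clusters in a binary mask.

    Components are found under 4- or 8-connectivity, components smaller
    than ``min_area`` pixels are suppressed (debris), and the survivors
    are relabeled 1..K in raster-scan order of their first pixel.
    Border-touching clusters are kept by default, matching common
    particle-analyzer behavior; set ``exclude_border`` to drop them.
    """
    mask = np.asarray(mask, bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = _sk_label(mask, connectivity=1 if connectivity == 4 else 2)
    if lab.max() == 0:
        return lab
    areas = np.bincount(lab.ravel())
    drop = np.flatnonzero(areas < min_area)
    if exclude_border:
        edge = np.unique(
            np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        )
        drop = np.union1d(drop, edge)
    keep = np.setdiff1d(np.arange(1, lab.max() + 1), drop)
    remap = np.zeros(lab.max() + 1, dtype=lab.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[lab]
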