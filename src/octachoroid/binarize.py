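"""Otsu global thresholding from the 256-bin intensity histogram.

The threshold convention throughout the package: a pixel is *black*
(vessel lumen) when its intensity is less than or equal to the threshold,
*white* (choroidal stroma) otherwise.  The threshold minimizes the
weighted intra-class intensity variance (equivalently maximizes the
between-class variance) over the 8-bit histogram; among tied candidates
the smallest threshold is returned.  Inputs that are not 8-bit are
linearly rescaled to 0-255 first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BinaryImage", "DegenerateImageWarning", "otsu_threshold", "binarize"]


class DegenerateImageWarning(UserWarning):
    """Raised (as a warning) when an image has a single grey level."""


@dataclass
class BinaryImage:
    """Thresholded image: ``mask`` True = black = vessel lumen."""

    mask: np.ndarray
    threshold: int
    source_shape: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mask.shape != tuple(self.source_shape):
            raise ValueError(
                f"mask shape {self.mask.shape} != source shape {self.source_shape}"
            )
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")

    @property
    def black_fraction(self) -> float:
        return float(self.mask.mean())


def _as_uint8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    if image.dtype == np.uint8:
        return image
    lo = float(image.min())
    hi = float(image.max())
    if hi == lo:
        return np.zeros(image.shape, np.uint8) + np.uint8(np.clip(round(lo), 0, 255))
    scaled = (image.astype(np.float64) - lo) / (hi - lo) * 255.0
    return np.round(scaled).astype(np.uint8)


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu threshold of a grayscale image, black = intensity <= t.

    Scans every split t in 0..254 (t = 255 would leave a single class) and
    maximizes the between-class variance computed from the 256-bin
    histogram; the smallest maximizing t is returned.  A constant image is
    degenerate: its single grey level is returned with a
    :class:`DegenerateImageWarning`.
    """
    img = _as_uint8(image)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        warnings.warn(
            f"constant image (grey level {nonzero[0]}); threshold is degenerate",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return int(nonzero[0])

    w0 = np.cumsum(hist)[:-1]                     # pixels with level <= t, t=0..254
    w1 = total - w0
    s0 = np.cumsum(hist * levels)[:-1]
    mu0 = np.divide(s0, w0, out=np.zeros_like(s0), where=w0 > 0)
    mu1 = np.divide(
        hist @ levels - s0, w1, out=np.zeros_like(s0), where=w1 > 0
    )
    between = w0 * w1 * (mu0 - mu1) ** 2          # scale factors drop out
    valid = (w0 > 0) & (w1 > 0)
    between[~valid] = -np.inf
    return int(np.argmax(between))                # argmax takes the smallest tie


def binarize(image: np.ndarray) -> BinaryImage:
    """Binarize with Otsu's method; black (True) = lumen, white = stroma.

    Degenerate (constant) images produce an all-white mask by convention.
    """
    img = _as_uint8(image)
    degenerate = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DegenerateImageWarning)
        t = otsu_threshold(img)
        degenerate = any(
            issubclass(w.category, DegenerateImageWarning) for w in caught
        )
    if degenerate:
        warnings.warn(
            "degenerate image: emitting all-white mask",
            DegenerateImageWarning,
            stacklevel=2,
        )
        mask = np.zeros(img.shape, bool)
    else:
        mask = img <= t
    return BinaryImage(
        mask=mask, threshold=t, source_shape=img.shape, degenerate=degenerate
    )
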