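"""Choroidal vascular density (CVD) from a binarized OCTA slab.

CVD is the proportion of black (vessel-lumen) pixels in a binarized
en-face choroidal OCTA image, in percent.  The dark pixels are counted
deliberately — the bright-pixel "flow density" that OCTA device software
reports for the choriocapillaris measures the opposite quantity in deep
choroid, where lumens are dark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binarize import binarize
from .slabs import quantize_depth

__all__ = ["CvdResult", "DEFAULT_CVD_DEPTH_UM", "measure_cvd"]

#: Default measurement depth: nominal 100 um beneath BM, quantized to the
#: 2.6-um axial grid.
DEFAULT_CVD_DEPTH_UM = quantize_depth(100.0, 2.6)   # 98.8 um


@dataclass
class CvdResult:
    eye_id: str
    depth: float                # um beneath BM
    cvd: float                  # percent black pixels
    threshold_used: int
    black_pixels: int
    total_pixels: int
    degenerate: bool = False


def measure_cvd(
    octa_image: np.ndarray, depth: float = DEFAULT_CVD_DEPTH_UM, eye_id: str = ""
) -> CvdResult:
    """Binarize an OCTA slab with Otsu's method and report the black fraction.

    A degenerate (constant) image yields CVD 0 with the degenerate flag set.
    """
    bi = binarize(octa_image)
    black = int(bi.mask.sum())
    total = int(bi.mask.size)
    return CvdResult(
        eye_id=eye_id,
        depth=depth,
        cvd=100.0 * black / total,
        threshold_used=bi.threshold,
        black_pixels=black,
        total_pixels=total,
        degenerate=bi.degenerate,
    )
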